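import numpy as np
import pytest

from foalwatch.coco import Annotation, CocoDataset, ImageRecord
from foalwatch.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    spec = SceneSpec(
        width=96, height=64, n_mares=1, postures=("standing",),
        classes=("MP",), seed=7,
    )
    return generate_scene(spec)


@pytest.fixture()
def toy_coco():
    """Five images, mixed classes, all boxes in bounds."""
    images = [ImageRecord(i, f"im{i}.png", 100, 80) for i in range(1, 6)]
    anns = [
        Annotation(1, 1, 1, (10, 10, 30, 20)),
        Annotation(2, 1, 2, (50, 40, 30, 20)),
        Annotation(3, 2, 2, (5, 5, 40, 30)),
        Annotation(4, 3, 1, (20, 25, 35, 25)),
        Annotation(5, 4, 2, (60, 10, 25, 40)),
        Annotation(6, 5, 2, (15, 30, 50, 20)),
    ]
    return CocoDataset(images=images, annotations=anns).validate()
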