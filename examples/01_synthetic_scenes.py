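"""Generate synthetic stable scenes with COCO annotations.

Each scene is a textured paddock with 1-4 mares drawn as ellipses; a mare
in parturition (MP) carries a small bright fetal-sac blob at its rear.
"""

import numpy as np

from foalwatch import SceneSpec, generate_dataset, generate_scene

scene = generate_scene(SceneSpec(
    width=384, height=216, n_mares=2,
    postures=("standing", "recumbent"), classes=("MP", "MNP"),
    lighting="day", seed=42,
))
print(f"scene image: {scene.image.shape}, dtype {scene.image.dtype}")
for box, label, rear in zip(scene.boxes, scene.labels, scene.rears):
    x, y, w, h = (round(v, 1) for v in box)
    print(f"  {label}: box=({x}, {y}, {w}, {h}), rear on the {rear}")

# the MP box's rear quarter is brighter than its front (the fetal sac)
(x, y, w, h), rear = scene.boxes[0], scene.rears[0]
grey = scene.image.mean(axis=2)
x0, x1, y0, y1 = int(x), int(x + w), int(y), int(y + h)
q = (x1 - x0) // 4
left, right = grey[y0:y1, x0:x0 + q].mean(), grey[y0:y1, x1 - q:x1].mean()
rear_mean, front_mean = (left, right) if rear == "left" else (right, left)
print(f"MP box rear-quarter intensity {rear_mean:.1f} vs front {front_mean:.1f}")

ds = generate_dataset(
    n_scenes=50, mp_fraction=0.3,
    spec_template=SceneSpec(width=192, height=108, n_mares=1,
                            postures=("standing",), classes=("MNP",), seed=7),
)
counts = ds.class_counts()
print(f"\n50-scene dataset: {len(ds.images)} images, "
      f"{len(ds.annotations)} annotations, "
      f"MP={counts['MP']} MNP={counts['MNP']}")
print("With mp_fraction=0.3 roughly 30% of scenes carry one MP mare.")
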