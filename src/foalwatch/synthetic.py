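"""Synthetic stable scenes and frame-label streams.

The farm footage behind this task is private, so every stage of the
pipeline is exercised on procedurally generated stand-ins:

* **Scenes** — a textured paddock containing 0–4 mares drawn as filled
  ellipses (standing and recumbent postures differ in aspect ratio).  A
  mare in parturition (MP) carries a small bright blob at the rear of its
  body, emulating the elevated white fetal sac that visually defines the
  class; it occupies only ~10–15% of the body length, which reproduces the
  small-feature regime that makes the detection problem hard.  Day scenes
  are colour; night scenes are greyscale with additive sensor noise.
* **Streams** — per-second MP/MNP labels with a true onset time and
  configurable per-frame sensitivity/specificity, emulating a frame
  classifier running on a 1 fps video stream.

All randomness flows through explicit integer seeds; identical specs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alertstream import MNP, MP, FrameEntry, FrameLabelStream
from .coco import CATEGORY_IDS, Annotation, CocoDataset, ImageRecord

STANDING, RECUMBENT = "standing", "recumbent"

#: body aspect ratios (length : height of the bounding ellipse)
_ASPECT = {STANDING: 1.6, RECUMBENT: 2.6}


@dataclass(frozen=True)
class SceneSpec:
    width: int = 384
    height: int = 216
    n_mares: int = 1
    postures: tuple[str, ...] = (STANDING,)
    classes: tuple[str, ...] = (MNP,)
    lighting: str = "day"
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.width < 32 or self.height < 32:
            raise ValueError("scene must be at least 32x32 pixels")
        if not (0 <= self.n_mares <= 4):
            raise ValueError("n_mares must be between 0 and 4")
        if len(self.postures) != self.n_mares or len(self.classes) != self.n_mares:
            raise ValueError(
                "postures and classes must each have one entry per mare"
            )
        for p in self.postures:
            if p not in (STANDING, RECUMBENT):
                raise ValueError(f"unknown posture {p!r}")
        for c in self.classes:
            if c not in (MP, MNP):
                raise ValueError(f"unknown class {c!r}")
        if self.lighting not in ("day", "night"):
            raise ValueError(f"unknown lighting {self.lighting!r}")


@dataclass
class SyntheticScene:
    image: np.ndarray  # H x W x 3 uint8
    boxes: list[tuple[float, float, float, float]]
    labels: list[str]
    rears: list[str] = field(default_factory=list)  # "left" | "right" per mare


@dataclass(frozen=True)
class StreamSpec:
    length_s: int = 300
    onset_s: int | None = 100
    sensitivity: float = 1.0
    specificity: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.onset_s is not None and not 0 <= self.onset_s < self.length_s:
            raise ValueError("onset_s must satisfy 0 <= onset_s < length_s")
        for p in (self.sensitivity, self.specificity):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float,
                  yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one stable scene with tight whole-body boxes per mare."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)

    # paddock background: muted green-grey with low-frequency texture
    base = np.array([96.0, 104.0, 88.0])
    img = np.tile(base, (H, W, 1))
    img += rng.normal(0.0, 6.0, size=(H, W, 1))
    gradient = (yy / max(H - 1, 1) * 14.0 - 7.0)[..., None]
    img += gradient

    boxes: list[tuple[float, float, float, float]] = []
    labels: list[str] = []
    rears: list[str] = []
    slots = np.arange(max(spec.n_mares, 1))
    rng.shuffle(slots)
    for i in range(spec.n_mares):
        posture, cls = spec.postures[i], spec.classes[i]
        aspect = _ASPECT[posture]
        # body length ~35-55% of the scene's short side
        length = (0.35 + 0.2 * rng.random()) * min(H, W)
        rx = length / 2.0
        ry = rx / aspect
        slot_w = W / max(spec.n_mares, 1)
        cx = slot_w * (slots[i] + 0.5) + rng.uniform(-0.1, 0.1) * slot_w
        cy = H * (0.35 + 0.4 * rng.random())
        cx = float(np.clip(cx, rx + 2, W - rx - 3))
        cy = float(np.clip(cy, ry + 2, H - ry - 3))
        flip = rng.random() < 0.5  # rear on the left when flipped

        body = _ellipse_mask(H, W, cy, cx, ry, rx, yy, xx)
        coat = np.array([118.0, 86.0, 60.0]) + rng.normal(0.0, 10.0, size=3)
        img[body] = coat + rng.normal(0.0, 5.0, size=(int(body.sum()), 3))
        # darker mane stripe along the top of the body
        mane = _ellipse_mask(H, W, cy - 0.6 * ry, cx, 0.35 * ry, 0.9 * rx, yy, xx)
        img[mane & body] *= 0.8

        if cls == MP:
            # fetal sac: bright blob at the rear, 10-15% of body length
            sac_rx = (0.10 + 0.05 * rng.random()) * length / 2.0 * 2.0
            sac_rx = max(sac_rx, 2.0)
            sac_ry = max(0.7 * sac_rx, 1.5)
            rear_x = cx + (-1 if flip else 1) * (rx - sac_rx * 0.9)
            sac = _ellipse_mask(H, W, cy + 0.15 * ry, rear_x, sac_ry, sac_rx, yy, xx)
            sac &= body  # sac stays inside the tight body box
            img[sac] = np.array([235.0, 231.0, 224.0]) + rng.normal(
                0.0, 3.0, size=(int(sac.sum()), 3)
            )

        x0, y0 = cx - rx, cy - ry
        bw, bh = 2 * rx, 2 * ry
        x0 = float(np.clip(x0, 0, W - 1))
        y0 = float(np.clip(y0, 0, H - 1))
        bw = float(min(bw, W - x0))
        bh = float(min(bh, H - y0))
        boxes.append((x0, y0, bw, bh))
        labels.append(cls)
        rears.append("left" if flip else "right")

    if spec.lighting == "night":
        grey = img @ np.array([0.299, 0.587, 0.114])
        img = np.repeat(grey[..., None], 3, axis=2)
    if spec.noise_sd > 0:
        if spec.lighting == "night":
            noise = rng.normal(0.0, spec.noise_sd, size=(H, W, 1))
            img = img + np.repeat(noise, 3, axis=2)
        else:
            img = img + rng.normal(0.0, spec.noise_sd, size=(H, W, 3))

    image = np.clip(img, 0, 255).astype(np.uint8)
    return SyntheticScene(image=image, boxes=boxes, labels=labels, rears=rears)


def generate_dataset(
    n_scenes: int,
    mp_fraction: float,
    spec_template: SceneSpec,
    out_dir: str | Path | None = None,
    scenes_out: list[SyntheticScene] | None = None,
) -> CocoDataset:
    """Generate ``n_scenes`` scenes and their COCO annotations.

    A scene is a parturition scene with probability ``mp_fraction``; such a
    scene contains exactly one MP mare, all others MNP.  Postures are drawn
    uniformly.  When ``out_dir`` is given, PNG images and an
    ``annotations.json`` are written there.  Pass ``scenes_out`` to also
    collect the rendered scenes in memory.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    if not 0.0 <= mp_fraction <= 1.0:
        raise ValueError("mp_fraction must lie in [0, 1]")
    rng = np.random.default_rng(spec_template.seed)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n_scenes)
    is_mp_scene = rng.random(n_scenes) < mp_fraction

    images: list[ImageRecord] = []
    annotations: list[Annotation] = []
    ann_id = 1
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        try:
            out_path.mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise OSError(f"cannot create output directory {out_path}: {exc}") from exc

    for i in range(n_scenes):
        local = np.random.default_rng(scene_seeds[i])
        n_mares = spec_template.n_mares
        postures = tuple(
            STANDING if local.random() < 0.5 else RECUMBENT for _ in range(n_mares)
        )
        classes = [MNP] * n_mares
        if is_mp_scene[i] and n_mares > 0:
            classes[int(local.integers(0, n_mares))] = MP
        spec = SceneSpec(
            width=spec_template.width,
            height=spec_template.height,
            n_mares=n_mares,
            postures=postures,
            classes=tuple(classes),
            lighting=spec_template.lighting,
            noise_sd=spec_template.noise_sd,
            seed=int(scene_seeds[i]),
        )
        scene = generate_scene(spec)
        if scenes_out is not None:
            scenes_out.append(scene)
        file_name = f"scene_{i:05d}.png"
        images.append(
            ImageRecord(id=i + 1, file_name=file_name,
                        width=spec.width, height=spec.height)
        )
        for bbox, label in zip(scene.boxes, scene.labels):
            annotations.append(
                Annotation(
                    id=ann_id, image_id=i + 1,
                    category_id=CATEGORY_IDS[label], bbox=bbox,
                )
            )
            ann_id += 1
        if out_path is not None:
            from PIL import Image

            Image.fromarray(scene.image).save(out_path / file_name)

    dataset = CocoDataset(images=images, annotations=annotations).validate()
    if out_path is not None:
        from .coco import write_coco

        write_coco(dataset, out_path / "annotations.json")
    return dataset


def generate_stream(spec: StreamSpec) -> FrameLabelStream:
    """Simulate a per-second frame-label stream with a true onset.

    Frames at or after the onset are truly positive and labelled MP with
    probability ``sensitivity``; frames before the onset (or all frames when
    there is no onset) are labelled MP with probability ``1 − specificity``.
    Emitted-class confidences are Uniform(0.5, 1].
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.random(spec.length_s)
    confs = 0.5 + 0.5 * (1.0 - rng.random(spec.length_s))  # in (0.5, 1.0]
    entries = []
    for t in range(spec.length_s):
        truly_positive = spec.onset_s is not None and t >= spec.onset_s
        p_mp = spec.sensitivity if truly_positive else 1.0 - spec.specificity
        label = MP if u[t] < p_mp else MNP
        entries.append(FrameEntry(t=t, label=label, conf=float(confs[t])))
    return FrameLabelStream(entries)
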