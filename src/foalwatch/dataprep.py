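"""Data curation: frame extraction, SSIM dedup, resizing, split, augmentation.

This mirrors the curation protocol used to build the parturition dataset:
keep one frame in ten from 25 fps footage, drop near-duplicate consecutive
frames whose structural similarity exceeds 0.76, resize 1920×1080 stills to
384×216, split 2:1 into train/test, and double the training set with one
augmented copy per image (small occlusion rectangle, contrast jitter, mild
blur).  Video decoding itself is delegated: any object that yields frames
and reports an ``fps`` works as a source, as does a directory of stills.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Protocol, Sequence

import numpy as np
from skimage.metrics import structural_similarity
from skimage.transform import resize as _sk_resize

from .coco import Annotation, CocoDataset, ImageRecord


class FrameSource(Protocol):
    """Anything that yields frames in temporal order and knows its fps."""

    fps: float

    def __iter__(self) -> Iterator[np.ndarray]: ...


@dataclass
class ArrayFrameSource:
    """In-memory frame source (mostly for tests and synthetic footage)."""

    frames: Sequence[np.ndarray]
    fps: float = 25.0

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)


class DirectoryFrameSource:
    """Frames stored as individual image files, sorted by filename."""

    def __init__(self, path: str | Path, fps: float = 25.0):
        self.path = Path(path)
        self.fps = fps
        if not self.path.is_dir():
            raise IOError(f"not a readable frame directory: {self.path}")
        self.files = sorted(
            p for p in self.path.iterdir()
            if p.suffix.lower() in (".png", ".jpg", ".jpeg")
        )

    def __iter__(self) -> Iterator[np.ndarray]:
        from PIL import Image

        for f in self.files:
            yield np.asarray(Image.open(f))


@dataclass(frozen=True)
class SplitConfig:
    train_parts: int = 2
    test_parts: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.train_parts < 1 or self.test_parts < 1:
            raise ValueError("split parts must be >= 1")


@dataclass(frozen=True)
class AugmentationConfig:
    crop_h_min: int = 8
    crop_h_max: int = 14
    crop_w_min: int = 8
    crop_w_max: int = 14
    brightness_limit: float = 0.0
    contrast_limit: tuple[float, float] = (0.0, 1.0)
    blur_low: float = 0.1
    blur_high: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.crop_h_min > self.crop_h_max or self.crop_w_min > self.crop_w_max:
            raise ValueError("occlusion mins must not exceed maxes")
        if self.brightness_limit < 0 or self.blur_low < 0:
            raise ValueError("limits must be non-negative")
        if self.contrast_limit[0] > self.contrast_limit[1]:
            raise ValueError("contrast_limit interval inverted")


def extract_frames(
    video: FrameSource,
    stride: int = 10,
    out_dir: str | Path | None = None,
    frames_out: list[np.ndarray] | None = None,
    id_offset: int = 0,
) -> list[ImageRecord]:
    """Keep every ``stride``-th frame (indices 0, stride, 2·stride, ...).

    Timestamps derive from the source fps: t = frame_index / fps.  Frames
    are written as PNG when ``out_dir`` is given and collected into
    ``frames_out`` when provided.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    fps = getattr(video, "fps", 25.0)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    records: list[ImageRecord] = []
    kept = 0
    for idx, frame in enumerate(video):
        if idx % stride != 0:
            continue
        frame = np.asarray(frame)
        h, w = frame.shape[:2]
        name = f"frame_{idx:06d}.png"
        records.append(
            ImageRecord(
                id=id_offset + kept + 1, file_name=name,
                width=w, height=h, timestamp=idx / fps,
            )
        )
        if frames_out is not None:
            frames_out.append(frame)
        if out_path is not None:
            from PIL import Image

            Image.fromarray(frame).save(out_path / name)
        kept += 1
    return records


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        img = img @ np.array([0.299, 0.587, 0.114])
    return img


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Structural similarity on greyscale, reference parameterisation."""
    ga, gb = _to_gray(a), _to_gray(b)
    if ga.shape != gb.shape:
        raise ValueError(f"dimension mismatch: {ga.shape} vs {gb.shape}")
    return float(structural_similarity(ga, gb, data_range=255.0))


def dedup_ssim_indices(
    images: Sequence[np.ndarray], threshold: float = 0.76
) -> list[int]:
    """Indices retained by sequential-greedy SSIM deduplication.

    The first image is always kept; a candidate is dropped iff its SSIM to
    the *last retained* image is strictly greater than ``threshold``.
    Order is preserved.
    """
    if len(images) == 0:
        raise ValueError("dedup requires a non-empty image list")
    kept = [0]
    for i in range(1, len(images)):
        if ssim(images[i], images[kept[-1]]) <= threshold:
            kept.append(i)
    return kept


def dedup_ssim(
    images: Sequence[np.ndarray], threshold: float = 0.76
) -> list[np.ndarray]:
    """The retained images themselves (see :func:`dedup_ssim_indices`)."""
    return [images[i] for i in dedup_ssim_indices(images, threshold)]


def resize_image(img: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Resize to ``(width, height)``; identity targets return a copy."""
    tw, th = target
    if tw <= 0 or th <= 0:
        raise ValueError("target dimensions must be positive")
    h, w = img.shape[:2]
    if (w, h) == (tw, th):
        return img.copy()
    out = _sk_resize(img, (th, tw), anti_aliasing=True, preserve_range=True)
    if np.issubdtype(img.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(img.dtype)
    return out


def scale_bbox(
    bbox: Sequence[float], sx: float, sy: float
) -> tuple[float, float, float, float]:
    x, y, w, h = bbox
    return (x * sx, y * sy, w * sx, h * sy)


def resize_images(
    images: Sequence[np.ndarray],
    target: tuple[int, int] = (384, 216),
    boxes: Sequence[Sequence[Sequence[float]]] | None = None,
):
    """Resize a batch to ``(width, height)``, scaling any boxes alongside."""
    out_images = []
    out_boxes = [] if boxes is not None else None
    for i, img in enumerate(images):
        h, w = img.shape[:2]
        out_images.append(resize_image(img, target))
        if boxes is not None:
            sx, sy = target[0] / w, target[1] / h
            out_boxes.append([scale_bbox(b, sx, sy) for b in boxes[i]])
    if boxes is not None:
        return out_images, out_boxes
    return out_images


def split_dataset(
    dataset: CocoDataset, config: SplitConfig = SplitConfig()
) -> tuple[CocoDataset, CocoDataset]:
    """Randomly partition images ``train_parts : test_parts`` (default 2:1).

    The train side takes round-half-up(n · train/(train+test)) images, so
    5680 images split 2:1 into 3787 train and 1893 test.
    """
    n = len(dataset.images)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    frac = config.train_parts / (config.train_parts + config.test_parts)
    n_train = int(math.floor(n * frac + 0.5))
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    ids = [dataset.images[i].id for i in order]
    train_ids, test_ids = set(ids[:n_train]), set(ids[n_train:])
    return dataset.subset(train_ids), dataset.subset(test_ids)


def _augment_pixels(
    img: np.ndarray, config: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """One augmented copy: occlusion rectangle + contrast jitter + blur."""
    from scipy.ndimage import gaussian_filter

    out = np.asarray(img, dtype=np.float64).copy()
    h, w = out.shape[:2]
    # occlusion rectangle, 8-14 px a side (simulates small occlusions)
    oh = int(rng.integers(config.crop_h_min, config.crop_h_max + 1))
    ow = int(rng.integers(config.crop_w_min, config.crop_w_max + 1))
    oh, ow = min(oh, h), min(ow, w)
    oy = int(rng.integers(0, h - oh + 1))
    ox = int(rng.integers(0, w - ow + 1))
    out[oy : oy + oh, ox : ox + ow] = 0.0
    # contrast jitter: factor in 1 + [lo, hi] around the image mean
    alpha = 1.0 + rng.uniform(*config.contrast_limit)
    mean = out.mean()
    out = (out - mean) * alpha + mean
    # brightness shift (disabled when the limit is 0)
    if config.brightness_limit > 0:
        out = out + rng.uniform(-config.brightness_limit, config.brightness_limit) * 255.0
    # mild gaussian blur
    sigma = rng.uniform(config.blur_low, config.blur_high)
    if out.ndim == 3:
        out = gaussian_filter(out, sigma=(sigma, sigma, 0))
    else:
        out = gaussian_filter(out, sigma=sigma)
    if np.issubdtype(img.dtype, np.integer):
        out = np.clip(np.rint(out), 0, 255).astype(img.dtype)
    return out


def augment_dataset(
    train: CocoDataset,
    config: AugmentationConfig = AugmentationConfig(),
    images: dict[int, np.ndarray] | None = None,
) -> CocoDataset | tuple[CocoDataset, dict[int, np.ndarray]]:
    """Append exactly one augmented copy per image, doubling the set.

    Annotations are copied onto the augmented image (the occlusion
    rectangle does not move objects).  When ``images`` maps image id to
    pixel array, the augmented arrays are returned alongside the records.
    """
    rng = np.random.default_rng(config.seed)
    if not train.images:
        return (CocoDataset(categories=dict(train.categories)), {}) if images is not None \
            else CocoDataset(categories=dict(train.categories))
    max_img = max(im.id for im in train.images)
    max_ann = max((a.id for a in train.annotations), default=0)
    out = CocoDataset(
        images=[replace(im) for im in train.images],
        annotations=[replace(a) for a in train.annotations],
        categories=dict(train.categories),
    )
    aug_images: dict[int, np.ndarray] = {}
    ann_id = max_ann
    for im in train.images:
        new_id = im.id + max_img
        stem, dot, ext = im.file_name.rpartition(".")
        aug_name = f"{stem or im.file_name}_aug{dot}{ext}" if dot else im.file_name + "_aug"
        out.images.append(
            ImageRecord(id=new_id, file_name=aug_name,
                        width=im.width, height=im.height, timestamp=im.timestamp)
        )
        if images is not None:
            aug_images[new_id] = _augment_pixels(images[im.id], config, rng)
        else:
            # keep the random stream aligned whether or not pixels are given
            _ = rng.integers(0, 2**31 - 1, size=6)
        for ann in train.annotations:
            if ann.image_id == im.id:
                ann_id += 1
                out.annotations.append(
                    Annotation(id=ann_id, image_id=new_id,
                               category_id=ann.category_id, bbox=tuple(ann.bbox))
                )
    out.validate()
    if images is not None:
        return out, aug_images
    return out


def apply_exclusions(dataset: CocoDataset, exclude_ids: Iterable[int]) -> CocoDataset:
    """Drop manually screened-out images (anomalies are a curator's call)."""
    excl = set(exclude_ids)
    keep = {im.id for im in dataset.images} - excl
    return dataset.subset(keep)
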