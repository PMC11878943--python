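"""COCO-style dataset containers and JSON I/O.

Boxes are ``[x, y, w, h]`` in absolute pixels, 0-based, top-left origin.
Category ids are fixed for this task: mare parturition (MP) = 1 and mare
non-parturition (MNP) = 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

CATEGORY_IDS = {"MP": 1, "MNP": 2}
CATEGORY_NAMES = {v: k for k, v in CATEGORY_IDS.items()}


class CocoValidationError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class ImageRecord:
    id: int
    file_name: str
    width: int
    height: int
    timestamp: float | None = None

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise CocoValidationError(
                f"image {self.id}: non-positive dimensions {self.width}x{self.height}"
            )


@dataclass
class Annotation:
    id: int
    image_id: int
    category_id: int
    bbox: tuple[float, float, float, float]
    area: float | None = None

    def __post_init__(self):
        x, y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise CocoValidationError(f"annotation {self.id}: degenerate bbox {self.bbox}")
        if self.area is None:
            self.area = float(w) * float(h)


@dataclass
class CocoDataset:
    images: list[ImageRecord] = field(default_factory=list)
    annotations: list[Annotation] = field(default_factory=list)
    categories: dict[str, int] = field(default_factory=lambda: dict(CATEGORY_IDS))

    def validate(self) -> "CocoDataset":
        ids = [im.id for im in self.images]
        if len(ids) != len(set(ids)):
            raise CocoValidationError("duplicate image ids")
        by_id = {im.id: im for im in self.images}
        cat_ids = set(self.categories.values())
        for ann in self.annotations:
            if ann.image_id not in by_id:
                raise CocoValidationError(
                    f"annotation {ann.id}: dangling image_id {ann.image_id}"
                )
            if ann.category_id not in cat_ids:
                raise CocoValidationError(
                    f"annotation {ann.id}: unknown category {ann.category_id}"
                )
            im = by_id[ann.image_id]
            x, y, w, h = ann.bbox
            if x < 0 or y < 0 or x + w > im.width + 1e-6 or y + h > im.height + 1e-6:
                raise CocoValidationError(
                    f"annotation {ann.id}: bbox {ann.bbox} outside image "
                    f"{im.id} ({im.width}x{im.height})"
                )
        return self

    def annotations_for(self, image_id: int) -> list[Annotation]:
        return [a for a in self.annotations if a.image_id == image_id]

    def class_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in self.categories}
        for a in self.annotations:
            counts[CATEGORY_NAMES[a.category_id]] += 1
        return counts

    def subset(self, image_ids: set[int]) -> "CocoDataset":
        return CocoDataset(
            images=[replace(im) for im in self.images if im.id in image_ids],
            annotations=[replace(a) for a in self.annotations if a.image_id in image_ids],
            categories=dict(self.categories),
        )

    def to_dict(self) -> dict:
        return {
            "images": [
                {
                    "id": im.id,
                    "file_name": im.file_name,
                    "width": im.width,
                    "height": im.height,
                    **({"timestamp": im.timestamp} if im.timestamp is not None else {}),
                }
                for im in self.images
            ],
            "annotations": [
                {
                    "id": a.id,
                    "image_id": a.image_id,
                    "category_id": a.category_id,
                    "bbox": list(a.bbox),
                    "area": a.area,
                    "iscrowd": 0,
                }
                for a in self.annotations
            ],
            "categories": [
                {"id": cid, "name": name} for name, cid in sorted(
                    self.categories.items(), key=lambda kv: kv[1]
                )
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CocoDataset":
        try:
            images = [
                ImageRecord(
                    id=im["id"],
                    file_name=im["file_name"],
                    width=im["width"],
                    height=im["height"],
                    timestamp=im.get("timestamp"),
                )
                for im in d["images"]
            ]
            annotations = [
                Annotation(
                    id=a["id"],
                    image_id=a["image_id"],
                    category_id=a["category_id"],
                    bbox=tuple(a["bbox"]),
                    area=a.get("area"),
                )
                for a in d["annotations"]
            ]
            categories = {c["name"]: c["id"] for c in d["categories"]}
        except (KeyError, TypeError) as exc:
            raise CocoValidationError(f"malformed COCO record: {exc}") from exc
        return cls(images, annotations, categories).validate()


def read_coco(path: str | Path) -> CocoDataset:
    """Read and validate a COCO JSON annotation file."""
    path = Path(path)
    try:
        with open(path) as fh:
            d = json.load(fh)
    except json.JSONDecodeError as exc:
        raise CocoValidationError(f"{path}: malformed JSON ({exc})") from exc
    return CocoDataset.from_dict(d)


def write_coco(dataset: CocoDataset, path: str | Path) -> Path:
    """Validate and write a dataset as COCO JSON; returns the path."""
    path = Path(path)
    dataset.validate()
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(dataset.to_dict(), fh, indent=1)
    return path
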