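"""The data-curation pipeline on simulated footage.

Keep one frame in ten, drop near-duplicates above SSIM 0.76, resize to
384x216, split 2:1, and double the training set by augmentation.
"""

import numpy as np

from foalwatch import (AugmentationConfig, SplitConfig, augment_dataset,
                       dedup_ssim, extract_frames, resize_images,
                       split_dataset)
from foalwatch.coco import CocoDataset, ImageRecord
from foalwatch.dataprep import ArrayFrameSource

# simulated 25 fps footage: slow drift plus two abrupt scene changes
rng = np.random.default_rng(0)
base = rng.integers(60, 180, size=(54, 96), dtype=np.uint8)
frames = []
for t in range(95):
    f = base.astype(float) + 2.0 * np.sin(t / 7.0)
    if t in (40, 70):  # abrupt change
        base = rng.integers(60, 180, size=(54, 96), dtype=np.uint8)
        f = base.astype(float)
    frames.append(np.clip(f, 0, 255).astype(np.uint8))

records = extract_frames(ArrayFrameSource(frames, fps=25.0), stride=10,
                         frames_out=(kept := []))
print(f"extracted {len(records)} of 95 frames "
      f"(timestamps step {records[1].timestamp - records[0].timestamp:.1f} s)")

survivors = dedup_ssim(kept, threshold=0.76)
print(f"SSIM dedup keeps {len(survivors)} of {len(kept)} "
      "(drifting near-duplicates collapse, scene changes survive)")

resized = resize_images(survivors, target=(384, 216))
print(f"resized to {resized[0].shape[1]}x{resized[0].shape[0]}")

corpus = CocoDataset(images=[ImageRecord(i, f"{i}.png", 384, 216)
                             for i in range(1, 5681)])
train, test = split_dataset(corpus, SplitConfig(seed=0))
augmented = augment_dataset(train, AugmentationConfig(seed=0))
print(f"\n5680 images -> train {len(train.images)} / test {len(test.images)}; "
      f"augmentation doubles the train side to {len(augmented.images)}")
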