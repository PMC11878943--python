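"""COCO-style evaluation: matching, AP interpolations, mAP and AR."""

import numpy as np

from foalwatch import SceneSpec, generate_dataset, mean_ap
from foalwatch.evaluation import ImageDetection, PRCurve, average_precision

template = SceneSpec(width=128, height=72, n_mares=1,
                     postures=("standing",), classes=("MNP",), seed=11)
gts = generate_dataset(10, 0.5, template)

rng = np.random.default_rng(0)
dets = []
for ann in gts.annotations:
    x, y, w, h = ann.bbox
    jx, jy = rng.uniform(-3, 3, size=2)  # slightly misplaced detections
    dets.append(ImageDetection(ann.image_id, ann.category_id,
                               (max(x + jx, 0), max(y + jy, 0), w, h),
                               float(rng.uniform(0.6, 1.0))))
dets.append(ImageDetection(1, 1, (2, 2, 20, 10), 0.3))  # a spurious box

report = mean_ap(gts, dets)
print(report.table())
print("\nmAP averages AP over both classes and IoU 0.50:0.05:0.95;"
      "\nAR averages recall over the same ten thresholds.")

curve = PRCurve.from_flags([False, True], n_pos=1)
print(f"\nranked FP-then-TP on one object: 11-point AP = "
      f"{average_precision(curve):.2f} (max precision at full recall is 0.5)")
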