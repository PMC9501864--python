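"""Score a small set of detections against ground truth.

Builds a two-image toy test set with known outcomes — one perfect
detection, one duplicated detection (a surplus false positive), and
one miss — and prints the per-class summary table: percent TP/FP/FN,
mean IoU (zeros included for misses), precision, recall, F1 and the
average precision from the precision-recall curve.
"""

from shrapod import BBox, Detection
from shrapod.evaluation import evaluate_dataset

truths = [
    [BBox(20, 20, 40, 40, "artery"), BBox(80, 30, 30, 20, "vein")],
    [BBox(50, 60, 35, 35, "artery"), BBox(10, 10, 20, 12, "shrapnel")],
]
preds = [
    [Detection(BBox(20, 20, 40, 40, "artery"), 0.95),     # exact hit
     Detection(BBox(22, 22, 40, 40, "artery"), 0.60),     # surplus -> FP
     Detection(BBox(81, 30, 30, 20, "vein"), 0.85)],
    [Detection(BBox(52, 62, 35, 35, "artery"), 0.90)],    # good hit, shrapnel missed
]

table, summaries, curves = evaluate_dataset(preds, truths)
print(table.round(3).to_string())
print()
print("artery: 2 hits + 1 surplus duplicate -> precision 2/3, recall 1")
print("shrapnel: one ground truth, no prediction -> recall 0, mIoU 0")
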