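"""Box-level detection metrics from TP/FP/FN counts and from raw box lists.

Builds a box set that matches one month of field-validation counts
(720 true positives, 11 false positives, 224 missed plants) and confirms
the precision/recall arithmetic, then computes an average precision on a
small ranked example.
"""

from radixweed.metrics import (
    average_precision,
    format_percent,
    match_detections,
    precision,
    recall,
)
from radixweed.synth import gen_detection_tables

preds, gts = gen_detection_tables(tp=720, fp=11, fn=224, seed=0)
counts = match_detections(preds, gts, iou_threshold=0.5)
print(f"counts: TP={counts.tp} FP={counts.fp} FN={counts.fn}")
print(f"precision = {format_percent(precision(counts))}%  "
      f"recall = {format_percent(recall(counts))}%")

ap = average_precision(preds, gts, iou_threshold=0.5)
print(f"AP@0.5 over the same ranked predictions: {ap:.1f}%")
# precision is the fraction of predicted boxes that hit a real plant; recall
# the fraction of real plants found; AP integrates precision over recall.
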