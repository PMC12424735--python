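"""Evaluate a score set: PR/ROC areas, precision at 50% recall, and
prevalence-corrected precision for a 1:36 deployment imbalance.

A classifier's precision on a 1:6.5 test set overstates what a user would
see on the proteome, where methylated lysines are rarer; re-weighting false
positives by the ratio of the two imbalances (here 36/6.5) yields the
precision expected at deployment.
"""

import numpy as np

from methylsite.evaluation import (
    PrevalenceCorrection,
    imbalance_ratio,
    pr_roc_curves,
    precision_at_recall,
    prevalence_corrected_precision,
    threshold_for_target_pcpr,
)

rng = np.random.default_rng(1)
n = 3000
labels = (rng.random(n) < 2 / 15).astype(int)  # ~1:6.5 imbalance
scores = np.clip(rng.normal(0.35, 0.18, n) + 0.38 * labels, 0, 1)

curves = pr_roc_curves(scores, labels)
ratio = imbalance_ratio(int(labels.sum()), int((1 - labels).sum()))
print(f"test imbalance 1:{ratio}  AUPRC {curves.auprc:.3f}  "
      f"AUROC {curves.auroc:.3f}  Pr@0.5Re "
      f"{precision_at_recall(curves, 0.5):.3f}")

corr = PrevalenceCorrection(test_neg_pos_ratio=ratio, target_neg_pos_ratio=36)
point = next(p for p in curves.points if p.recall >= 0.5)
print(f"at 50% recall: raw precision {point.precision:.3f}, corrected to a "
      f"1:36 imbalance {prevalence_corrected_precision(point, corr):.3f}")

thr, pcpr, recall = threshold_for_target_pcpr(curves, corr, target_pcpr=0.75)
print(f"operating threshold for PCPr>=0.75: score >= {thr:.3f} "
      f"(achieves PCPr {pcpr:.3f} at recall {recall:.3f})")
print("the corrected precision is always <= the raw precision when the "
      "target imbalance is more severe than the test set's.")
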