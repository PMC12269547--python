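"""Scoring: MAE/MALE, state confusion, and changepoint Jaccard/RMSE.

Shows the two-level error averaging, the tolerance-gated Hungarian
pairing of changepoints, and the worked RMSE example.
"""

import numpy as np

from diffpoint.evaluate import cp_rmse, jaccard, mae, male, pair_changepoints, state_metrics

# two trajectories with per-trajectory mean errors 0.1 and 0.3 -> MAE 0.2
preds = [np.full(30, 1.1), np.full(90, 1.3)]
gts = [np.full(30, 1.0), np.full(90, 1.0)]
print(f"MAE(alpha) = {mae(preds, gts):.3f}  (mean of per-trajectory means)")

# K errors live in log10(K+1) space
print(f"MALE(K)    = {male([np.ones(10)], [np.zeros(10)]):.3f}  "
      "(gt K=0 vs predicted log-space 1)")

conf, acc = state_metrics([np.array([0, 0, 2, 2, 2, 3])],
                          [np.array([0, 0, 2, 2, 3, 3])])
print(f"average class accuracy = {acc:.3f} (rows of absent classes excluded)")

gt_cps, pred_cps = np.array([10, 50]), np.array([12, 47, 90])
pairs, fn, fp = pair_changepoints(gt_cps, pred_cps)
print(f"\npairing gt={gt_cps.tolist()} pred={pred_cps.tolist()} -> "
      f"pairs={pairs}, FN={fn}, FP={fp}")
print(f"Jaccard = {jaccard(len(pairs), fn, fp):.3f}  (TP / (TP+FN+FP))")
print(f"RMSE over pairs = {cp_rmse(pairs):.4f}  (sqrt((4 + 9) / 2) = 2.5495)")
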