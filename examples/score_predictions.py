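"""Rank-based metrics on hand-built predictions.

Builds a tiny set of prediction records with known ranks and walks through
Top-N, mean reciprocal rank and macro-averaged F1, including the
pessimistic treatment of tied probabilities.
"""

import numpy as np

import morphoident as mi
from morphoident.identifier import Prediction
from morphoident.metrics import score

classes = ("sp_a", "sp_b", "sp_c")

records = [
    # true class on top -> rank 1
    mi.PredictionRecord("sp_a", Prediction(classes, np.array([0.7, 0.2, 0.1]))),
    # true class second -> rank 2
    mi.PredictionRecord("sp_b", Prediction(classes, np.array([0.5, 0.3, 0.2]))),
    # tie at the top: the true class loses the tie -> rank 2 (pessimistic)
    mi.PredictionRecord("sp_a", Prediction(classes, np.array([0.4, 0.4, 0.2]))),
    # true class last -> rank 3
    mi.PredictionRecord("sp_c", Prediction(classes, np.array([0.5, 0.3, 0.2]))),
]

for r in records:
    print(f"true={r.true_class}  probs={r.prediction.probabilities.tolist()}"
          f"  rank={mi.rank_of(r)}")

report = score(records)
print(f"\nTop-1 {report.top1:.3f}  Top-3 {report.top3:.3f}  "
      f"MRR {report.mrr:.3f}  macro-F1 {report.macro_f1:.3f}")
print("scaled /100:", report.scaled())
print("\nRanks are (1, 2, 2, 3): Top-1 = 1/4; MRR = (1 + 1/2 + 1/2 + 1/3)/4;")
print("macro-F1 averages per-class F1 over classes with a true instance.")
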