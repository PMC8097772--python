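"""Combining the binding and immunogenicity models.

The immunogenic model acts as a filter: a candidate predicted
non-immunogenic gets combined score 0 regardless of its binding affinity.
The example scores a small candidate set with both models, combines them,
and reports confusion metrics and top-k recognition.
"""

import numpy as np

from netbim import (
    combine_predictions,
    confusion_metrics,
    topk_recognition,
)

rng = np.random.default_rng(3)
n = 60
pairs = [("HLA-A*02:01", "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 9)))
         for _ in range(n)]
truth = (rng.random(n) < 0.3).astype(int)
# toy model outputs: informative but noisy scores
ba = np.clip(0.5 * truth + rng.normal(0.3, 0.15, n), 0, 1)
icp = np.clip(0.4 * truth + rng.normal(0.3, 0.15, n), 0, 1)

pred = combine_predictions(pairs, ba, icp)
print(pred.df.head(5).round(3).to_string(index=False))

calls = (pred.df["combined_score"] > 0.426).astype(int)
s = confusion_metrics(calls, truth)
print(f"\naccuracy {s.accuracy:.2f}  sensitivity {s.sensitivity:.2f}  "
      f"specificity {s.specificity:.2f}  PPV {s.ppv:.2f}")

top = topk_recognition(pred.df["combined_score"], pred.df["peptide"].tolist(), truth,
                       ks=[10, 20])
print(f"true positives in top-10: {top[10]:.0%}, top-20: {top[20]:.0%}")
print("A pair with ic=0 has combined score 0: the filter removes it from the ranking.")
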