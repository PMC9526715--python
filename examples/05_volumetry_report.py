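"""Volumetry agreement analytics on simulated reader annotations.

Computes, without any training: per-structure Dice/VD/RVD of one reader
against the majority-vote SoR, Bland–Altman bias and limits of agreement
of volumes across cases, OLS volume regression, and the pairwise
reader-agreement matrix (Dice upper triangle, volume R² lower triangle).
"""

import numpy as np

from hepavol import evaluate as ev
from hepavol.phantom import generate_dataset

cases = generate_dataset(6, base_seed=12, shape=(16, 48, 48))
sors = [ev.majority_vote_sor(c.readers) for c in cases]
pred = [c.readers[0] for c in cases]  # treat reader 1 as the "tool"

report = ev.evaluate_cases(pred, sors)
liver = report["aggregate"]["liver"]
print(f"liver: Dice {liver['dice_mean']:.4f} ± {liver['dice_sd']:.4f}, "
      f"VD {liver['vd_ml_mean']:+.2f} ml, RVD {liver['rvd_pct_mean']:+.2f}%")
ba = liver["bland_altman"]
print(f"Bland–Altman: bias {ba['bias_ml']:+.2f} ml, "
      f"LoA [{ba['loa_low_ml']:+.2f}, {ba['loa_high_ml']:+.2f}] ml")
ols = liver["ols"]
print(f"OLS: slope {ols['slope']:.3f}, intercept {ols['intercept_ml']:+.1f} ml, "
      f"R² {ols['r2']:.4f}")

matrix = ev.agreement_matrix([c.readers for c in cases], pred, ev.LIVER)
d = matrix.as_dict()
for pair, val in d["dice"].items():
    print(f"{pair}: Dice {val['mean']:.4f} ± {val['sd']:.4f}, "
          f"volume R² {d['r2'][pair]:.4f}")

# Reader 1 agrees with the consensus at Dice ~0.97 with a small volume
# bias; the pairwise matrix mirrors a multi-reader study's triangular
# agreement table.
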