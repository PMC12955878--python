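"""Survival risk and immunotherapy-response prediction from expression grids.

A synthetic Cox cohort: each subject's expression grid carries latent gene
shifts that define the hazard. The ConvNeXt-V2 backbone plus Cox head is
trained by 5-fold stratified cross-validation; held-out risks are scored by
Harrell's C-index and a median-split log-rank test — the same read-outs
used for real cohorts.
"""

import numpy as np

from hist_st.experiments import icb_recovery, survival_recovery

res = survival_recovery(seed=0, n=200, hazard_ratio=3.0)
print("survival head, 5-fold cross-validation (n = 200, HR 3, 30% censoring):")
print(f"  held-out C-index per fold: {np.round(res['fold_c_index'], 3)}")
print(f"  mean C-index:              {res['mean_c_index']:.3f}")
print(f"  (C-index of the true linear predictor: {res['true_c_index']:.3f})")
print(f"  median-split log-rank p:   {res['logrank_p']:.2e}")
print("  -> p < 0.05 means predicted risk groups have separated survival\n")

icb = icb_recovery(seed=0)
print("response classifier, balanced separable cohort (n = 60):")
for k in ("accuracy", "precision", "recall", "f1"):
    print(f"  {k}: {icb[k]:.3f}")
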