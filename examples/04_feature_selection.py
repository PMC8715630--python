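"""Correlation-based feature selection with collinearity pruning.

Features with |R| > 0.5 against the target scale survive the filter; of
each group of mutually dependent survivors (|R| > 0.85 among themselves),
one representative is kept.
"""

import numpy as np
import pandas as pd

from robokin import prune_collinear, select_features, vif

rng = np.random.default_rng(1)
n = 300
z = rng.normal(size=n)  # latent severity
df = pd.DataFrame(
    {
        "offset": 0.8 * z + 0.6 * rng.normal(size=n),
        "deviation": 0.7 * z + 0.7 * rng.normal(size=n),
        "speed_shape": -0.75 * z + 0.66 * rng.normal(size=n),  # anti-correlates
        "sub_number": 0.3 * z + 0.95 * rng.normal(size=n),  # too weak
        "fma_ue": np.clip(33 - 12 * z + 3 * rng.normal(size=n), 0, 66),
    }
)
df["scatter"] = df["offset"] + 0.2 * rng.normal(size=n)  # near-duplicate of offset

sel = select_features(df, "fma_ue")
print("candidate correlations:")
for f, r in sorted(sel.candidate_correlations.items(), key=lambda kv: -abs(kv[1])):
    mark = "*" if f in sel.selected else " "
    print(f"  {mark} {f:12s} R = {r:+.2f}")
pruned = prune_collinear(df, sel, keep_list=["offset"])
print(f"after pruning (keep-list prefers 'offset'): {pruned.selected}")
print(f"pruned: {pruned.pruned}")
rep = vif(df, sel.selected)
print("VIF of the selected set (>10 flags strong multicollinearity):")
for f, v in rep.vif.items():
    print(f"  {f:12s} {v:.1f}")
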