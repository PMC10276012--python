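"""Pearson screening and PCA of a size-normalized species trait table.

Traits are z-scored (correlation-matrix PCA) because they mix units.
The printed percentages are the variance fractions captured by the
leading components; loadings show which traits drive each axis.
"""

import numpy as np
import pandas as pd

import pulsekin as pk

rng = np.random.default_rng(3)
n = 17
freq = rng.standard_normal(n)
table = pd.DataFrame({
    "P_freq": freq,
    "u_mean": 0.8 * freq + 0.3 * rng.standard_normal(n),   # fast pulsers swim fast
    "P_time": -0.9 * freq + 0.2 * rng.standard_normal(n),
    "PER": rng.standard_normal(n),                          # independent axis
}, index=[f"sp{i}" for i in range(n)])

r, p = pk.pearson_matrix(table)
print("Pearson r (P_freq vs u_mean): "
      f"{r.loc['P_freq', 'u_mean']:.2f} (p = {p.loc['P_freq', 'u_mean']:.1e})")

res = pk.pca(table)
for i, frac in enumerate(res.explained_variance_ratio):
    print(f"PC{i + 1}: {100 * frac:5.1f}% of variance")
print("\nPC1 loadings (pulsation-speed axis):")
print(res.loadings["PC1"].round(2).to_string())
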