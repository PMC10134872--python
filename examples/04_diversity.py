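"""Alpha diversity, Bray-Curtis ordination and host-level clustering.

Computes Shannon/Simpson per sample, the all-pairs Bray-Curtis matrix,
a 2-axis principal-coordinate embedding, ANOSIM with host labels, and the
within- vs between-host distance comparison.
"""

import numpy as np
import pandas as pd

from viamet import (
    anosim,
    beta_diversity_matrix,
    intra_inter_comparison,
    pcoa,
    shannon,
    simpson,
)

rng = np.random.default_rng(3)
# Three hosts x four samples; each host has its own community profile.
profiles = {}
hosts = {}
for h in range(3):
    base = rng.dirichlet(np.ones(40) * 0.3)
    for r in range(4):
        sid = f"H{h + 1}_s{r + 1}"
        noisy = base * rng.lognormal(0, 0.2, size=40)
        profiles[sid] = noisy / noisy.sum()
        hosts[sid] = f"H{h + 1}"
table = pd.DataFrame(profiles)

for sid in list(table.columns)[:3]:
    p = table[sid].to_numpy()
    print(f"{sid}: Shannon={shannon(p):.3f}  Simpson={simpson(p):.3f}")

dm = beta_diversity_matrix(table)
ord_res = pcoa(dm, n_axes=2)
print("PC1/PC2 explain "
      + " / ".join(f"{v:.1%}" for v in ord_res.proportion_explained))

res = anosim(dm, [hosts[s] for s in dm.ids], n_permutations=999, seed=0)
print(f"ANOSIM by host: R={res.r_statistic:.3f}  p={res.p_value:.3f}")

ii = intra_inter_comparison(dm, [hosts[s] for s in dm.ids])
print(f"median distance within host {ii.median_intra:.3f} vs between hosts "
      f"{ii.median_inter:.3f} (rank-sum p={ii.p_value:.2e})")
# R near 1 with a small p says samples cluster by individual: personal
# signatures dominate the technical noise.
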