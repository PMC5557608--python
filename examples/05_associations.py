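"""Downstream statistics on a rate table.

Decomposes steady-state abundance variance into transcription/export/
decay shares, then detects a planted decay-rate shift in a labeled gene
set with the Wilcoxon + Holm-Bonferroni group comparison.
"""

import math

import numpy as np

from nucflux import group_rate_comparison, variance_contributions
from nucflux.simulate import plant_label_effect, sample_rates_with_variance_shares

g = math.log(2) / 1440.0

# variance decomposition with known generative shares 85/5/10
rates = sample_rates_with_variance_shares(5000, (0.85, 0.05, 0.10), g, rng=17)
shares = variance_contributions(rates, g)
for name, share in shares.items():
    print(f"variance share {name:14s} {100 * share:5.1f} %")

# plant a 2x decay shift in 300 of 3000 genes and test for it
rng = np.random.default_rng(2)
rates2 = rates.iloc[:3000].reset_index(drop=True)
shifted, labels = plant_label_effect(rates2, 300, "kD", 2.0, rng, label="RBP-X")
table = group_rate_comparison(shifted, labels)
row = table[(table.label == "RBP-X") & (table.rate == "kD")].iloc[0]
print(f"\nRBP-X vs unbound decay: log2 median ratio = "
      f"{row.log2_median_ratio:.2f}, Holm-adjusted p = {row.p_adj:.2e}, "
      f"significant = {bool(row.significant)}")

print(
    "\nShares sum to one by construction of the additive log decomposition; "
    "a two-fold decay shift in a 300-gene set is detected far below the "
    "0.01 adjusted threshold."
)
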