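"""Structural complementarity: miRNA-targeted genes carry less methylation.

Per-gene methylation levels are drawn from the generator's level model
(baseline beta mean 0.20) with a planted depression of 0.035 in the
targeted group — the scale of the real effect this package is built around
(group means near 0.19 vs 0.23). The two groups are compared per time point
with the two-sided Wilcoxon rank-sum test.
"""

import numpy as np

from mirmeth.integration import structural_complementarity
from mirmeth.synthetic import sample_gene_methylation_levels

rng = np.random.default_rng(11)
levels, targeted, others = sample_gene_methylation_levels(
    rng, n_targeted=300, n_other=300, mu=0.20, delta_targeted=0.035
)
report = structural_complementarity(targeted, others, levels)
cols = ["time_h", "targeted_mean", "targeted_sd", "other_mean", "other_sd",
        "p_value", "stars"]
print(report.levels[cols].to_string(index=False,
                                    float_format=lambda v: f"{v:.4g}"))
print()
print("At every time point the targeted group's mean methylation level sits")
print("about 0.035 below the non-targeted group, and the rank-sum test flags")
print("the gap (stars as in box-plot legends: * <0.05 ... **** <0.0001).")
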