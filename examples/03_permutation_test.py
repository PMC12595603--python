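"""Is dual regulation more frequent than chance? A permutation test.

A universe of 1000 functional genes contains 200 miRNA-regulated and 60
methylation-regulated genes, with the expected dual-regulation overlap
enriched threefold over independence (expected overlap under the null:
200*60/1000 = 12). Each of the 1000 iterations redraws both sets uniformly
without replacement and records the overlap; the add-one empirical p is the
upper tail at the observed overlap.
"""

import numpy as np

from mirmeth.integration import dual_regulation_permutation
from mirmeth.synthetic import SimConfig, generate

bundle = generate(
    SimConfig(seed=1, n_genes=1000, frac_functional=1.0, frac_targeted=0.2,
              frac_meth_regulated=0.06, rho_dual=3.0, n_mirnas=300)
)
truth = bundle.truth
res = dual_regulation_permutation(
    truth["functional"], truth["mirna_regulated"], truth["meth_regulated"],
    iterations=1000, seed=2,
)
null = np.array(res.null_overlaps)
print(f"universe N = {res.universe_size}, |miRNA set| = {res.n_mirna}, "
      f"|methylation set| = {res.n_meth}")
print(f"observed dual-regulated genes: {res.observed_overlap}")
print(f"null overlap: mean {null.mean():.2f}, sd {null.std(ddof=1):.2f} "
      f"(analytic expectation {res.n_mirna * res.n_meth / res.universe_size:.1f})")
print(f"empirical p = {res.p_empirical:.6f}")
print()
print("p at the add-one floor (1/1001) means no null draw reached the")
print("observed overlap: the planted co-regulation is non-random.")
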