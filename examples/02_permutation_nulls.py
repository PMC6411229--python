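"""Assess significance of co-phosphorylation with permutation null models.

Three randomizations (within each state, within each site, global) destroy
the pair-correlation structure while conserving value multisets. The
observed distribution is wider than every null when real coordination is
present, and the two-sample Kolmogorov-Smirnov test quantifies the gap.
"""

import numpy as np

from cophos import (
    SyntheticConfig,
    build_cophos_network,
    generate,
    ks_compare,
    null_cophos_distribution,
    PERMUTATION_SCHEMES,
)

dataset = generate(SyntheticConfig(
    n_kinases=4, substrates_per_kinase=10, n_background=40,
    n_states=12, within_kinase_correlation=0.7, seed=5,
))
observed = build_cophos_network(dataset.matrix).condensed()
print(f"observed distribution over {observed.size} pairs: "
      f"sd={np.std(observed, ddof=1):.3f}")

for scheme in PERMUTATION_SCHEMES:
    null = null_cophos_distribution(
        dataset.matrix, scheme, n_perm=20, seed=1
    )
    d, p = ks_compare(observed, null)
    print(f"{scheme:>12} null: sd={np.std(null, ddof=1):.3f}  "
          f"KS D={d:.3f}  p={p:.2e}")
print("-> every null is narrower than the observed distribution "
      "(more strongly correlated pairs than chance predicts)")
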