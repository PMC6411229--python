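"""Build a co-phosphorylation network and see why the robust estimator matters.

Generates a small synthetic phosphoproteomics matrix, corrupts one sample of
one profile with a large outlier, and compares the biweight midcorrelation
with Pearson before building the full network.
"""

import numpy as np

from cophos import (
    SyntheticConfig,
    biweight_midcorrelation,
    build_cophos_network,
    generate,
    pearson,
    summarize_distribution,
)

dataset = generate(SyntheticConfig(
    n_kinases=3, substrates_per_kinase=6, n_background=20,
    n_states=12, within_kinase_correlation=0.7, seed=2,
))
matrix = dataset.matrix

# two substrates of the same kinase: truly correlated profiles
a, b = matrix.values[0].copy(), matrix.values[1].copy()
print(f"clean pair:     bicor={biweight_midcorrelation(a, b):+.3f}  "
      f"pearson={pearson(a, b):+.3f}")
b[3] = 10.0  # one aberrant sample (10 sigma)
print(f"with outlier:   bicor={biweight_midcorrelation(a, b):+.3f}  "
      f"pearson={pearson(a, b):+.3f}")
print("-> the biweight midcorrelation downweights the aberrant state, "
      "Pearson is dragged toward zero\n")

network = build_cophos_network(matrix, method="bicor")
summary = summarize_distribution(network.condensed())
print(f"network over {network.n_sites} sites, "
      f"{network.n_sites * (network.n_sites - 1) // 2} pairs")
print(f"co-phosphorylation distribution: mean={summary.mean:+.3f} "
      f"sd={summary.sd:.3f} skew={summary.skewness:+.2f} "
      f"kurtosis={summary.kurtosis:.2f}")
print("-> the mean sits near zero; planted kinase structure puts extra "
      "mass in the positive tail")
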