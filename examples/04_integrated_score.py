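"""Integrate co-phosphorylation with a static kinase-site predictor.

The integrated score M(k,p) = h(k,p) + log2 x(k,p) adds the static
(sequence/interaction) evidence to the dynamic co-phosphorylation evidence.
Here profiles carry no kinase signal but the static predictor is fully
informative, so integration rescues the ranking - the two sources are
orthogonal.
"""

from cophos import SyntheticConfig, generate, loocv, topk_accuracy

dataset = generate(SyntheticConfig(
    within_kinase_correlation=0.0,        # profiles are pure noise
    static_score_informativeness=1.0,     # static predictor is clean
    seed=4,
))

h_only = loocv(dataset.matrix, dataset.annotation)
integrated = loocv(
    dataset.matrix, dataset.annotation,
    scorer="cophosk_plus", static=dataset.static_scores,
)

print(f"co-phosphorylation only: top-1 {topk_accuracy(h_only, 1):.2f} "
      f"(random baseline 0.10 over 10 kinases)")
print(f"integrated with static:  top-1 {topk_accuracy(integrated, 1):.2f}")
print("-> when the dynamic signal is absent, the static term carries the "
      "ranking; with both present the two add on the log scale")
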