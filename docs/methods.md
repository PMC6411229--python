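# Methods

## Model and assumptions

The package predicts kinase–substrate associations (KSAs) from the
second-order structure of a phosphosite × biological-state fold-change
matrix. The working assumption is that a kinase's activity varies across
states and imprints a shared temporal/conditional signature on its
substrates, so substrates of the same kinase are positively co-phosphorylated
more often than arbitrary site pairs. The method is deliberately agnostic
about mechanism: it consumes only pairwise profile correlations, never raw
spectra, peptide evidence, or kinetic parameters.

Assumptions worth keeping in mind:

- **Fold-change input.** The matrix is assumed already normalized to
  fold-changes against a reference (optionally log2-transformed at load);
  the package does not reconstruct reference pools from raw intensities.
- **Complete rows.** Sites with any missing state are dropped at load; no
  imputation is attempted, because imputed values would enter every pairwise
  correlation involving that site.
- **Annotation quality.** The prior (kinase → substrate sites) is treated
  as correct but incomplete. Kinases with fewer than `min_substrates = 2`
  annotated sites are excluded: a single substrate gives no shared-kinase
  pair and no within-kinase evidence.

## Co-phosphorylation estimator

The primary estimator is the biweight midcorrelation. Observations are
centred on the median; the scale is `9 · mad(x)` with the **unscaled**
median absolute deviation (no 1.4826 consistency factor); weights are Tukey
biweights `(1 − u²)² I(1 − |u| > 0)`, so states more than nine mad from the
median contribute exactly zero but still count (with zero contribution) in
the normalization. The normalization is the square root of the sum of
squared weighted deviations, which guarantees self-correlation 1 and
|c| ≤ 1. Pearson correlation is provided as an alternative (`method=
"pearson"`) for sensitivity analyses.

Numerical details: all three quadratic forms (numerator and the two norms)
go through the same dot-product kernel and the normalization is
`sqrt(s_x · s_y)`, so `c(x, x) == 1.0` exactly in IEEE arithmetic; results
are clamped to [−1, 1] against rounding overshoot. Profiles with zero mad
(bicor) or zero variance (Pearson) are *degenerate*: pairwise calls raise a
typed error identifying the offending vector, and network construction
excludes such sites with a logged list rather than mixing estimators —
falling back to Pearson for those sites only would bias the tail models
with a different estimator's distribution.

The network over `n` sites is computed by standardizing each profile once
and taking blockwise matrix products (`block_size` rows at a time bounds
memory); results are independent of the block size.

## Null models and adequacy

Three permutation schemes conserve the value multiset at different
granularities: per state column, per site row, and globally. Significance
of the observed co-phosphorylation distribution is assessed with the
two-sample Kolmogorov–Smirnov test against the pooled null over `n_perm`
permuted replicates (default 100; pooling matches treating all permuted
pairs as one null sample). scipy's `ks_2samp` with `method="auto"` supplies
the asymptotic p-value for large samples and the exact one for small
samples. A single user seed spawns one substream per replicate through
numpy `SeedSequence` spawning, so results are independent of evaluation
order and bit-reproducible.

The adequacy analysis subsamples `d` of the `m` states `n_rep` times and
reports the observed distribution's sd, the null sd, and the KS statistic
per `d`. For i.i.d. profiles the null sd tracks the closed form
`1/sqrt(d−1)`; with planted structure the KS separation grows with `d`.
This motivates the recorded warning when a matrix has fewer than 5 states:
correlations from 3–4 states are too noisy to separate signal from null.

## Tail models and scoring

`A` is the co-phosphorylation distribution over all network pairs; `S` is
the distribution over shared-kinase pairs, pooled across **all** kinases
(one global tail model). Per-kinase tails were considered and rejected:
most kinases have too few measured substrate pairs to estimate a tail, and
the pooled distribution is what the observed right-shift describes. Each
unordered pair contributes once to `S` no matter how many kinases it
shares.

Survival probabilities use the add-one estimator
`(#{v > c} + 1) / (n + 1)`, clamped to `[ε, 1]` with ε defaulting to the
estimator's natural floor `1/(n+1)` per distribution. This keeps the
likelihood ratio finite at both support extremes without ad-hoc
pseudocounts inside the ratio.

The score `h(k, p)` sums `log2[surv_S(c_pq) / surv_A(c_pq)]` over the
kinase's annotated substrates measured in the network, excluding `q = p`;
sites on the same protein as `p` are included (no exclusion rule is
justified by the model). A kinase with no measured substrate other than
`p` itself is **unscorable** for `p` — represented by a sentinel, never by
0, since 0 is a meaningful "equally likely under S and A" value. Ranking
is by descending score with ties broken on ascending kinase name, so output
is deterministic.

Score accumulation uses `math.fsum` (correctly rounded, order-independent)
and the log goes through libm's `log2` elementwise rather than numpy's SIMD
loop; both choices make scores bit-identical between the vectorized scorer
and any straightforward scalar implementation, at negligible cost for the
problem sizes involved.

## Integrated score

`M(k, p) = h(k, p) + log2 x(k, p)` combines the co-phosphorylation score
with a positive static kinase–site score. The static score is used raw — no
rescaling before the log — so users whose static tool reports on a
different scale should pre-normalize. Pairs missing from either side are
absent from the integrated table (coverage is the intersection); an
optional flag substitutes `h = 0` to reproduce a static-only fallback for
pairs the co-phosphorylation scorer cannot see. Integrated rankings are
invariant under per-site multiplicative rescaling of the static scores.

## Evaluation protocols

**LOOCV.** For every annotated (kinase, site) association with the site
measured: hide that single association (the kinase's other substrates and
the site's other annotations remain), refit the shared-kinase tail model
without it, re-score the site against all kinases, and record the hidden
(*target*) kinase's rank. Refitting per fold is the leak-free choice: the
hidden edge must not inform the tail estimate. Associations whose removal
leaves the target kinase without a measured substrate are reported as
unevaluable rather than silently skipped. Sites with several annotated
kinases contribute one record per annotation. Top-k accuracy uses strict
ranks after the deterministic tie-break.

**Reproducibility and consensus.** Across two prediction tables, the
reproducibility rates are the fraction of common sites with identical
top-1, and with one table's top-1 inside the other's top 5. Consensus over
several tables categorizes each site's top-1 against the annotation
(category 1: matches **any** annotated kinase; 2: annotated but
mismatched; 3: unannotated), stratifies sites by how many datasets predict
them, and reports precision `cat1/(cat1+cat2)` and, per support level, the
fraction of cross-dataset-identical calls that match the annotation.

## Synthetic data generator

A latent factor model: kinase `k` gets an activity factor `f_k ~ N(0, I_m)`
over the `m` states; a substrate's profile is
`sqrt(ρ)·s·f + sqrt(1−ρ)·ε` with noise `ε ~ N(0, I_m)`, sign `s = −1` for
negative-regulator sites (phosphatase-coupled or inhibitory sites that run
opposite to the kinase's activity), and for multi-kinase sites `f` is the
variance-preserving average `(f_k1 + f_k2)/sqrt(2)` of two factors.
Background sites are pure noise. Two plain substrates of one kinase then
have expected profile correlation exactly ρ and background pairs 0, giving
closed-form targets for tests. Static scores are
`x(k, p) = exp(info · z_true + (1 − info) · z_noise)` with `z_true = 2` for
true pairs, 0 otherwise, and `z_noise ~ N(0, 1)`; informativeness 1 yields
a cleanly separating static predictor, 0 pure positive noise. The
separation constant 2 puts a fully informative static predictor roughly
2.9 bits above noise per pair after the log2 — strong but not infinite
evidence.

Defaults (m = 20 states, 10 kinases × 20 substrates, 200 background sites,
ρ = 0.7, no multi-kinase or negative-regulator sites, informativeness 0.5)
describe a mid-sized quantitative design with a strongly coordinated kinase
program: large enough that tail models are estimated from ~1,900 shared
pairs, small enough that the full LOOCV (200 folds with per-fold tail
refits) runs in seconds.

What the generator does **not** emulate: missing values and the mechanisms
behind them, iTRAQ/TMT ratio compression, peptide-level ambiguity,
incomplete or erroneous annotations (incompleteness can be emulated with
`annotation_subsample`), and correlated backgrounds from shared pathways.
Passing tests on this generator therefore demonstrate that the machinery
recovers planted second-order structure — not that real annotation
databases or real acquisition noise behave this benignly.

## Known limitations and open choices

- Duplicate site rows (the same site observed on several phosphopeptides)
  are aggregated by element-wise mean before analysis; the choice is
  symmetric and order-independent but is a convention, not a derivation.
- The pooled `S` treats all kinases as exchangeable; kinases whose
  substrates genuinely anti-correlate (inhibitory programs) are penalized
  by the right-shifted pooled tail.
- Empirical step-function tails make the likelihood ratio only
  approximately monotone in `c`; with realistic sample sizes the violations
  are confined to neighbouring order statistics.
- With very few shared-kinase pairs the `S` tail saturates and `h` degrades
  toward counting measured substrates; tests construct such a case
  deliberately. At least a few hundred shared pairs are advisable.
- Scoring is per-site independent (Naive Bayes): no joint assignment across
  sites, no partial correlation to remove indirect network edges.
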