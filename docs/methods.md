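# Methods

This note documents the models, numerical choices and known limitations of
`sludgecast`, module by module.

## Predictive model

Each community feature gets its own regressor: a single-hidden-layer
network with `hidden = 2n + 1` relu units over `n` input factors and one
sigmoid output. Targets are min–max scaled to (0, 1) **on the data the
model is fitted to** and inverse-scaled for reporting, which makes the
bounded sigmoid output coherent with the target range; a constant target
short-circuits to a degenerate model that predicts the constant. The
optimiser is Adam with β = (0.9, 0.999), ε = 1e−8, learning rate 1e−5,
batch size 256, dropout 0 and weight decay 0.01 applied as an L2 term added
to the gradient (coupled decay). "Iterations" are optimiser steps over
shuffled mini-batches (an epoch pointer reshuffles when exhausted), not
epochs; the protocol default is 10,000 steps.

*Initialisation.* The pipeline always feeds factors on the 1–100 normalised
scale, so input–hidden weights are He-normal draws divided by the expected
input magnitude (50); hidden–output weights are Glorot-scaled. This keeps
hidden pre-activations and the output logit O(1) at the start, so the
sigmoid begins in its active range. With Adam the scale of later updates is
set by the learning rate, not by the initial weight scale.

*Evaluation.* `r2_1to1 = 1 − Σ(o−p)²/Σ(o−ō)²` judges predictions against
the identity line and is reported unclipped (negative values mean the
observed mean would beat the model — averages over seeds use the raw
values). `r2_bestfit` is the squared Pearson correlation and is NaN when
either side is constant. The repeated protocol runs seeds 0..19 by default;
each seed drives the 80/20 split (train size = round(0.8·n)), the weight
initialisation and the batch order. Fourfold cross-validation inside the
training split is available (`run_cv=True`) for monitoring; the reported
model is always refit on the full training split. CV is off by default in
the repeated protocol because it multiplies training cost fivefold without
changing the held-out metric.

## Garson importance

For input i and hidden unit j, `c_ij = |w_ij|·|v_j|`; contributions are
normalised within each hidden unit (`r_ij = c_ij / Σ_k c_kj`), summed over
units and normalised over inputs, so profiles sum to 1. Biases are
excluded. The measure is invariant to reciprocal rescaling of any hidden
unit's fan-in/fan-out and to sign flips. Factor profiles across many
target models are clustered with k-means (k = 3, 10 restarts, seeded) and
ranked by median (or mean) importance with lexicographic tie-breaks.
Distribution-shape analysis uses bias-corrected sample skewness and
**excess** kurtosis (normal → 0); zero-variance factors get NaN and drop
out of the OLS fits.

## Neutral community model

`expected_frequency(p) = 1 − F_Beta(d; N_T·m·p, N_T·m·(1−p))`. The single
parameter m is fitted by least squares over taxa with mean relative
abundance strictly inside (0, 1) (at least 10 required): a 120-point
log-spaced scan over (1e−6, 1] brackets the optimum, then bounded scalar
minimisation refines it to 1e−6. Fit R² is 1 − SSE/SST about the mean
observed frequency. The 95% band treats the predicted frequency as a
binomial proportion over the observed number of samples and uses Wilson
score intervals (Wald intervals collapse at frequencies near 0/1). The
band is closed: a frequency exactly on a bound is neutral. Counts are
flattened to 2,000 reads per sample before fitting so that m̂ is comparable
across subcommunities; per-partition refits reuse each partition's
original (p, frequency) pairs without renormalising abundances.

*Detection limit.* Occurrence is scored from sampled reads, so detection
of a taxon at latent abundance x is the event "≥ 1 read in N_T draws",
with probability 1 − (1−x)^{N_T} — a smoothed threshold. For the steeply
decreasing abundance densities of the rare taxa that dominate the fit,
matching tail masses of 1 − e^{−N_T·x} against a sharp indicator under a
locally log-uniform density gives an equivalent threshold of exactly
e^{−γ}/N_T (γ the Euler–Mascheroni constant, ≈ 0.5615/N_T). That value is
the default d. The classic one-read convention d = 1/N_T remains available
by passing it explicitly; on data simulated from the model itself it
overestimates m by roughly 25%, which is worth keeping in mind when
comparing absolute m̂ values across studies that use it.

## Preprocessing

* *Binary encoding*: observed tokens of a flagged column are sorted and
  mapped to 0, 1 (label-encoder semantics); >2 tokens is an error, a
  single token encodes to the constant 0.
* *Imputation*: "two nearest neighbours" is read as k = 2, unweighted
  mean; the distance between two samples is the root-mean-square
  difference over the columns observed in both (normalising by the shared
  column count keeps samples with different missingness comparable).
  Ties are broken by sample order, so the result is deterministic.
* *Normalisation*: per column `x' = 1 + 99·(x − min)/(max − min)`, with
  endpoints pinned exactly and constant columns mapped to the midpoint
  50.5. Fitting on the full table is the default; passing training-only
  min/max gives a leakage-free variant. Normalisation is idempotent on
  already-normalised non-constant columns.
* *Duplicate removal*: the fence is Q1 − 3·IQR of all pairwise community
  distances, clamped at 0 because that quantity is negative for typical
  distance distributions — so only samples with identical metadata rows
  *and* (near-)identical communities merge. Merging is transitive within a
  duplicate group and keeps the lexicographically smallest id, making the
  result independent of row order. Equality of metadata rows is evaluated
  after encoding/imputation; the raw (unnormalised) weighted UniFrac is
  the default distance.
* *Rarefaction* draws a multivariate hypergeometric sample (without
  replacement) per row; rows already at the target depth pass through
  unchanged, short rows are dropped (or raise). *Filtering* removes
  whole-table singletons first, then taxa present in fewer than
  ⌈f·n_samples⌉ samples — "at least 10%" is read inclusively.

## Diversity

Shannon is in natural log over taxa present in a sample; Pielou is
H/ln S and reported missing for S = 1; Faith's PD includes the path to the
root (the QIIME convention). Weighted UniFrac and Faith's PD are computed
by scikit-bio; the raw UniFrac form is Σ_b l_b·|A_b − B_b| and the
normalised form divides by Σ_b l_b·(A_b + B_b). Bray–Curtis similarity is
1 minus the usual dissimilarity on relative abundances.

## Community analysis

Core classification follows three rules evaluated independently: overall
abundant = the ⌈0.01·n⌉ taxa of highest mean relative abundance (ties by
id); ubiquitous = occurrence frequency **strictly** above 0.2; frequently
abundant = member of the per-sample "top 80% of reads" prefix (smallest
descending-abundance prefix whose cumulative share reaches 0.8, crossing
taxon included, ties by id) in at least 10% of samples. The Mantel test
correlates upper triangles with Pearson's r and permutes rows/columns of
the second matrix jointly; p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm),
one-sided, 999 permutations by default. CV is sd/mean (n−1 sd) of relative
abundance across all samples, zeros included. The abundance/frequency
grouping thresholds (high ≥ 1e−3 / low < 1e−4 mean relative abundance;
frequency high ≥ 0.5 / low < 0.2) are package defaults, configurable, not
fixed constants of the field.

## Synthetic data

The generator inverts the analysis assumptions: metacommunity abundances
are normalised lognormal(0, σ = 2) draws — σ = 2 gives the heavy dominance
of low-abundance taxa typical of amplicon surveys; each sample's latent
relative abundances are independent Beta(N_T·m·p_i, N_T·m·(1−p_i)) draws,
renormalised, and integer counts come from a single multinomial draw at
the stated depth (read sampling is part of the emulation, which is why the
fit's detection limit matters, above). Environmental responses multiply a
driven taxon's expected abundance by a monotone link of the standardised
driver — `linear`: max(1 + β·z, 0.05); `logistic`: 2·sigmoid(β·z), both
mean ≈ 1 under a symmetric driver — then rows are renormalised and counts
redrawn at the original depth. Binary factors are "yes"/"no" Bernoulli(0.5)
tokens so the encoder is exercised; missingness is completely at random
(a mechanism choice, since survey metadata rarely documents its own
missingness). Trees are random-join topologies with exponential branch
lengths.

What the generator does **not** emulate: spatial/climatic covariance among
factors, taxon–taxon interactions, phylogenetic signal in environmental
responses, compositional correlations beyond the shared multinomial, or
sequencing artefacts (chimeras, taxonomy errors). Passing recovery tests
therefore shows the estimators are correct *under the stated model*, not
that real surveys satisfy that model.

## Problem sizes and determinism

Tests and examples run at deliberately modest sizes (60–500 samples,
60–300 taxa, 2,000 training steps, 5–20 seeds) — large enough for the
recovery properties to hold with margin, small enough to iterate on.
All randomness flows through `numpy.random.default_rng` seeded per call;
the pipeline derives every stage seed from one master seed and reruns are
byte-identical.

## Known limitations

* The trainer is plain numpy on one core; it is sized for shallow networks
  at survey scale (hundreds of samples), not for architecture search.
* The per-partition m refit conditions on a partition defined by the joint
  fit's own band, so its absolute values inherit selection effects; only
  the above > below ordering is treated as meaningful.
* `intra_inter_similarity` compares full predicted subcommunities built
  from independently trained per-taxon models; predictions are clipped to
  a small positive floor before renormalisation, which slightly smooths
  predicted communities.
* The k = 2 imputation is exact to its definition but quadratic in sample
  count; for surveys beyond ~10⁴ samples a tree-based neighbour search
  would be the natural replacement.
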