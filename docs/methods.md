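# Methods

## The problem

A gene "expressed in only one condition" has zero counts in all replicates
of one group and positive counts in the other. Because the natural
estimate of its dispersion (or of its fold change) lies on the boundary of
the parameter space, such genes are a stress test for count-based DE
models. Benchmarks in this area have used the signal-to-noise ratio (S/N)
of the expressed condition as a truth surrogate; this package implements
both that S/N-percentile benchmark and a simulation with hard ground
truth, so the two styles of evaluation can be compared on equal footing.

## Count model and simulator (`simdata`)

Counts are negative binomial: a gene with mean μ (at a reference depth of
2×10⁷ reads) and dispersion φ has variance μ(1 + μφ); φ = 0 is the Poisson
limit, drawn directly from a Poisson to avoid the degenerate gamma. For
sample j with library size L_j the mean is μ·L_j/2×10⁷. Library sizes are
drawn uniformly on [16, 39] million, the depth range of the bulk
experiment the simulation emulates; with the full 30,000 features the
realized column sums land in the same range.

**Parameter pool.** (μ, φ) pairs are sampled jointly from a pool. The
default parametric surrogate draws log₁₀ μ from Normal(2.0, 0.8) truncated
to μ ∈ [5, 10⁵] (≈4 orders of magnitude; empirical estimate pools come
from expression-filtered genes, so very small means do not occur) and sets
φ = (2/μ + 0.05)·ε with lognormal noise ε (σ = 0.4). This reproduces the
two robust features of real estimate tables: a decreasing dispersion-mean
trend and substantial gene-level scatter around it. A loader accepts
two-column (mean, dispersion) tables so that empirical pools can be used
instead; rows with invalid values or φ outside a configurable filter
(default [0, 5]) are dropped.

**Zero injection.** Exactly round(f·n) features (default f = 5%) are
selected without replacement with probability ∝ rank(mean expression,
lowest first)^(−e); the default exponent e = 1 concentrates the injected
genes at low expression, matching the empirical observation that
one-condition genes occur mostly among weakly expressed genes (the
`empirical_zero_profile` table quantifies this on any dataset). For each
selected feature a fair coin picks the condition to zero; a draw whose
complementary condition is all zero is rejected and redrawn, so every true
gene is genuinely expressed in exactly one condition. e = 0 recovers
uniform selection; the exact-count rule makes the truth-set size
deterministic.

All randomness flows from one integer seed through named substreams
(`seed`, stage name, replicate index), so each stage is reproducible in
isolation and repeated runs are bit-identical.

## Normalization and scales (`normtransform`)

TMM factors follow the published trimmed-mean-of-M-values recipe: the
reference sample is the one whose upper-quartile CPM is closest to the
mean upper-quartile; M (log₂ ratio) and A (average log₂ abundance) are
computed over genes positive in both libraries; the top/bottom 30% by M
and 5% by A are trimmed (ranks tie-broken by gene index for determinism);
the factor is 2^(weighted mean of M) with inverse-asymptotic-variance
weights, and factors are rescaled to geometric mean 1. CPM uses effective
library sizes (library × factor) with prior count 0, so all-zero genes map
to exactly 0; log-CPM is log₂(CPM + 0.5).

The variance-stabilizing transform is the generalized log
glog₂(x; c) = log₂((x + √(x² + c²))/2) applied to CPM. Under the working
model sd ≈ √(a + b·mean²), the choice c = √(a/b) flattens the mean-sd
trend. The calibration fits log(sd) against ½·log(a + b·mean²) by soft-L1
robust least squares (positivity enforced by an exponential
parameterization): fitting on the log scale lets the low-expression
plateau pin a and the proportional regime pin b; fitting sd² linearly
instead lets a handful of high-expression genes dominate and inflates c by
an order of magnitude. A degenerate fit falls back to c = 1 with a logged
warning. This is a deliberate simplification of full variance-stabilizing
calibration models: the benchmark needs *a* variance-stabilized scale, not
a particular package's output.

## Signal-to-noise (`snr`)

Empirical S/N is mean/sd with the n−1 (sample) standard deviation — the
convention verified against the printed worked examples (e.g., CPM
replicates 237.1/232.5/226.0/227.5 give 230.775/5.050 ≈ 45.70; an
n-denominator gives 52.8, incompatible with the printed 45.75). A gene
with zero variance and non-zero mean gets a +∞ sentinel, ranked above all
finite values in percentile labeling (it is a maximally consistent
signal); the all-zero case returns 0. `snr_table` restricts to genes whose
raw counts are all-zero in exactly one condition and computes S/N on the
other condition's values on whatever scale the input matrix carries.

The theoretical NB S/N is 1/√(1/μ + φ): increasing in μ, decreasing in φ,
bounded by √μ and φ^(−1/2), and saturating at φ^(−1/2) for large μ. This
is the formal statement of why linear-scale S/N is mostly a dispersion
readout for well-expressed genes.

## Surrogate DE tests (`de_methods`)

The benchmarked method families are represented by two transparent
surrogates rather than re-implementations of specific packages (an adapter
ingests external result tables so originals can be evaluated too).

**Dispersion estimation.** Per gene, on counts rescaled to the mean
library size: φ̂ = max(0, (pooled within-group variance − mean)/mean²).
The trend is a running median (window 101, ends extended) over genes
ordered by mean; genes all-zero in one condition do not inform the trend
(their degenerate group contributes zero variance with full df, biasing it
down) and instead take the interpolated trend value at their mean. The
working estimate is the convex combination
φ* = w·trend + (1−w)·φ̂ with w = 0.7.

**Exact NB test.** Effective library sizes are equalized (counts scaled to
their geometric mean, rounded half-up), making replicates approximately
iid so group sums are NB with shape n_g/φ. Conditional on the total
s = s_A + s_B, the two-sided P value sums the probabilities of all splits
as or less likely than the observed one (ties included, with a 10⁻¹²
relative tolerance); P = 1 when s = 0. The φ = 0 case reduces to the
conditional binomial. An exhaustive-enumeration oracle checks the
implementation to 10⁻¹⁰.

**Moderated t.** On log-CPM: (i) lowess (span 0.5) of √(residual sd) on
average log₂ count; (ii) per-observation weights = predicted variance⁻¹ at
the fitted log-count; (iii) weighted two-group fit per gene; (iv) the
variance prior (d₀, s₀²) is moment-matched on log s² — the excess of
var(log s²) over trigamma(d/2) identifies trigamma(d₀/2), with d₀ = ∞
(point prior) when the spread is at or below the sampling floor; (v)
moderated t with d₀ + d degrees of freedom. FDR is Benjamini-Hochberg in
both tests.

**Dispersion-shift diagnostic.** For each injected gene, φ̂ from the
single non-zero condition of the modified data is paired with φ̂ from the
unmodified data (simulation) or from expression-matched expressed genes
(real data). In simulation the two medians agree within a factor well
below 2 — zeroing one condition does not collapse dispersion estimates
toward Poisson.

## Evaluation (`evaluation`)

Percentile labels rank genes by S/N descending (∞ first, ties broken by
gene ID): top ceil(0.40·n) "true", bottom floor(0.20·n) "false", gray zone
excluded from ROC construction. The caption convention (top 40% true) is
the default; both fractions are arguments. ROC curves group tied scores,
close at (0,0)/(1,1) and use trapezoid AUC (equal to pairwise concordance,
cross-checked against a brute-force oracle). Achieved FDR at a nominal
cutoff q is FP/max(1, FP+TP) among genes with BH-FDR ≤ q, defined as 0 and
"controlled" when nothing is called. Replicates are aggregated by pooling
gene-level results before curve construction (per-replicate curves are
also emitted). Per-scale percentile labels are recomputed on each scale by
default; a config switch can fix them on linear CPM.

## Problem sizes and what the tests show

The package's own checks run the benchmark at 5,000 features × 3
replicates (5 vs 5, 5% injected) and null calibration at 5,000 features —
sizes at which every reported statistic is stable to the second decimal
while the whole suite stays fast; the full-scale 30,000-feature design is
the config default for real use. Under these conditions both surrogates
separate injected from null genes essentially perfectly (AUC ≈ 0.999) and
the moderated t controls achieved FDR at all cutoffs. The exact NB test is
mildly anti-conservative (achieved FDR ≈ 0.12 at nominal 0.05): its
plug-in dispersion — moment estimate shrunk 70% toward a running-median
trend — cannot track gene-level dispersion scatter at 5 replicates per
group, and treating the estimate as known inflates the null tail. With a
scatter-free pool the same pipeline controls at ≈ 0.09, and with oracle
dispersions at ≈ 0.07, so the inflation is attributable to dispersion
estimation, not to the conditional test itself. Likelihood-based
empirical-Bayes estimators (as in production count-model packages) close
most of this gap; implementing one is out of scope for a transparent
surrogate.

The simulator emulates bulk RNA-seq two-group designs only: no
multi-factor designs, no fold-change DE other than the zeroing mechanism,
no single-cell dropout. Passing tests therefore demonstrate behavior under
NB sampling with a realistic mean-dispersion pool — not robustness to
outliers, batch effects or compositional artifacts of real data.

## Numerical choices

- NB draws via gamma-Poisson mixture; φ = 0 short-circuits to Poisson.
- Exact-test tie tolerance 10⁻¹² (log scale); P clamped to
  [P(observed), 1].
- Trigamma inversion by Newton iteration to 10⁻¹⁰ relative tolerance.
- Half-up rounding in library equalization (platform-independent).
- Deterministic tie-breaks everywhere a rank is taken: (value, gene
  index) in TMM trimming, (S/N, gene ID) in percentile labels.
- Geometric-mean factor normalization exact to 10⁻¹².
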