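# Methods

## Model

A gene module is concordant when its expression profiles are mutually
linearly correlated. Formally, for G ∈ ℝⁿˣᴺ (n ≥ 2 genes in rows, N ≥ 3
samples in columns), perfect pairwise correlation |ρ(gᵢ, gⱼ)| = 1 for all
pairs means every row is αᵢ·g₁ + βᵢ for scalars αᵢ ≠ 0, βᵢ. G then
decomposes as a rank-1 term in g₁ plus a rank-1 term in the all-ones
vector, so rank(G) ≤ 2, and the ratio

    R12 = (S11² + S22²) / ‖G‖²_F

(Sₖₖ the singular values of the raw G) equals 1. R12 is hard to threshold
in practice: it is computed on raw values, so background offsets and a few
highly expressed genes dominate the L²-based SVD — a pure-noise block
typically scores ~0.8. The package therefore centers each row to mean 0
and rescales it to unit norm, giving Ĝ. Two facts make Ĝ the right
object:

1. ĜĜᵀ is exactly the gene–gene Pearson correlation matrix (the inner
   product of centered, unit-norm rows is the correlation).
2. Under perfect pairwise correlation every row of Ĝ is ±ĝ₁, so
   rank(Ĝ) = 1 and, because each row has unit norm, ‖Ĝ‖²_F = n and
   Ŝ11² = n.

The **centralized concordance index** is

    CCI = Ŝ11² / n = λ_max(Pearson matrix) / n ∈ [1/n, 1].

The lower bound holds because the correlation matrix has unit trace n and
its largest eigenvalue is at least the average. CCI is invariant to
per-row affine maps (λ·gᵢ + ε, λ ≠ 0), to sign flips of any subset of rows
(anti-correlation is concordance), and to a common permutation of the
samples; all three are verified as property tests.

The companion **density** baseline is the mean of |ρ(gᵢ, gⱼ)| over the
n(n−1)/2 gene pairs — the usual weighted-network module quality score,
implemented with plain |ρ| weights (no soft-thresholding power, which
would be a different metric).

## Significance

Two nulls, both with M = 1000 draws by default:

- **Within-row permutation**: each row's entries are shuffled
  independently, destroying all cross-gene correlation while preserving
  each gene's marginal distribution. p_permute = #(CCI_p ≥ CCI)/M with no
  pseudocount, so p = 0 is reportable; outputs carry the smallest
  resolvable p = 1/M so a zero is read correctly. Permutation is applied
  to the raw module rows and the full transform re-applied; permuting
  already-transformed rows gives the identical null because centering and
  standardization commute with within-row permutation (property-tested).
- **Random gene sets**: M sets of n genes drawn uniformly without
  replacement from the whole expression matrix (fresh draw each time; sets
  may overlap each other or the tested module). The observed CCI is
  reported as z = (CCI − mean)/sd, sd the sample standard deviation
  (ddof = 1). The z-scale is preferred over a percentile because the
  random-set CCI distribution is bell-shaped, M draws cannot resolve
  extreme percentiles honestly, and z-scores compare across conditions.
  Genes constant across samples are excluded from the sampling frame (a
  constant row has no correlation structure and cannot be standardized);
  a null whose draws are all the same gene set (n = genome size) has zero
  spread and the z-score is refused rather than returned as ±inf.

With m modules the significance threshold is τ = Φ⁻¹(1 − 0.05/m), the
Bonferroni-compensated one-tail quantile. The screen scores each module in
both conditions against a null from the *same* condition's matrix and
classifies: significant in A only → `specific_to_a`, in B only →
`specific_to_b`, both → `concordant_both`, neither →
`concordant_neither`. Significance is z ≥ τ — the upper tail, consistent
with how τ is constructed (a larger-than-random CCI is the signal).
Null draws are seeded by (master seed, module size) only, so same-size
modules share one cached null per condition (statistically identical,
M-fold cheaper) and swapping the two input matrices swaps the two
specific verdicts exactly.

## Synthetic data generator

`make_correlated_matrix(n, N, rng)` draws a base profile U(0,1)^N and
forms the other n − 1 rows as α·base + β with α, β ~ U(0,1) — by
construction every pairwise |ρ| is 1, giving the rank-2/rank-1 ideal the
indices are derived from. Defaults across the studies are n = 50 genes,
N = 100 samples. What the generator emulates is the *correlation
geometry* of a co-expressed module, not the marginal distribution of real
expression data (microarray intensities are log-scale, heteroskedastic,
and batch-structured); passing tests show the statistic behaves as the
linear-algebra analysis predicts, not that any particular biological
module will score high.

Numerical choice: α values below 0.01 are redrawn. A row with a vanishing
scale factor is numerically constant; after standardization its direction
is set by float-rounding error of relative size ~eps/α, which for
α ≲ 5×10⁻³ exceeds the numerical-rank tolerance and makes a mathematically
rank-1 Ĝ test as rank 2. The redraw removes under 1% of the U(0,1) mass
and leaves every statistic's distribution visibly unchanged while keeping
the generator's defining property (rank(Ĝ) = 1) true in floating point.
Shifts β are annihilated by centering and keep the full U(0,1) law.

The two-condition study builder plants correlated blocks (with Gaussian
noise, default σ = 0.05) in one or both of two independently sampled
genomes of i.i.d. U(0,1) background genes — 20 modules of 20 genes, 200
background genes, 40 samples per condition by default, sizes chosen to
give near-certain power for the planted effects while keeping the
end-to-end screen fast.

## Benchmark studies

- **Noise sweep**: for each σ in {0.01, 0.02, 0.05, 0.07, 0.1, 0.15, 0.2,
  0.3, 0.5, 1} and each repetition, a fresh 50 × 100 module is generated,
  i.i.d. N(0, σ²) noise added, and CCI recorded together with
  R_F = ‖Ĝ_noisy − Ĝ‖_F/‖Ĝ‖_F (both in transformed form; two antipodal
  matrices give R_F = 2). The study default is 1000 repetitions per level;
  the shipped tests and examples use 100, which already pins the mean CCI
  to ±0.005.
- **Robustness vs density**: at σ ∈ {0.05, 0.2}, either k independently
  generated U(0,1)^N outlier rows are appended (k = 0, 5, …, 50) or a
  second, independently generated correlated block of size k is stacked on
  (interference), 100 repetitions per setting. Within a repetition the
  same module and pool are reused across k and both metrics are normalized
  by that repetition's k = 0 value, so spread at each level measures
  metric stability. Expected behavior, asserted in the acceptance tests:
  the interquartile range of normalized CCI stays at or below density's at
  every outlier count, and in the interference scenario the mean
  normalized density's per-step change falls below ε = 0.02 once the
  interfering block exceeds half the module size (pair-count bookkeeping:
  cross-pair and within-pair counts nearly balance) while mean CCI is
  still strictly decreasing — CCI keeps signalling that the merged set is
  not one concordant module.

## Degenerate inputs and numerical conventions

- Constant (zero-variance) genes cannot be standardized: operations raise
  a `DegenerateGeneError` naming the gene, with an opt-in
  `on_constant="drop"` mode that removes them, warns, and reports the
  reduced n.
- Numerical rank counts singular values above max(n, N)·eps·S11 (the
  standard convention); the exact-arithmetic statements "rank 2" / "rank
  1" are tested through it.
- R12 of an all-zero matrix, and any z-score against a null with spread
  ≤ 10⁻¹² (on a statistic of order 1), are refused as undefined rather
  than returned as NaN/±inf.
- Module gene lists are resolved against each matrix independently;
  missing genes are dropped with a warning and fewer than two surviving
  genes is an error. Duplicate gene ids in input tables are an error by
  default (probe-to-gene collapsing is out of scope) with an opt-in
  first-occurrence policy. No implicit log-transform is applied; the CLI
  offers `--log2` (log2(x + 1)) off by default.
- All randomness flows from one user-visible seed through
  `numpy.random.Generator`; reports record it, and CLI data rows are
  byte-identical across reruns with the same seed.

## Limitations

- CCI measures *one-dimensional* concordance. A gene set containing two
  internally tight but mutually independent modules scores roughly the
  size-weighted λ_max of the larger block over n — correctly below 1, but
  CCI cannot say *why*; inspect the singular-value spectrum (returned in
  `ConcordanceResult`) to distinguish "noisy single module" from "two
  merged modules".
- The random-gene-set z-score inherits the composition of the supplied
  matrix: if the genome is rich in correlated structure the null mean
  rises and z falls. That is intended (significance is relative to the
  dataset) but means z values are not comparable across datasets with
  very different correlation backgrounds.
- The normal approximation behind the one-tail p of the z-score is an
  approximation to a bounded statistic's distribution; for tiny genomes
  or n close to the genome size it degrades, and the package refuses the
  fully degenerate case only.
- Module discovery (lmQCM, WGCNA), probe-to-gene mapping, normalization
  and batch correction are out of scope; modules and matrices are
  consumed as given.
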