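# Methods

## Model

A single-cell (or spatial-bin) experiment is a matrix of UMI counts
N_{Z,i} for genes Z and cells i, with per-cell depths N_i = Σ_Z N_{Z,i}.
The analyzed quantity is always the relative expression
n_{Z,i} = N_{Z,i}/N_i; cells with N_i = 0 must be removed before any
computation (the package raises rather than silently dropping them).

Each cell is treated as a cluster of a cluster-randomized experiment:
N_i is the cluster size and n_{Z,i} the cluster outcome rate.  The mean
expression of a group of cells is the weighted average
n̄_Z = Σ_i w_{Z,i} n_{Z,i} with

    w_{Z,i} ∝ N_i / (1 + ρ_Z (N_i − 1)),       Σ_i w_{Z,i} = 1,

where ρ_Z ∈ [0, 1] is the gene's intracluster correlation coefficient
(ICC).  The two limits are the two assumptions implicit in common
pipelines: ρ_Z = 0 gives aggregate-count weights w ∝ N_i (pure counting
noise; pseudo-bulk), ρ_Z = 1 gives equal weights 1/N (pure biological
variance; unweighted averaging).  Real genes sit in between, which the
weight distribution coefficient WDC_Z = Var(w_{Z,i})/Var(w_AC) makes
visible (0 at equal weights, 1 at aggregate-count weights; both variances
are population variances so the ratio is convention-free; WDC > 1 is
mathematically possible and is not clipped).

### ICC estimation

ρ_Z is estimated per gene and per cell group with the one-way ANOVA
(Fleiss–Donner) moment estimator for clustered binary outcomes, the
standard estimator in cluster-randomized trials: with k cells, M = Σ N_i,
p_i = n_{Z,i}, p̄ = ΣN_{Z,i}/M,

    MSB = Σ N_i (p_i − p̄)² / (k − 1)
    MSW = Σ N_i p_i (1 − p_i) / (M − k)
    n0  = (M − ΣN_i²/M) / (k − 1)
    ρ̂  = (MSB − MSW) / (MSB + (n0 − 1) MSW),

computed in a single pass (no weight/ICC iteration), clamped to [0, 1];
an exactly zero denominator (constant gene) yields ρ̂ = 0, i.e. weights
∝ N_i, matching the meaning of the ρ = 0 limit.  No shrinkage or
empirical-Bayes moderation across genes is applied — the method is
deliberately moment-based.  Parameter recovery is verified in the test
suite on beta-binomial clusters (k = 1000, depths log-uniform in
[100, 10000]): the mean estimate over 200 genes lands within ±0.02 of
planted ρ ∈ {0, 0.1, 0.3}.

ρ is estimated separately within each group being compared (weights
describe measurement precision inside each sample being averaged), not
pooled across groups.

### Variance of the weighted mean

The reliability-weights unbiased form with the Kish effective sample size
n_eff = 1/Σw²:

    Var(n̄_Z) = [Σ_i w_i (n_i − n̄)²] · Σw² / (1 − Σw²).

At equal weights this is exactly s²/n.  For homoscedastic values with
arbitrary fixed weights the estimator is unbiased (verified against the
empirical variance of the mean over 2000 replicates in the tests).  When
the weights are inverse-variance weights under heteroscedastic
transcript-sampling noise it overestimates the true variance by the
factor (k − 1)/(n_eff − 1) ≥ 1 — the weighted test is therefore
conservative, increasingly so as the depth spread grows.  This is a
property, not a defect: it is precisely the slack that absorbs
cell-sampling bias and keeps the null benchmarks at zero false positives,
and it vanishes in the equal-depth regime where the test reduces exactly
to Welch's t.

### Tests

* **Weighted t-test** — t = (n̄_A − n̄_B)/√(V_A + V_B), two-tailed,
  unequal variances, Welch–Satterthwaite degrees of freedom with
  (n_eff − 1) as the per-group denominators.  If both variances are zero:
  p = 1 for equal means, p = 0 (degenerate, flagged by ±inf t) otherwise.
* **χ² aggregate test** — Pearson χ², df 1, no continuity correction, on
  [[X_A, T_A−X_A], [X_B, T_B−X_B]] where X = Σ counts of the gene and
  T = Σ depths in the group.  Aggregate totals in the intended use are
  10⁵–10⁷, where the correction is negligible.  A gene absent from both
  groups gets NaN (written as "NA").  The test sees only
  transcript-sampling variance, so it is only ever used to *veto* weighted
  t-test findings.
* **Combination rules** — `proxy`: report the χ² p-value instead of the
  weighted-t one when the former but not the latter exceeds the
  significance floor (default 0.05); `max`: the larger of the two.  An
  undefined χ² p falls back to the weighted-t p.
* **Comparators** (for benchmarking only) — Welch t on relative counts;
  Welch t on log(1 + 10⁴·n) (natural log, scale 10,000 — the Seurat
  convention); two-sided Wilcoxon rank-sum with tie-corrected normal
  approximation and no continuity correction (group sizes in intended use
  are ≥ 50; for small tie-free inputs the exact null distribution is used
  so that textbook enumeration values are reproduced).

### Multi-sample (replicate) mode

Each sample s is summarized by per-gene n̄_{Z,s} and Var(n̄_{Z,s}) using
the machinery above.  Condition means use inverse-variance sample weights
W_s ∝ 1/Var(n̄_{Z,s}) (normalized within condition); the variance of a
condition mean uses the same reliability-weights form applied at the
sample level, and the across-condition test is Welch-type with
per-condition df from the Kish effective number of samples (conservative
under unequal weights).  A zero per-gene sample variance is floored at
10⁻³ × the smallest positive variance among that condition's samples for
that gene, keeping weights finite while preserving their ordering.
Aggregate-count comparators (unweighted and inverse-binomial-variance
weighted t on per-sample ΣX/ΣN) are included; negative-binomial
pseudo-bulk models are out of scope by design.

### Spatial mode

Bins carry few transcripts and mix overlapping cells, so ρ_Z is forced to
0 (aggregate-count weights) and the conservative `max` combination is the
default; results are interpreted as differences in aggregated expression.
Bin QC mirrors a growth-plate selection: strictly more than 20 detected
features per bin, strictly more than 100 counts outside the configured
structural genes, mitochondrial fraction (genes matched by
case-insensitive id prefix, default "mt-") inside an inclusive band
[0.1%, 5%], marker fractions strictly above their thresholds.  Genes are
additionally required to be detected in ≥ 10% of bins in *each* group
(per-group, not pooled — conservative and symmetric).  Spatial
coordinates are ignored; bin selections arrive as barcode lists.
Imaging-based assays (Xenium-like) are out of scope: their capped optical
counts break relative-count normalization.

## Simulation machinery

* **UMI thinning** (`subsample_umis`) — `binomial` mode keeps every UMI
  independently with probability p (each entry → Binomial(N, p));
  `per_gene_exact` mode keeps exactly round(p · gene total) UMIs per gene,
  multivariate-hypergeometric across cells.  The exact mode preserves each
  gene's aggregate ratio, which makes the thinned matrix a strict null for
  the aggregate χ² test; per-entry binomial thinning leaves a residual
  aggregate signal of ~3/7 of the χ² null variance that produces a few
  tenths of a percent of χ² calls at p < 0.05.  The null benchmark
  therefore uses exact mode; binomial mode is the generic
  reduced-sequencing-depth operation.
* **Uniform noise** (`noise_fn`) — fn(α, N) = round(U · A(α, N)) with U
  uniform on [−1, 1] and amplitude A = sf·√N,
  sf(α, N) = √(3α) − (√(3α) − 1)/(1 + 0.1 N).  This amplitude satisfies
  fn(α, 0) = 0, Var(fn) → α·N as N → ∞ (the √(3α) factor, since a uniform
  on ±A has variance A²/3), keeps N + fn ≥ 0 for α < 10, and gives a
  maximum amplitude between ~0.8 N and N for counts N ≤ 5 at α = 5.  The
  amplitude expression is isolated in one function (`noise_amplitude`) so
  it can be swapped without touching anything else.  Noise is applied only
  to stored entries (zeros are fixed points); a negative draw is clamped
  at 0 and counted (it should not occur for α < 10).
* **Upregulation** (`apply_upregulation`) — N → N + round((β − 1)·N) with
  round-half-even, i.e. an expected multiplicative change of β; β = 1.5 on
  even counts is exactly +50%, while β = 1.3 on moderate-expression genes
  realizes 25–30% because of integer rounding loss (quantified by
  enumeration in the tests).
* **Synthetic matrices** (`generate_synthetic`) — per cell, depth
  N_i ~ log-normal (default meanlog = ln 10⁴, sdlog = 0.7, spanning
  roughly 2,000–50,000, i.e. ~100-fold across 1,000 cells); per gene, a
  heavy-tailed log-normal abundance (sdlog = 1.8, under which ~12,000 of
  15,000 genes exceed 30 total counts at the default scale); per
  gene × cell, the expected proportion is the abundance times a gamma
  variate with gene-specific dispersion (mean 1, variance = dispersion,
  drawn log-uniformly over 10⁻³–10⁰), renormalized per cell; counts are
  multinomial(N_i, ·), so column sums equal the drawn depths exactly.
  The dispersion spread reproduces the full observed WDC range (near 0
  for highly variable well-expressed genes up to ~1 for low-count genes).
  What the generator does *not* emulate: doublets, ambient RNA,
  batch-specific capture efficiencies, gene–gene correlation structure,
  and cell-type mixtures.  Passing benchmarks on it therefore demonstrates
  the statistical behavior of the tests under depth variation, sampling
  noise and overdispersion — not robustness to every artifact of real
  tissue data.
* **Randomness** — all operations derive independent streams from
  (seed, operation tag) via SeedSequence, so pipelines are reproducible
  stage by stage with a single user seed.

## Benchmark designs and problem sizes

The packaged benchmarks are desk-scale versions of three designs, run on
the synthetic base matrix (1,000 cells × 15,000 genes, ~12,500 genes
above the >30-count filter):

1. **Subsampling null** — original vs 40%-thinned (exact mode), 10
   replicates.  Expected outcome: zero genes at p < 0.05 for the weighted
   t, χ², and combination; Wilcoxon ≥ 75% of genes at p < 0.001 and ≥ 60%
   at p < 10⁻⁵; log-normalized t ≥ 20% at p < 0.001; relative-count t
   near zero.  One replicate runs in ~5 s.
2. **Noise + upregulation** — α = 5 noise on 1,000 moderate-expression
   genes (0.3–3 counts/cell), β = 1.5 on a 300-gene subset.  Tallies use
   both definitions: p-only, and p combined with |log₂FC| > 0.1.  The
   weighted combination detects at least as many planted genes as every
   comparator with zero false positives.
3. **Multi-sample 5v5** — ten samples subset at 20–100% of the cells,
   noise in all, β = 1.3 upregulation in one condition; the across-sample
   weighted t yields no more false negatives than the aggregate-count t,
   and a null variant stays at ≤ 7% of genes below p = 0.05.

The type-I calibration check uses an equal-depth population (depth
sdlog = 0, 300 cells per group, 2,200 genes) where the weighted t-test is
exactly Welch's t and the p-distribution is uniform; under 100-fold depth
spread the test is intentionally conservative (see above), which is
measured rather than asserted away.

## Numerical choices and edge cases

* Counts must be integral (tolerance 10⁻⁹ when reading "real"-typed
  Matrix Market files) and non-negative; duplicate feature ids are
  deduplicated deterministically with ".1", ".2", … suffixes.
* Gene filters: total-count filter is strict (> min_total, default 30);
  detection filter is per group with an inclusive ≥ fraction.
  Filtered-out genes are absent from output (no NA rows).
* The vectorized per-gene engine (`gene_profiles`) is algebraically
  identical to composing the scalar operations and is tested against them
  gene by gene; it processes genes in blocks of 4,096 to bound memory.
* Constant genes return exactly zero variance (no floating residue), so
  identical groups give p = 1 exactly.
* log₂FC is ±inf when exactly one mean is zero (written "Inf"/"-Inf") and
  NaN when both are zero; undefined p-values are written "NA".
* Weighted means with ρ = 0 weights equal aggregate ratios to 10⁻¹⁴ and
  are asserted at that tolerance.

## Known limitations

* The ICC estimator is the unweighted one-way ANOVA form; with extreme
  cluster-size imbalance other estimators (weighted ANOVA, variance
  decomposition specific to multinomial sampling) could differ in
  small-sample detail, as could the degrees-of-freedom rule of the
  weighted t-test.
* Cells selected by expression-based clustering violate the independent
  sampling premise of every test here; groups should be selected by
  marker rules or external labels, and marker genes excluded from
  downstream interpretation.
* The spatial mode ignores probe-diffusion correlation between adjacent
  bins; an alternative scheme treating clusters of bins as replicates is
  sketched in the literature but not implemented.
* p-values are raw; FDR control is context-dependent and intentionally
  left to the user.
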