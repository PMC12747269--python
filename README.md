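# wdge — weighted differential gene expression for single-cell and spatial RNA-seq

Differential gene expression (DGE) calls from single-cell (scRNA-seq) and
spatial (spRNA-seq) experiments are notoriously unstable: the total number
of transcripts detected per cell varies by up to ~100-fold, and the common
tests either ignore this (Wilcoxon rank-sum, unweighted t-tests on
log-normalized counts) or assume every cell contributes in proportion to
its depth (pseudo-bulk count aggregation).  Both assumptions are wrong for
most genes and both produce large numbers of false positives and false
negatives.

`wdge` treats each cell as a cluster of a cluster-randomized experiment and
makes no assumption beyond randomness of the technical noise.  For a gene
*Z* with UMI counts *N*<sub>*Z,i*</sub> in cells *i* of total depth
*N*<sub>*i*</sub>:

* relative expression  *n*<sub>*Z,i*</sub> = *N*<sub>*Z,i*</sub>/*N*<sub>*i*</sub>;
* weighted mean  *n̄*<sub>*Z*</sub> = Σ*w*<sub>*Z,i*</sub>*n*<sub>*Z,i*</sub> with

  *w*<sub>*Z,i*</sub> ∝ *N*<sub>*i*</sub> / (1 + ρ<sub>*Z*</sub>(*N*<sub>*i*</sub> − 1)),

  where ρ<sub>*Z*</sub> ∈ [0, 1] is the gene's intracluster correlation
  coefficient (ICC), estimated from the counts with the Fleiss–Donner
  one-way-ANOVA moment estimator.  ρ<sub>*Z*</sub> = 0 recovers
  aggregate-count weights (*w* ∝ *N*<sub>*i*</sub>, counting noise
  dominates); ρ<sub>*Z*</sub> = 1 recovers equal weights (biological
  variance dominates).  The weight distribution coefficient
  WDC<sub>*Z*</sub> = Var(*w*<sub>*Z,i*</sub>)/Var(*w*<sub>AC</sub>)
  locates each gene between those regimes.
* significance from a two-tailed **weighted t-test** on the weighted means
  (reliability-weights variance, Kish effective sample sizes,
  Welch–Satterthwaite df), optionally **combined with a χ² test** on the
  2×2 aggregate-count table.  The χ² test sees only transcript-sampling
  noise, so it is never used alone; the *proxy* rule replaces a significant
  weighted-t p-value by a non-significant χ² one, and the *max* rule takes
  the larger p-value.
* for replicated experiments, per-sample weighted means *n̄*<sub>*Z,s*</sub>
  and their variances are combined across samples with inverse-variance
  weights — a drop-in replacement for pseudo-bulk aggregation.
* for sequencing-based spatial assays (e.g. Visium HD), bins play the role
  of cells with ρ<sub>*Z*</sub> forced to 0 and the conservative *max*
  combination, after configurable bin QC (features/bin, counts excluding
  structural genes, mitochondrial fraction, marker fraction).

The package also ships the full simulation machinery used to benchmark the
tests — binomial and exact-fraction UMI thinning, a zero-mean uniform noise
function with Var → α·*N*, proportional upregulation, and a synthetic
count-matrix generator with known ground truth — so every claim is testable
without downloading data.

No multiple-testing correction is applied anywhere; p-values are reported
raw.

## Worked example

Plant a 50% upregulation (β = 1.5) of three genes in half of a synthetic
600-cell population and test treated vs control:

```python
import numpy as np
import wdge

cm, _ = wdge.generate_synthetic(wdge.SynthConfig(n_cells=600, n_genes=2000, seed=42))

targets = ["G00010", "G00050", "G00200"]
idx = np.arange(cm.n_cells)
treated = wdge.apply_upregulation(cm.subset_cells(idx[300:]), targets, beta=1.5)
control = cm.subset_cells(idx[:300])

ga = wdge.CellGroup(treated, np.arange(300), "treated")
gb = wdge.CellGroup(control, np.arange(300), "control")
table = wdge.run_dge(ga, gb, wdge.DGEConfig(min_total=30))
```

The planted genes come out as:

```
  gene  mean_w_A  mean_w_B  log2fc_w    rho_A  wdc_A     p_wt  p_chi2  p_combined  p_wilcoxon
G00010   8.3e-06  6.59e-06     0.332 9.35e-06  0.675    0.502   0.356       0.502       0.472
G00050  1.77e-05  2.06e-05    -0.219 2.27e-05  0.465    0.493   0.919       0.493      0.0369
G00200  0.000368  0.000236     0.641 0.000175 0.0905 3.02e-08   1e-33    3.02e-08    4.32e-05

unmodified genes tested: 1924; with combined p < 0.05: 39
```

The well-expressed target `G00200` (~1 count per cell) is detected with
log₂FC ≈ 0.64 ≈ log₂ 1.5 and a combined p of 3×10⁻⁸; the two targets near
the detection floor are masked by transcript-sampling noise, as expected.
Only 2% of the 1,924 unmodified genes reach p < 0.05 — the weighted
combination errs on the conservative side.  Note `G00050`: its realized
fold change is actually negative (the planted effect drowned in sampling
noise), yet the Wilcoxon test reports p = 0.037 — rank tests respond to
distributional differences that mean-based tests correctly treat as noise.

The same pipeline is available from the shell:

```sh
wdge dge --matrix data/mtx --group-a markers:Gad1,Gad2,Slc6a1 \
         --group-b markers:Gls,Grin2b,Slc17a7 --out dge.tsv
wdge benchmark --design subsample --reps 10 --out report.tsv
```

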