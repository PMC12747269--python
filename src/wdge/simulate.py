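"""Benchmark machinery: thinning, noise, upregulation, synthetic matrices.

The benchmarks perturb a count matrix in ways with a known ground truth:

* **UMI subsampling** — reduced sequencing depth.  Two modes: per-entry
  binomial thinning (every UMI kept independently with probability p) and
  per-gene exact-fraction thinning (exactly round(p·total) of each gene's
  UMIs retained, multivariate-hypergeometric across cells).  The exact mode
  preserves each gene's aggregate ratio, which is the configuration under
  which subsampling alone leaves no aggregate signal at all.
* **Uniform noise** — zero-mean integer perturbations fn(α, N) uniform on
  ±A(α, N) before rounding, with A(α, 0) = 0 and Var(fn) → αN at large N.
* **Proportional upregulation** — N → N + round((β−1)·N), an expected
  multiplicative change of β (β = 1.5 models 50% upregulation).
* **Synthetic count matrices** — log-normal per-cell depths spanning ~100
  fold, heavy-tailed gene abundances, and gene-specific gamma-distributed
  biological variability producing a realistic spread of ICC/WDC values;
  counts are multinomial per cell so column sums equal the drawn depths.

Randomness: every operation takes a single integer seed; independent
streams are derived from (seed, operation tag) so pipelines are
reproducible stage by stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

__all__ = [
    "NoiseSpec",
    "SimTruth",
    "SynthConfig",
    "rng_for",
    "subsample_umis",
    "noise_amplitude",
    "noise_fn",
    "apply_noise",
    "apply_upregulation",
    "generate_synthetic",
    "simulate_clustered_counts",
    "plant_effects",
    "tally_benchmark",
]


def rng_for(seed: int, tag: str) -> np.random.Generator:
    """Independent, reproducible stream for one operation of a pipeline."""
    import zlib

    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(tag.encode()) % 2**31])
    )


@dataclass
class NoiseSpec:
    """Uniform-noise perturbation of a set of target genes."""

    alpha: float = 5.0
    target_genes: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 10.0:
            raise ValueError("alpha must be in (0, 10)")


@dataclass
class SimTruth:
    """Per-gene ground truth of a benchmark simulation."""

    status: pd.Series  # index: gene id; values in {unmodified, noise_only, upregulated}
    beta: dict[str, float] = field(default_factory=dict)

    def genes_with(self, *statuses: str) -> np.ndarray:
        return self.status.index[self.status.isin(statuses)].to_numpy()


@dataclass
class SynthConfig:
    """Conditions of the synthetic base matrix.

    Defaults emulate a ~1,000-cell 10x experiment: log-normal depths with
    median ~10,000 spanning roughly 2,000–50,000 (~100-fold across cells),
    a heavy-tailed (log-normal, σ=1.8) gene abundance distribution under
    which ~12,000 of 15,000 genes exceed 30 total counts, and per-gene
    biological dispersions log-uniform over three orders of magnitude so
    that estimated ICC/WDC values span their full range.
    """

    n_cells: int = 1000
    n_genes: int = 15_000
    depth_meanlog: float = np.log(10_000.0)
    depth_sdlog: float = 0.7
    abundance_sdlog: float = 1.8
    dispersion_log10_range: tuple[float, float] = (-3.0, 0.0)
    group_depth_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("degenerate config: need positive cell and gene counts")
        if self.group_depth_multiplier <= 0:
            raise ValueError("depth multiplier must be positive")


def subsample_umis(
    cm: CountMatrix, retain_p: float, seed: int, mode: str = "binomial"
) -> CountMatrix:
    """Thin a count matrix, retaining each UMI with probability ``retain_p``.

    mode="binomial": every entry becomes an independent Binomial(N, p) draw.
    mode="per_gene_exact": exactly round(p · gene total) UMIs of each gene
    are kept, allocated across cells by multivariate hypergeometric
    sampling — the per-gene aggregate ratio is preserved exactly.
    """
    if not 0.0 <= retain_p <= 1.0:
        raise ValueError("retain_p must be in [0, 1]")
    rng = rng_for(seed, f"subsample:{mode}")
    coo = cm.counts.tocoo()
    if mode == "binomial":
        data = rng.binomial(coo.data, retain_p)
    elif mode == "per_gene_exact":
        csr = cm.counts.tocsr()
        data = np.empty_like(csr.data)
        for g in range(cm.n_genes):
            lo, hi = csr.indptr[g], csr.indptr[g + 1]
            row = csr.data[lo:hi]
            tot = int(row.sum())
            keep = int(round(retain_p * tot))
            data[lo:hi] = (
                rng.multivariate_hypergeometric(row, keep) if tot else row
            )
        # copy index arrays: eliminate_zeros() prunes in place
        new = sp.csr_matrix(
            (data, csr.indices.copy(), csr.indptr.copy()), shape=csr.shape
        )
        new.eliminate_zeros()
        return CountMatrix(new, cm.gene_ids, cm.barcodes)
    else:
        raise ValueError(f"unknown subsampling mode: {mode}")
    new = sp.coo_matrix((data, (coo.row, coo.col)), shape=coo.shape).tocsr()
    new.eliminate_zeros()
    return CountMatrix(new, cm.gene_ids, cm.barcodes)


def _sf(alpha: float, N: np.ndarray) -> np.ndarray:
    s = np.sqrt(3.0 * alpha)
    return s - (s - 1.0) / (1.0 + 0.1 * N)


def noise_amplitude(alpha: float, N) -> np.ndarray:
    """Noise amplitude A(α, N) = sf(α, N)·√N with sf = √(3α) − (√(3α)−1)/(1+0.1N).

    A(α, 0) = 0 and Var(round(U·A)) → αN as N → ∞ (U uniform on [−1, 1]).
    """
    N = np.asarray(N, dtype=float)
    return _sf(alpha, N) * np.sqrt(N)


def noise_fn(alpha: float, N, rng: np.random.Generator):
    """Integer zero-mean uniform noise draw(s) for count(s) N."""
    if not 0.0 < alpha < 10.0:
        raise ValueError("alpha must be in (0, 10)")
    N = np.asarray(N)
    if np.any(N < 0):
        raise ValueError("counts must be >= 0")
    u = rng.uniform(-1.0, 1.0, size=N.shape)
    out = np.round(u * noise_amplitude(alpha, N))  # round half to even
    return out.astype(np.int64)


def apply_noise(cm: CountMatrix, spec: NoiseSpec) -> CountMatrix:
    """Add fn(α, N) to every entry of the target genes (clamped at 0).

    Negative post-noise counts should not occur for α < 10; they are clamped
    defensively and counted on the returned matrix as ``n_clamped``.
    """
    rng = rng_for(spec.seed, "noise")
    target_idx = np.array([cm.gene_index(g) for g in spec.target_genes], dtype=int)
    csr = cm.counts.tocsr().astype(np.int64).copy()
    n_clamped = 0
    # fn(alpha, 0) = 0, so only the stored (nonzero) entries can change
    for g in target_idx:
        lo, hi = csr.indptr[g], csr.indptr[g + 1]
        row = csr.data[lo:hi]
        noisy = row + noise_fn(spec.alpha, row, rng)
        n_clamped += int((noisy < 0).sum())
        csr.data[lo:hi] = np.maximum(noisy, 0)
    csr.eliminate_zeros()
    out = CountMatrix(csr, cm.gene_ids, cm.barcodes)
    out.n_clamped = n_clamped  # type: ignore[attr-defined]
    return out


def apply_upregulation(cm: CountMatrix, genes, beta: float) -> CountMatrix:
    """Upregulate target genes: N → N + round((β−1)·N), half-even rounding."""
    if beta < 1.0:
        raise ValueError("beta must be >= 1")
    target_idx = np.array([cm.gene_index(g) for g in genes], dtype=int)
    csr = cm.counts.tocsr().astype(np.int64).copy()
    for g in target_idx:
        lo, hi = csr.indptr[g], csr.indptr[g + 1]
        row = csr.data[lo:hi]
        csr.data[lo:hi] = row + np.round((beta - 1.0) * row).astype(np.int64)
    return CountMatrix(csr, cm.gene_ids, cm.barcodes)


def generate_synthetic(config: SynthConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Synthetic base count matrix with known per-gene structure.

    Per cell: depth N_i ~ log-normal.  Per gene: base abundance from a
    heavy-tailed distribution; the expected proportion in each cell is the
    abundance times a gamma variate with gene-specific dispersion (mean 1,
    variance = dispersion), renormalized per cell; counts are
    multinomial(N_i, proportions), so column sums equal the drawn depths.

    Returns the matrix and a per-gene frame (abundance, dispersion) that
    records the generating parameters.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 424243]))
    depths = rng.lognormal(config.depth_meanlog, config.depth_sdlog, config.n_cells)
    depths = np.maximum((depths * config.group_depth_multiplier).astype(np.int64), 1)
    abund = rng.lognormal(0.0, config.abundance_sdlog, config.n_genes)
    base_p = abund / abund.sum()
    lo, hi = config.dispersion_log10_range
    disp = 10.0 ** rng.uniform(lo, hi, config.n_genes)
    shape = 1.0 / disp

    X = np.empty((config.n_genes, config.n_cells), dtype=np.int64)
    for i in range(config.n_cells):
        gam = rng.gamma(shape, disp)
        q = base_p * gam
        q /= q.sum()
        X[:, i] = rng.multinomial(depths[i], q)

    gene_ids = np.array([f"G{j:05d}" for j in range(config.n_genes)])
    barcodes = np.array([f"CELL{i:05d}" for i in range(config.n_cells)])
    cm = CountMatrix(sp.csr_matrix(X), gene_ids, barcodes)
    meta = pd.DataFrame({"gene": gene_ids, "abundance": base_p, "dispersion": disp})
    return cm, meta


def simulate_clustered_counts(
    n_cells: int,
    totals: np.ndarray,
    p: float,
    rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Beta-binomial clustered counts with a planted ICC.

    Each cell draws a success probability q_i ~ Beta with mean p and
    intracluster correlation rho (Var(q) = ρ·p·(1−p)), then
    X_i ~ Binomial(N_i, q_i).  ρ = 0 degenerates to plain binomial counts.
    Used for estimator parameter-recovery checks.
    """
    totals = np.asarray(totals, dtype=np.int64)
    if totals.size != n_cells:
        raise ValueError("totals length must equal n_cells")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0, 1)")
    if rho == 0.0:
        return rng.binomial(totals, p)
    conc = (1.0 - rho) / rho  # a + b
    q = rng.beta(p * conc, (1.0 - p) * conc, size=n_cells)
    return rng.binomial(totals, q)


def plant_effects(
    cm: CountMatrix,
    noise_genes,
    upregulated_genes,
    alpha: float = 5.0,
    beta: float = 1.5,
    seed: int = 0,
) -> tuple[CountMatrix, SimTruth]:
    """Noise all ``noise_genes``, then upregulate the ``upregulated_genes``
    subset; returns the modified matrix and the ground-truth annotation."""
    noise_genes = list(noise_genes)
    upregulated_genes = list(upregulated_genes)
    if not set(upregulated_genes) <= set(noise_genes):
        raise ValueError("upregulated genes must be a subset of the noise genes")
    out = apply_noise(cm, NoiseSpec(alpha=alpha, target_genes=noise_genes, seed=seed))
    if upregulated_genes:
        out = apply_upregulation(out, upregulated_genes, beta)
    status = pd.Series("unmodified", index=cm.gene_ids, name="status")
    status.loc[noise_genes] = "noise_only"
    status.loc[upregulated_genes] = "upregulated"
    return out, SimTruth(status, {g: beta for g in upregulated_genes})


# ---------------------------------------------------------------------------
# Benchmark drivers
# ---------------------------------------------------------------------------


def benchmark_subsampling(
    cm: CountMatrix,
    retain_p: float = 0.4,
    n_reps: int = 10,
    seed: int = 0,
    mode: str = "per_gene_exact",
    min_total: int = 30,
) -> list[pd.DataFrame]:
    """Original-vs-thinned null design: one DGE table per replicate.

    The gene universe is fixed on the *original* data (total count strictly
    above ``min_total`` over all cells); every replicate rethins the whole
    matrix and compares all original cells against all thinned cells.  Any
    detection in this design is a false positive.
    """
    from .io import CellGroup, filter_genes_min_total
    from .two_group import run_dge

    genes = filter_genes_min_total(cm, None, min_total)
    all_cells = np.arange(cm.n_cells)
    group_a = CellGroup(cm, all_cells, "original")
    out = []
    for rep in range(n_reps):
        thinned = subsample_umis(cm, retain_p, seed=seed * 1009 + rep, mode=mode)
        group_b = CellGroup(thinned, all_cells, "thinned")
        out.append(run_dge(group_a, group_b, genes=genes))
    return out


def benchmark_noise_upregulation(
    cm: CountMatrix,
    n_noise: int = 1000,
    n_up: int = 300,
    alpha: float = 5.0,
    beta: float = 1.5,
    n_reps: int = 10,
    seed: int = 0,
    min_total: int = 30,
    moderate_range: tuple[float, float] = (0.3, 3.0),
) -> tuple[list[pd.DataFrame], list[SimTruth]]:
    """Noise + proportional-upregulation design (one truth per replicate).

    Each replicate draws a fresh random set of ``n_noise`` moderately
    expressed genes (average counts per cell within ``moderate_range``),
    perturbs them with uniform noise, upregulates a random ``n_up`` subset
    by β, and compares original vs modified over the filtered universe.
    """
    from .io import CellGroup, filter_genes_min_total
    from .two_group import run_dge

    genes = filter_genes_min_total(cm, None, min_total)
    per_cell = np.asarray(cm.counts.sum(axis=1)).ravel() / cm.n_cells
    moderate = genes[
        (per_cell[genes] >= moderate_range[0]) & (per_cell[genes] <= moderate_range[1])
    ]
    if moderate.size < n_noise:
        raise ValueError(
            f"only {moderate.size} moderate-expression genes available, need {n_noise}"
        )
    all_cells = np.arange(cm.n_cells)
    group_a = CellGroup(cm, all_cells, "original")
    tables, truths = [], []
    for rep in range(n_reps):
        rng = rng_for(seed * 1013 + rep, "design")
        noise_genes = cm.gene_ids[rng.choice(moderate, size=n_noise, replace=False)]
        up_genes = rng.choice(noise_genes, size=n_up, replace=False)
        modified, truth = plant_effects(
            cm, noise_genes, up_genes, alpha=alpha, beta=beta, seed=seed * 1013 + rep
        )
        group_b = CellGroup(modified, all_cells, "modified")
        tables.append(run_dge(group_a, group_b, genes=genes))
        truths.append(truth)
    return tables, truths


def benchmark_multisample(
    cm: CountMatrix,
    n_samples: int = 5,
    subset_fractions=(0.2, 0.4, 0.6, 0.8, 1.0),
    n_noise: int = 1000,
    n_up: int = 300,
    alpha: float = 5.0,
    beta: float = 1.3,
    seed: int = 0,
    min_total: int = 30,
    moderate_range: tuple[float, float] = (0.3, 3.0),
) -> tuple[pd.DataFrame, SimTruth]:
    """Replicated-samples design: noise-only vs noise+upregulation conditions.

    2·``n_samples`` samples are drawn from the base matrix by random cell
    subsetting at the given fractions; all samples receive fresh uniform
    noise on the same ``n_noise`` moderately expressed genes, and one
    condition additionally receives a β upregulation of an ``n_up`` subset.
    Returns the multi-sample DGE table and the truth annotation.
    """
    from .io import CellGroup, filter_genes_min_total
    from .multisample import run_dge_multisample

    genes = filter_genes_min_total(cm, None, min_total)
    per_cell = np.asarray(cm.counts.sum(axis=1)).ravel() / cm.n_cells
    moderate = genes[
        (per_cell[genes] >= moderate_range[0]) & (per_cell[genes] <= moderate_range[1])
    ]
    if moderate.size < n_noise:
        raise ValueError(
            f"only {moderate.size} moderate-expression genes available, need {n_noise}"
        )
    rng = rng_for(seed, "multisample-design")
    noise_genes = cm.gene_ids[rng.choice(moderate, size=n_noise, replace=False)]
    up_genes = rng.choice(noise_genes, size=n_up, replace=False) if n_up else []

    fractions = list(subset_fractions)
    while len(fractions) < n_samples:
        fractions.append(1.0)
    samples_a, samples_b = [], []
    truth = None
    for cond, bucket in (("A", samples_a), ("B", samples_b)):
        for s in range(n_samples):
            frac = fractions[s % len(fractions)]
            n_keep = max(2, int(round(frac * cm.n_cells)))
            cells = rng.choice(cm.n_cells, size=n_keep, replace=False)
            sub = cm.subset_cells(np.sort(cells))
            ups = up_genes if cond == "B" else []
            modified, tr = plant_effects(
                sub, noise_genes, ups, alpha=alpha, beta=beta,
                seed=seed * 1021 + 10 * s + (0 if cond == "A" else 1),
            )
            if cond == "B":
                truth = tr
            bucket.append(CellGroup(modified, np.arange(modified.n_cells), f"{cond}{s}"))
    table = run_dge_multisample(samples_a, samples_b, genes=genes)
    return table, truth


def tally_benchmark(
    results: list[pd.DataFrame],
    truth: SimTruth,
    thresholds=(0.05, 0.001, 1e-5),
    fc_threshold: float = 0.1,
    tests=("p_combined", "p_wt", "p_chi2", "p_t_rc", "p_t_log", "p_wilcoxon"),
    fc_column: str = "log2fc_w",
) -> pd.DataFrame:
    """False-positive / false-negative tallies across replicates.

    For every test column, significance threshold and tally mode:

    * mode "p": detected iff p < threshold.
    * mode "p_fc": detected iff p < threshold and |log2FC| > ``fc_threshold``.

    FP fraction is computed over genes whose truth status is ``noise_only``
    or ``unmodified`` present in the result table; FN fraction over
    ``upregulated`` genes.  Returns one tidy row per
    (test, threshold, mode) with median and quartiles across replicates.
    """
    rows = []
    for test in tests:
        for thr in thresholds:
            for mode in ("p", "p_fc"):
                fps, fns = [], []
                for tab in results:
                    st = truth.status.reindex(tab["gene"]).to_numpy()
                    if pd.isna(st).any():
                        raise ValueError("result table contains genes absent from truth")
                    p = tab[test].to_numpy()
                    detected = p < thr
                    if mode == "p_fc":
                        detected &= np.abs(tab[fc_column].to_numpy()) > fc_threshold
                    null_mask = (st == "noise_only") | (st == "unmodified")
                    pos_mask = st == "upregulated"
                    if null_mask.any():
                        fps.append(detected[null_mask].mean())
                    if pos_mask.any():
                        fns.append((~detected[pos_mask]).mean())
                rows.append(
                    {
                        "test": test,
                        "threshold": thr,
                        "mode": mode,
                        "fp_median": float(np.median(fps)) if fps else np.nan,
                        "fp_q25": float(np.percentile(fps, 25)) if fps else np.nan,
                        "fp_q75": float(np.percentile(fps, 75)) if fps else np.nan,
                        "fn_median": float(np.median(fns)) if fns else np.nan,
                        "fn_q25": float(np.percentile(fns, 25)) if fns else np.nan,
                        "fn_q75": float(np.percentile(fns, 75)) if fns else np.nan,
                        "n_replicates": len(results),
                    }
                )
    return pd.DataFrame(rows)
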