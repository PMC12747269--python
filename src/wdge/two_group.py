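"""Two-group differential expression.

Per gene, the weighted means of the two groups are compared with a
two-tailed unequal-variance weighted t-test (Welch–Satterthwaite degrees of
freedom on the effective sample sizes), and the pooled aggregate counts are
compared with a df-1 Pearson χ² test on the 2x2 table
[[X_A, T_A−X_A], [X_B, T_B−X_B]].  The χ² test accounts only for transcript
sampling in the sequenced cells, so it is never used alone; two combination
rules are provided:

* ``proxy``  — substitute the χ² p-value for the weighted-t one when the
  former but not the latter exceeds the significance floor (moderately
  conservative, the default for single-cell data);
* ``max``    — the larger of the two p-values (most conservative).

Comparator tests used in the benchmarks (Welch t on relative counts, Welch
t on log-normalized counts, Wilcoxon rank-sum) are provided alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .io import CellGroup, filter_genes_min_total, detection_fraction_filter
from .weighting import gene_profiles

__all__ = [
    "CombinationPolicy",
    "DGEConfig",
    "weighted_t_test",
    "chi2_aggregate_test",
    "combine_pvalues",
    "log2_fold_change",
    "comparator_tests",
    "run_dge",
    "write_dge_tsv",
    "DGE_COLUMNS",
]

LOG_NORM_SCALE = 10_000.0  # Seurat convention: log(1 + 10^4 * relative count)

DGE_COLUMNS = [
    "gene",
    "mean_w_A", "mean_w_B", "log2fc_w",
    "rho_A", "rho_B", "wdc_A", "wdc_B",
    "agg_A", "tot_A", "agg_B", "tot_B",
    "p_wt", "p_chi2", "p_combined", "p_t_rc", "p_t_log", "p_wilcoxon",
]


@dataclass
class CombinationPolicy:
    """How the weighted-t and χ² p-values are merged."""

    mode: str = "proxy"  # "proxy" | "max"
    alpha_min: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in ("proxy", "max"):
            raise ValueError(f"unknown combination mode: {self.mode}")
        if not 0.0 < self.alpha_min < 1.0:
            raise ValueError("alpha_min must be in (0, 1)")


@dataclass
class DGEConfig:
    min_total: int = 30
    detection_fraction: float = 0.0
    policy: CombinationPolicy = field(default_factory=CombinationPolicy)
    rho_override: float | None = None
    comparators: bool = True


def _p_from_t(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(t), df)


def weighted_t_test(profile_a, profile_b) -> tuple[float, float, float]:
    """Two-tailed weighted t-test between two :class:`GeneWeightProfile`s.

    Returns ``(t, df, p)``.  df is Welch–Satterthwaite with (n_eff − 1) as
    the per-group denominators.  Both variances zero: p = 1 when the means
    agree, p = 0 (degenerate) when they differ.
    """
    va, vb = profile_a.var_mean, profile_b.var_mean
    ma, mb = profile_a.mean_w, profile_b.mean_w
    if va + vb == 0.0:
        if ma == mb:
            return 0.0, float("inf"), 1.0
        return float("inf") if ma > mb else float("-inf"), float("inf"), 0.0
    if profile_a.n_eff <= 1.0 or profile_b.n_eff <= 1.0:
        raise ValueError("weighted t-test needs n_eff > 1 in both groups")
    t = (ma - mb) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (
        va**2 / (profile_a.n_eff - 1.0) + vb**2 / (profile_b.n_eff - 1.0)
    )
    return float(t), float(df), float(_p_from_t(np.asarray(t), np.asarray(df)))


def _weighted_t_arrays(ma, va, na, mb, vb, nb):
    """Vectorized weighted t over per-gene arrays; returns (t, df, p)."""
    ma, va, na = (np.asarray(x, dtype=float) for x in (ma, va, na))
    mb, vb, nb = (np.asarray(x, dtype=float) for x in (mb, vb, nb))
    vs = va + vb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(vs)
        df = vs**2 / (va**2 / (na - 1.0) + vb**2 / (nb - 1.0))
        p = _p_from_t(t, df)
    zero = vs == 0.0
    if np.any(zero):
        t = np.where(zero, 0.0, t)
        p = np.where(zero & (ma == mb), 1.0, np.where(zero, 0.0, p))
    return t, df, p


def chi2_aggregate_test(agg_a, tot_a, agg_b, tot_b):
    """Pearson χ² (df 1, no continuity correction) on the 2x2 aggregate table.

    Accepts scalars or per-gene arrays (``tot`` may be scalar).  Genes absent
    from both groups get NaN (undefined).
    """
    a = np.asarray(agg_a, dtype=float)
    c = np.asarray(agg_b, dtype=float)
    ta = np.asarray(tot_a, dtype=float)
    tb = np.asarray(tot_b, dtype=float)
    if np.any(a > ta) or np.any(c > tb):
        raise ValueError("aggregate count exceeds total")
    if np.any(ta <= 0) or np.any(tb <= 0):
        raise ValueError("totals must be positive")
    b = ta - a
    d = tb - c
    n = ta + tb
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        p = stats.chi2.sf(stat, 1)
    undef = (a + c == 0) | (b + d == 0)
    p = np.where(undef, np.nan, p)
    if p.ndim == 0:
        return float(p)
    return p


def combine_pvalues(p_wt, p_chi2, policy: CombinationPolicy | None = None):
    """Merge the weighted-t and χ² p-values under the given policy.

    Undefined (NaN) χ² p-values fall back to the weighted-t p-value.
    Accepts scalars or arrays.
    """
    policy = policy or CombinationPolicy()
    p_wt = np.asarray(p_wt, dtype=float)
    p_chi2 = np.asarray(p_chi2, dtype=float)
    defined = ~np.isnan(p_chi2)
    if policy.mode == "max":
        out = np.where(defined, np.fmax(p_wt, p_chi2), p_wt)
    else:  # proxy
        swap = defined & (p_chi2 >= policy.alpha_min) & (p_wt < policy.alpha_min)
        out = np.where(swap, p_chi2, p_wt)
    if out.ndim == 0:
        return float(out)
    return out


def log2_fold_change(mean_a, mean_b):
    """log2(mean_A/mean_B); ±inf when exactly one mean is 0, NaN when both."""
    ma = np.asarray(mean_a, dtype=float)
    mb = np.asarray(mean_b, dtype=float)
    if np.any(ma < 0) or np.any(mb < 0):
        raise ValueError("means must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(ma) - np.log2(mb)
    if out.ndim == 0:
        return float(out)
    return out


def _welch_t_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Welch t p-values along the last axis; constant-equal input gives 1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(a, b, axis=-1, equal_var=False).pvalue
    p = np.asarray(p, dtype=float)
    const = (np.ptp(a, axis=-1) == 0) & (np.ptp(b, axis=-1) == 0)
    if np.any(const):
        same = a[..., 0] == b[..., 0]
        p = np.where(const & same, 1.0, p)
        p = np.where(const & ~same, 0.0, p)
    return p


def _wilcoxon_p(a: np.ndarray, b: np.ndarray, exact_small: bool = True) -> np.ndarray:
    """Two-sided rank-sum p along the last axis.

    Tie-corrected normal approximation without continuity correction; exact
    null enumeration for small tie-free inputs (like R's wilcox.test).
    """
    na, nb = a.shape[-1], b.shape[-1]
    small = exact_small and max(na, nb) <= 25
    if small and a.ndim == 1:
        pooled = np.concatenate([a, b])
        if np.unique(pooled).size == pooled.size:  # tie-free
            return np.asarray(
                stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.mannwhitneyu(
            a, b, axis=-1, alternative="two-sided",
            method="asymptotic", use_continuity=False,
        )
    p = np.asarray(res.pvalue, dtype=float)
    # all values identical across both groups -> no evidence
    allsame = (np.ptp(a, axis=-1) == 0) & (np.ptp(b, axis=-1) == 0) & (a[..., 0] == b[..., 0])
    return np.where(np.isnan(p) | allsame, 1.0, p)


def comparator_tests(group_a: CellGroup, group_b: CellGroup, gene: str):
    """(p_t_rc, p_t_log, p_wilcoxon) for one gene — the benchmark comparators.

    p_t_rc: Welch t on relative counts; p_t_log: Welch t on
    log(1 + 10⁴·relative count); p_wilcoxon: two-sided rank-sum.
    """
    na = group_a.matrix.gene_row(gene)[group_a.member_indices] / group_a.cell_totals
    nb = group_b.matrix.gene_row(gene)[group_b.member_indices] / group_b.cell_totals
    p_rc = float(_welch_t_p(na, nb))
    p_log = float(_welch_t_p(np.log1p(na * LOG_NORM_SCALE), np.log1p(nb * LOG_NORM_SCALE)))
    p_wil = float(_wilcoxon_p(na, nb))
    return p_rc, p_log, p_wil


def _dense_relative(counts: sp.spmatrix, totals: np.ndarray, rows: np.ndarray) -> np.ndarray:
    return np.asarray(counts[rows].todense(), dtype=float) / totals[None, :]


def run_dge(
    group_a: CellGroup,
    group_b: CellGroup,
    config: DGEConfig | None = None,
    genes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full two-group differential expression table.

    ``genes`` optionally fixes the gene universe (row indices into the shared
    gene id list); otherwise genes are filtered by total count (> min_total
    across both groups' cells) and, when configured, by detection fraction.
    Output rows are ordered by gene id.
    """
    config = config or DGEConfig()
    ga, gb = group_a, group_b
    if not np.array_equal(ga.matrix.gene_ids, gb.matrix.gene_ids):
        raise ValueError("groups must share an identical gene universe")
    gene_ids = ga.matrix.gene_ids

    if genes is None:
        if ga.matrix is gb.matrix:
            genes = filter_genes_min_total(ga.matrix, [ga, gb], config.min_total)
        else:
            ta = np.asarray(ga.counts.sum(axis=1)).ravel()
            tb = np.asarray(gb.counts.sum(axis=1)).ravel()
            genes = np.flatnonzero(ta + tb > config.min_total)
        if config.detection_fraction > 0.0:
            det_a = detection_fraction_filter(ga.matrix, [ga], config.detection_fraction)
            det_b = detection_fraction_filter(gb.matrix, [gb], config.detection_fraction)
            genes = np.intersect1d(genes, np.intersect1d(det_a, det_b))
    genes = np.asarray(genes, dtype=int)
    if genes.size == 0:
        import warnings

        warnings.warn("no genes survive filtering; empty result")
        return pd.DataFrame(columns=DGE_COLUMNS)

    order = np.argsort(gene_ids[genes], kind="stable")
    genes = genes[order]

    counts_a = ga.counts[genes]
    counts_b = gb.counts[genes]
    tot_a_cells = ga.cell_totals
    tot_b_cells = gb.cell_totals
    prof_a = gene_profiles(counts_a, tot_a_cells, rho=config.rho_override)
    prof_b = gene_profiles(counts_b, tot_b_cells, rho=config.rho_override)

    t, df, p_wt = _weighted_t_arrays(
        prof_a["mean_w"], prof_a["var_mean"], prof_a["n_eff"],
        prof_b["mean_w"], prof_b["var_mean"], prof_b["n_eff"],
    )
    tot_a = float(tot_a_cells.sum())
    tot_b = float(tot_b_cells.sum())
    p_chi2 = chi2_aggregate_test(prof_a["agg"], tot_a, prof_b["agg"], tot_b)
    p_comb = combine_pvalues(p_wt, p_chi2, config.policy)
    log2fc = log2_fold_change(prof_a["mean_w"], prof_b["mean_w"])

    n_genes = genes.size
    p_t_rc = np.full(n_genes, np.nan)
    p_t_log = np.full(n_genes, np.nan)
    p_wil = np.full(n_genes, np.nan)
    if config.comparators:
        chunk = 2048
        for lo in range(0, n_genes, chunk):
            hi = min(lo + chunk, n_genes)
            rows = np.arange(lo, hi)
            na = _dense_relative(counts_a, tot_a_cells, rows)
            nb = _dense_relative(counts_b, tot_b_cells, rows)
            p_t_rc[lo:hi] = _welch_t_p(na, nb)
            p_t_log[lo:hi] = _welch_t_p(
                np.log1p(na * LOG_NORM_SCALE), np.log1p(nb * LOG_NORM_SCALE)
            )
            p_wil[lo:hi] = _wilcoxon_p(na, nb, exact_small=False)

    return pd.DataFrame(
        {
            "gene": gene_ids[genes],
            "mean_w_A": prof_a["mean_w"],
            "mean_w_B": prof_b["mean_w"],
            "log2fc_w": log2fc,
            "rho_A": prof_a["rho"],
            "rho_B": prof_b["rho"],
            "wdc_A": prof_a["wdc"],
            "wdc_B": prof_b["wdc"],
            "agg_A": prof_a["agg"].astype(np.int64),
            "tot_A": np.int64(tot_a),
            "agg_B": prof_b["agg"].astype(np.int64),
            "tot_B": np.int64(tot_b),
            "p_wt": p_wt,
            "p_chi2": p_chi2,
            "p_combined": p_comb,
            "p_t_rc": p_t_rc,
            "p_t_log": p_t_log,
            "p_wilcoxon": p_wil,
        }
    )


def write_dge_tsv(table: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    """Write the DGE table with the fixed column contract.

    Infinite log2 fold changes are written as "Inf"/"-Inf", undefined
    p-values as "NA".
    """
    out = table.loc[:, DGE_COLUMNS].copy()
    fc = out["log2fc_w"]
    out["log2fc_w"] = np.where(
        np.isposinf(fc), "Inf", np.where(np.isneginf(fc), "-Inf", fc.astype(object))
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index=False, na_rep="NA")
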