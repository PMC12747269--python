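"""Replicate-aware weighted differential expression across samples.

Instead of pseudo-bulk count aggregation, every sample s is summarized by
its per-gene weighted mean n̄_{Z,s} and the variance of that mean, computed
with the weighting module inside the sample.  Samples are then combined per
condition with inverse-variance weights W_s ∝ 1/Var(n̄_{Z,s}), and the two
condition means are compared with a Welch-type two-tailed t-test whose
per-condition degrees of freedom use the Kish effective number of samples.

Aggregate-count comparators (unweighted and weighted t-tests on per-sample
aggregate ratios ΣX/ΣN) are provided for benchmarking; negative-binomial
pseudo-bulk models are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CellGroup
from .weighting import gene_profiles

__all__ = [
    "SampleSummary",
    "summarize_sample",
    "weighted_t_across_samples",
    "aggregate_count_tests",
    "run_dge_multisample",
    "MULTI_COLUMNS",
]

MULTI_COLUMNS = [
    "gene", "mean_A", "mean_B", "log2fc",
    "p_wt_samples", "p_aggr_t", "p_aggr_wt",
    "n_samples_A", "n_samples_B",
]

_VAR_FLOOR_FACTOR = 1e-3  # zero-variance samples: floor at min positive var x this


@dataclass
class SampleSummary:
    """Per-sample, per-gene weighted summary used for across-sample testing."""

    sample_id: str
    gene_ids: np.ndarray
    mean_w: np.ndarray      # n̄_{Z,s}
    var_mean: np.ndarray    # Var(n̄_{Z,s}); NaN for one-cell samples
    agg: np.ndarray         # ΣX per gene
    tot: float              # ΣN over cells

    @property
    def agg_ratio(self) -> np.ndarray:
        return self.agg / self.tot


def summarize_sample(
    sample: CellGroup,
    genes: np.ndarray | None = None,
    sample_id: str = "",
    rho: float | None = None,
) -> SampleSummary:
    """Weighted per-gene summary of one sample (one :class:`CellGroup`)."""
    gene_rows = np.arange(sample.matrix.n_genes) if genes is None else np.asarray(genes)
    counts = sample.counts[gene_rows]
    totals = sample.cell_totals
    if sample.n_cells == 1:
        n = np.asarray(counts.todense(), dtype=float).ravel() / totals[0]
        return SampleSummary(
            sample_id or sample.label,
            sample.matrix.gene_ids[gene_rows],
            n,
            np.full(gene_rows.size, np.nan),
            n * totals[0],
            float(totals[0]),
        )
    prof = gene_profiles(counts, totals, rho=rho)
    return SampleSummary(
        sample_id or sample.label,
        sample.matrix.gene_ids[gene_rows],
        prof["mean_w"],
        prof["var_mean"],
        prof["agg"],
        float(totals.sum()),
    )


def _floor_variances(V: np.ndarray) -> np.ndarray:
    """Replace zero per-gene sample variances by the smallest positive one in
    the condition scaled by 1e-3, keeping inverse-variance weights finite."""
    V = V.copy()
    bad = ~np.isfinite(V) | (V <= 0)
    if np.any(bad):
        masked = np.where(bad, np.inf, V)
        minpos = masked.min(axis=0)  # per gene
        floor = np.where(np.isfinite(minpos), minpos * _VAR_FLOOR_FACTOR, 1.0)
        V = np.where(bad, floor[None, :], V)
    return V


def _condition_mean_var(means: np.ndarray, variances: np.ndarray):
    """Inverse-variance condition mean, its reliability-weights variance and
    the Kish effective number of samples.  Arrays are samples x genes."""
    V = _floor_variances(variances)
    W = 1.0 / V
    W /= W.sum(axis=0, keepdims=True)
    m = (W * means).sum(axis=0)
    sw2 = (W**2).sum(axis=0)
    var = (W * (means - m[None, :]) ** 2).sum(axis=0) * sw2 / (1.0 - sw2)
    return m, var, 1.0 / sw2


def _welch_from_summaries(ma, va, na_eff, mb, vb, nb_eff):
    from scipy import stats

    vs = va + vb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(vs)
        df = vs**2 / (va**2 / (na_eff - 1.0) + vb**2 / (nb_eff - 1.0))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero = vs == 0.0
    p = np.where(zero & (ma == mb), 1.0, np.where(zero, 0.0, p))
    return np.where(zero, 0.0, t), df, p


def _stack(cond: Sequence[SampleSummary], attr: str) -> np.ndarray:
    ref = cond[0].gene_ids
    for s in cond[1:]:
        if not np.array_equal(s.gene_ids, ref):
            raise ValueError("samples must share an identical gene universe")
    return np.stack([getattr(s, attr) for s in cond])


def weighted_t_across_samples(
    cond_a: Sequence[SampleSummary], cond_b: Sequence[SampleSummary]
):
    """Across-sample weighted t-test per gene.

    Returns ``(t, df, p, log2fc)`` arrays over the shared gene universe.
    Needs >= 2 samples per condition.
    """
    if len(cond_a) < 2 or len(cond_b) < 2:
        raise ValueError("need at least 2 samples per condition")
    ma, va, ea = _condition_mean_var(_stack(cond_a, "mean_w"), _stack(cond_a, "var_mean"))
    mb, vb, eb = _condition_mean_var(_stack(cond_b, "mean_w"), _stack(cond_b, "var_mean"))
    t, df, p = _welch_from_summaries(ma, va, ea, mb, vb, eb)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(ma) - np.log2(mb)
    return t, df, p, log2fc


def aggregate_count_tests(
    cond_a: Sequence[SampleSummary], cond_b: Sequence[SampleSummary]
):
    """Comparators on per-sample aggregate ratios ΣX/ΣN.

    Returns ``(p_unweighted_t, p_weighted_t_on_aggregates)`` per gene: an
    unweighted Welch t across samples, and a weighted variant whose sample
    weights are inverse binomial variances r(1−r)/T of the aggregate ratio.
    """
    if len(cond_a) < 2 or len(cond_b) < 2:
        raise ValueError("need at least 2 samples per condition")

    def cond_stats(cond):
        R = _stack(cond, "agg_ratio")  # samples x genes
        T = np.array([s.tot for s in cond])[:, None]
        n = R.shape[0]
        m = R.mean(axis=0)
        v = R.var(axis=0, ddof=1) / n
        # weighted variant: inverse binomial variance weights
        Vb = R * (1.0 - R) / T
        mw, vw, ew = _condition_mean_var(R, Vb)
        return m, v, np.full(R.shape[1], float(n)), mw, vw, ew

    ma, va, na, mwa, vwa, ewa = cond_stats(cond_a)
    mb, vb, nb, mwb, vwb, ewb = cond_stats(cond_b)
    _, _, p_unw = _welch_from_summaries(ma, va, na, mb, vb, nb)
    _, _, p_w = _welch_from_summaries(mwa, vwa, ewa, mwb, vwb, ewb)
    return p_unw, p_w


def run_dge_multisample(
    samples_a: Sequence[CellGroup],
    samples_b: Sequence[CellGroup],
    min_total: int = 30,
    genes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full multi-sample weighted DGE table over the shared gene universe.

    Genes are filtered by pooled total count across all samples
    (strict > ``min_total``) unless an explicit universe is given.
    """
    all_samples = list(samples_a) + list(samples_b)
    gene_ids = all_samples[0].matrix.gene_ids
    for s in all_samples[1:]:
        if not np.array_equal(s.matrix.gene_ids, gene_ids):
            raise ValueError("samples must share an identical gene universe")
    if genes is None:
        pooled = sum(np.asarray(s.counts.sum(axis=1)).ravel() for s in all_samples)
        genes = np.flatnonzero(pooled > min_total)
    genes = np.asarray(genes, dtype=int)
    order = np.argsort(gene_ids[genes], kind="stable")
    genes = genes[order]

    summ_a = [summarize_sample(s, genes, sample_id=f"A{i}") for i, s in enumerate(samples_a)]
    summ_b = [summarize_sample(s, genes, sample_id=f"B{i}") for i, s in enumerate(samples_b)]
    _, _, p_wt, log2fc = weighted_t_across_samples(summ_a, summ_b)
    p_aggr_t, p_aggr_wt = aggregate_count_tests(summ_a, summ_b)
    ma, _, _ = _condition_mean_var(_stack(summ_a, "mean_w"), _stack(summ_a, "var_mean"))
    mb, _, _ = _condition_mean_var(_stack(summ_b, "mean_w"), _stack(summ_b, "var_mean"))
    return pd.DataFrame(
        {
            "gene": gene_ids[genes],
            "mean_A": ma,
            "mean_B": mb,
            "log2fc": log2fc,
            "p_wt_samples": p_wt,
            "p_aggr_t": p_aggr_t,
            "p_aggr_wt": p_aggr_wt,
            "n_samples_A": len(samples_a),
            "n_samples_B": len(samples_b),
        }
    )
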