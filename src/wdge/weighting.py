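"""Per-gene cell weights from the intracluster correlation coefficient.

Each cell i contributes its relative expression n_{Z,i} = N_{Z,i}/N_i of
gene Z with a statistical weight

    w_{Z,i}  ∝  N_i / (1 + ρ_Z (N_i − 1)),

where ρ_Z ∈ [0, 1] is the intracluster correlation coefficient (ICC) of the
gene: the balance between true cell-to-cell expression variance and
transcript-sampling noise.  At ρ_Z = 0 the weights reduce to aggregate-count
weights N_i/ΣN_i (counting noise dominates); at ρ_Z = 1 all cells are
weighted equally (biological variance dominates).  ρ_Z is estimated from the
counts themselves with the one-way-ANOVA (Fleiss–Donner) moment estimator
for clustered binary outcomes — the standard estimator of cluster-randomized
trials — in a single pass and clamped to [0, 1].

The variance of the weighted mean uses the reliability-weights unbiased form
with the Kish effective sample size n_eff = 1/Σw²; it reduces to s²/n at
equal weights.

All functions also exist in a vectorized form (:func:`gene_profiles`)
operating on a sparse gene x cell block at once; the scalar operations are
the reference path and the vectorized path is tested against them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io import CellGroup

__all__ = [
    "GeneWeightProfile",
    "relative_expression",
    "estimate_icc",
    "cluster_weights",
    "weighted_mean",
    "weighted_mean_variance",
    "wdc",
    "gene_profile",
    "gene_profiles",
    "profiles_to_frame",
]


@dataclass
class GeneWeightProfile:
    """Weighting summary of one gene in one cell population."""

    rho: float
    weights: np.ndarray
    wdc: float  # NaN when undefined (all totals equal)
    mean_w: float
    var_mean: float
    n_eff: float


def relative_expression(counts: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Per-cell relative expression n_{Z,i} = N_{Z,i}/N_i."""
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if counts.shape != totals.shape:
        raise ValueError("counts and totals length mismatch")
    if np.any(totals <= 0):
        raise ValueError("zero-total cell included; pre-filter cells with N_i = 0")
    return counts / totals


def estimate_icc(counts: np.ndarray, totals: np.ndarray) -> float:
    """Fleiss–Donner one-way-ANOVA ICC for clustered binary outcomes.

    Cells are the clusters, cell totals the cluster sizes, and the per-cell
    gene proportion the cluster outcome rate.  Clamped to [0, 1]; a zero
    denominator (constant gene) yields 0.
    """
    counts = np.asarray(counts, dtype=float)
    totals = np.asarray(totals, dtype=float)
    k = counts.size
    if k < 2:
        raise ValueError("ICC needs at least 2 cells")
    if np.any(totals <= 0):
        raise ValueError("all cell totals must be positive")
    M = totals.sum()
    pbar = counts.sum() / M
    p = counts / totals
    msb = (totals * (p - pbar) ** 2).sum() / (k - 1)
    msw = (totals * p * (1.0 - p)).sum() / (M - k)
    n0 = (M - (totals**2).sum() / M) / (k - 1)
    den = msb + (n0 - 1.0) * msw
    if den == 0.0:
        return 0.0
    return float(np.clip((msb - msw) / den, 0.0, 1.0))


def cluster_weights(totals: np.ndarray, rho: float) -> np.ndarray:
    """Normalized per-cell weights w_i ∝ N_i / (1 + ρ (N_i − 1))."""
    totals = np.asarray(totals, dtype=float)
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    if np.any(totals <= 0):
        raise ValueError("all cell totals must be positive")
    u = totals / (1.0 + rho * (totals - 1.0))
    return u / u.sum()


def weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    """Σ w_i x_i (weights already normalized)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights length mismatch")
    return float(weights @ values)


def weighted_mean_variance(values: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Variance of the weighted mean and the Kish effective sample size.

    var_mean = [Σ w_i (x_i − x̄_w)²] · Σw_i² / (1 − Σw_i²),  n_eff = 1/Σw_i².
    Reduces to s²/n (unbiased s²) at equal weights.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape:
        raise ValueError("values and weights length mismatch")
    sw2 = float(weights @ weights)
    n_eff = 1.0 / sw2
    if values.size >= 2 and 1.0 - sw2 <= 0.0:
        raise ValueError("degenerate weights: all mass on one cell")
    if values.size < 2:
        return float("nan"), n_eff
    if np.ptp(values) == 0.0:  # constant gene: exactly zero, no fp residue
        return 0.0, n_eff
    xbar = weights @ values
    var = float((weights @ (values - xbar) ** 2) * sw2 / (1.0 - sw2))
    return var, n_eff


def wdc(weights: np.ndarray, totals: np.ndarray) -> float:
    """Weight distribution coefficient: Var(w) / Var(w_AC).

    Both variances are population variances; w_AC are the aggregate-count
    weights N_i/ΣN_i.  0 at uniform weights, 1 at aggregate-count weights.
    """
    weights = np.asarray(weights, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if weights.size < 2:
        raise ValueError("WDC needs at least 2 cells")
    w_ac = totals / totals.sum()
    var_ac = w_ac.var()
    if var_ac == 0.0:
        raise ValueError("WDC undefined: all cell totals equal")
    return float(weights.var() / var_ac)


def gene_profile(group: CellGroup, gene: str, rho: float | None = None) -> GeneWeightProfile:
    """Full weighting profile of one gene in one cell group.

    ``rho`` overrides the ICC estimate when given (e.g. 0 for spatial bins).
    """
    counts = group.matrix.gene_row(gene)[group.member_indices]
    totals = group.cell_totals
    if np.any(totals <= 0):
        raise ValueError("group contains zero-total cells")
    if rho is None:
        rho = estimate_icc(counts, totals)
    w = cluster_weights(totals, rho)
    n = relative_expression(counts, totals)
    mean_w = weighted_mean(n, w)
    var_mean, n_eff = weighted_mean_variance(n, w)
    try:
        wdc_val = wdc(w, totals)
    except ValueError:
        wdc_val = float("nan")
    return GeneWeightProfile(rho, w, wdc_val, mean_w, var_mean, n_eff)


# ---------------------------------------------------------------------------
# Vectorized engine
# ---------------------------------------------------------------------------

_CHUNK = 4096  # genes per dense block when expanding weights


def gene_profiles(
    counts: sp.spmatrix,
    totals: np.ndarray,
    rho: float | np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Vectorized per-gene weighting over a sparse gene x cell block.

    Parameters
    ----------
    counts : sparse matrix, genes x cells
    totals : per-cell totals N_i (positive)
    rho : None to estimate the ICC per gene, or a forced value/array.

    Returns a dict of per-gene arrays: rho, mean_w, var_mean, n_eff, wdc,
    agg (aggregate gene counts) — algebraically identical to composing the
    scalar operations gene by gene.
    """
    counts = sp.csr_matrix(counts)
    totals = np.asarray(totals, dtype=float)
    G, k = counts.shape
    if k != totals.size:
        raise ValueError("totals length does not match cell count")
    if k < 2:
        raise ValueError("need at least 2 cells")
    if np.any(totals <= 0):
        raise ValueError("all cell totals must be positive")

    M = totals.sum()
    inv_tot = 1.0 / totals
    agg = np.asarray(counts.sum(axis=1), dtype=float).ravel()
    csq = counts.astype(np.float64)
    csq.data **= 2
    sx2n = np.asarray(csq @ inv_tot).ravel()  # Σ N²_{Z,i}/N_i = Σ N_i p_i²
    del csq

    if rho is None:
        pbar = agg / M
        msb = (sx2n - M * pbar**2) / (k - 1)
        msw = (agg - sx2n) / (M - k)
        n0 = (M - (totals**2).sum() / M) / (k - 1)
        den = msb + (n0 - 1.0) * msw
        with np.errstate(invalid="ignore", divide="ignore"):
            rho_arr = np.where(den > 0, (msb - msw) / np.where(den != 0, den, 1.0), 0.0)
        rho_arr = np.clip(rho_arr, 0.0, 1.0)
    else:
        rho_arr = np.broadcast_to(np.asarray(rho, dtype=float), (G,)).copy()

    mean_w = np.empty(G)
    var_mean = np.empty(G)
    sw2_arr = np.empty(G)
    cf = counts.astype(np.float64)
    for lo in range(0, G, _CHUNK):
        hi = min(lo + _CHUNK, G)
        r = rho_arr[lo:hi, None]
        u = totals[None, :] / (1.0 + r * (totals[None, :] - 1.0))  # block x cells
        s = u.sum(axis=1)
        sw2 = (u**2).sum(axis=1) / s**2
        block = cf[lo:hi]
        # Σ w n = Σ_i [u_i/S] (X_i/N_i); sparse-friendly via X_i/(1+ρ(N_i−1))
        denom = 1.0 + r * (totals[None, :] - 1.0)
        # mean: Σ X_i / (1+ρ(N_i−1)) / S   (since u_i n_i = X_i/(1+ρ(N_i−1)))
        bd = block.toarray() if (hi - lo) * k <= 2**24 else None
        if bd is not None:
            mw = (bd / denom).sum(axis=1) / s
            swn2 = (bd**2 / (totals[None, :] * denom)).sum(axis=1) / s  # Σ w n²
        else:  # pragma: no cover - very large blocks
            mw = np.asarray((block.multiply(1.0 / denom)).sum(axis=1)).ravel() / s
            sq = block.copy()
            sq.data **= 2
            swn2 = np.asarray(sq.multiply(1.0 / (totals[None, :] * denom)).sum(axis=1)).ravel() / s
        mean_w[lo:hi] = mw
        var_mean[lo:hi] = np.maximum(swn2 - mw**2, 0.0) * sw2 / (1.0 - sw2)
        sw2_arr[lo:hi] = sw2

    # WDC from Σw² only: population Var(w) = Σw²/k − 1/k² when Σw = 1.
    w_ac = totals / M
    var_ac = w_ac.var()
    if var_ac == 0.0:
        wdc_arr = np.full(G, np.nan)
    else:
        wdc_arr = (sw2_arr / k - 1.0 / k**2) / var_ac
    return {
        "rho": rho_arr,
        "mean_w": mean_w,
        "var_mean": var_mean,
        "n_eff": 1.0 / sw2_arr,
        "wdc": wdc_arr,
        "agg": agg,
    }


def profiles_to_frame(gene_ids: np.ndarray, profiles: dict[str, np.ndarray]):
    """Exportable per-gene table (gene, rho, wdc, mean_w, var_mean, n_eff)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "gene": np.asarray(gene_ids, dtype=str),
            "rho": profiles["rho"],
            "wdc": profiles["wdc"],
            "mean_w": profiles["mean_w"],
            "var_mean": profiles["var_mean"],
            "n_eff": profiles["n_eff"],
        }
    )
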