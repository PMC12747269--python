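"""Bin-level differential expression for sequencing-based spatial assays.

Spatial bins carry far fewer transcripts than cells and mix material from
overlapping cells, so the aggregate-count approximation (ρ_Z = 0 for every
gene) is used for the weights, and the weighted-t / χ² p-values — expected
to be close at low counts per bin — are combined with the conservative
``max`` rule by default.  Bins are quality-filtered on feature count,
non-structural counts, mitochondrial fraction and marker-gene fraction
before testing; spatial coordinates are not needed and are ignored (bin
selections arrive as barcode lists).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CellGroup, CountMatrix
from .two_group import CombinationPolicy, DGEConfig, run_dge

__all__ = ["BinQCConfig", "bin_qc_filter", "spatial_dge"]


@dataclass
class BinQCConfig:
    """Bin quality-control thresholds.

    Defaults mirror a growth-plate chondrocyte selection: > 20 detected
    features per bin, > 100 counts outside the structural collagens Col1a1
    and Col1a2, mitochondrial fraction within [0.1%, 5%] of bin UMI, and
    Col2a1 above 5% of bin UMI.
    """

    min_features: int = 20
    min_counts_excluding: tuple[int, list[str]] = (100, None)  # type: ignore[assignment]
    mito_fraction_range: tuple[float, float] = (0.001, 0.05)
    mito_gene_rule: str = "mt-"  # case-insensitive id prefix
    marker_min_fraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        thr, excl = self.min_counts_excluding
        if excl is None:
            self.min_counts_excluding = (thr, [])
        lo, hi = self.mito_fraction_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("mito fraction range must satisfy 0 <= lo < hi <= 1")
        if self.min_features < 0 or thr < 0:
            raise ValueError("thresholds must be >= 0")


def bin_qc_filter(cm: CountMatrix, qc: BinQCConfig, label: str = "qc_pass") -> CellGroup:
    """Bins passing *all* QC criteria as a :class:`CellGroup`.

    Feature count is the number of genes with nonzero count in the bin; all
    fractions are relative to bin total UMI.  ">" criteria are strict; the
    mitochondrial band is inclusive.  Unknown gene ids in the config raise.
    """
    totals = cm.cell_totals.astype(float)
    ok = totals > 0

    n_features = np.asarray((cm.counts > 0).sum(axis=0)).ravel()
    ok &= n_features > qc.min_features

    thr, excluded = qc.min_counts_excluding
    excl_counts = np.zeros(cm.n_cells)
    for g in excluded:
        excl_counts += cm.gene_row(g)  # raises KeyError on unknown id
    ok &= (totals - excl_counts) > thr

    mito_mask = np.char.startswith(np.char.lower(cm.gene_ids), qc.mito_gene_rule.lower())
    mito = np.asarray(cm.counts[mito_mask].sum(axis=0)).ravel() if mito_mask.any() else np.zeros(cm.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / totals, 0.0)
    lo, hi = qc.mito_fraction_range
    ok &= (mito_frac >= lo) & (mito_frac <= hi)

    for gene, min_frac in qc.marker_min_fraction.items():
        frac = np.where(totals > 0, cm.gene_row(gene) / totals, 0.0)
        ok &= frac > min_frac

    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise ValueError("no bins pass QC")
    return CellGroup(cm, idx, label)


def spatial_dge(
    group_a: CellGroup,
    group_b: CellGroup,
    config: DGEConfig | None = None,
    genes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Two-group DGE with spatial conventions.

    Identical to :func:`wdge.two_group.run_dge` but with ρ forced to 0 in
    both groups, a 10% detection-fraction filter and the conservative
    ``max`` p-value combination by default.
    """
    if config is None:
        config = DGEConfig(
            detection_fraction=0.10,
            policy=CombinationPolicy(mode="max"),
        )
    config.rho_override = 0.0
    return run_dge(group_a, group_b, config, genes=genes)
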