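"""Count-matrix IO, cell-group selection, and gene filters.

UMI count matrices are held as sparse gene x cell integer matrices with
gene and barcode identifiers.  Readers accept the 10x-style Matrix Market
triplet (``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``, optionally
gzipped) and dense TSV; the method operates on raw UMI counts, so readers
reject non-integral values.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "CellGroup",
    "MarkerRule",
    "read_10x_mtx",
    "write_counts",
    "read_dense_tsv",
    "write_dense_tsv",
    "read_barcode_list",
    "select_group",
    "select_group_by_barcodes",
    "filter_genes_min_total",
    "detection_fraction_filter",
]

_INT_TOL = 1e-9


def _make_unique(names: np.ndarray) -> np.ndarray:
    """Deduplicate ids deterministically by suffixing ".1", ".2", ..."""
    seen: dict[str, int] = {}
    out = np.empty(len(names), dtype=object)
    for j, name in enumerate(names):
        k = seen.get(name, 0)
        out[j] = name if k == 0 else f"{name}.{k}"
        seen[name] = k + 1
    return out.astype(str)


@dataclass
class CountMatrix:
    """Sparse non-negative integer gene x cell (or bin) UMI count matrix.

    Attributes
    ----------
    counts : scipy.sparse.csr_matrix
        Genes as rows, cells as columns, integer dtype.
    gene_ids, barcodes : ndarray of str
        Unique row / column identifiers.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    barcodes: np.ndarray
    _cell_totals: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if np.any(np.abs(data - np.round(data)) > _INT_TOL):
                raise ValueError("count matrix contains non-integer values")
            self.counts = self.counts.astype(np.int64)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("count matrix contains negative values")
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.barcodes = np.asarray(self.barcodes, dtype=str)
        if self.counts.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError(
                "dimension mismatch: matrix is %s but %d gene ids and %d barcodes given"
                % (self.counts.shape, len(self.gene_ids), len(self.barcodes))
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_totals(self) -> np.ndarray:
        """Per-cell total counts N_i (cached)."""
        if self._cell_totals is None:
            self._cell_totals = np.asarray(self.counts.sum(axis=0)).ravel()
        return self._cell_totals

    def gene_index(self, gene_id: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene_id)
        if idx.size == 0:
            raise KeyError(f"unknown gene id: {gene_id}")
        return int(idx[0])

    def gene_row(self, gene_id: str) -> np.ndarray:
        """Dense per-cell counts of one gene."""
        return np.asarray(self.counts[self.gene_index(gene_id)].todense()).ravel()

    def subset_cells(self, indices: Sequence[int]) -> "CountMatrix":
        indices = np.asarray(indices, dtype=int)
        return CountMatrix(self.counts[:, indices], self.gene_ids, self.barcodes[indices])


@dataclass
class CellGroup:
    """A labelled subset of cell columns of a :class:`CountMatrix`."""

    matrix: CountMatrix
    member_indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.member_indices, dtype=int)
        if idx.size == 0:
            raise ValueError("empty cell group")
        if len(np.unique(idx)) != idx.size:
            raise ValueError("duplicate indices in cell group")
        if idx.min() < 0 or idx.max() >= self.matrix.n_cells:
            raise ValueError("cell index out of bounds")
        self.member_indices = np.sort(idx)

    @property
    def n_cells(self) -> int:
        return self.member_indices.size

    @property
    def counts(self) -> sp.csr_matrix:
        return self.matrix.counts[:, self.member_indices]

    @property
    def cell_totals(self) -> np.ndarray:
        return self.matrix.cell_totals[self.member_indices]


@dataclass
class MarkerRule:
    """Select cells with nonzero counts for every listed marker gene."""

    genes: list[str]
    mode: str = "all_nonzero"

    def __post_init__(self) -> None:
        if self.mode != "all_nonzero":
            raise ValueError(f"unsupported marker mode: {self.mode}")
        if not self.genes:
            raise ValueError("marker rule needs at least one gene")


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find_file(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing file: {directory}/{stem}[.gz]")


def _read_id_column(path: Path) -> tuple[np.ndarray, np.ndarray | None]:
    """First column = id, second (if present) = name."""
    ids, names = [], []
    with _open_maybe_gz(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            ids.append(parts[0])
            names.append(parts[1] if len(parts) > 1 else parts[0])
    if not ids:
        raise ValueError(f"empty id file: {path}")
    return np.array(ids, dtype=str), np.array(names, dtype=str)


def read_10x_mtx(directory: str | Path) -> CountMatrix:
    """Read a 10x-style MTX triplet directory into a :class:`CountMatrix`.

    Genes end up as rows and cells as columns regardless of the on-disk
    orientation (resolved against the lengths of the id files).  Both
    "integer" and "real" Matrix Market headers are accepted, but values
    must be integral to 1e-9.  Duplicate feature ids are deduplicated with
    ".1", ".2", ... suffixes.
    """
    directory = Path(directory)
    mtx_path = _find_file(directory, "matrix.mtx")
    feat_path = _find_file(directory, "features.tsv")
    bc_path = _find_file(directory, "barcodes.tsv")

    with _open_maybe_gz(mtx_path, "rb") as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)
    gene_ids, _ = _read_id_column(feat_path)
    barcodes, _ = _read_id_column(bc_path)

    if mat.shape == (len(gene_ids), len(barcodes)):
        pass
    elif mat.shape == (len(barcodes), len(gene_ids)):
        mat = mat.T.tocsr()
    else:
        raise ValueError(
            "dimension mismatch: matrix %s vs %d features, %d barcodes"
            % (mat.shape, len(gene_ids), len(barcodes))
        )
    gene_ids = _make_unique(gene_ids)
    barcodes = _make_unique(barcodes)
    return CountMatrix(mat, gene_ids, barcodes)


def write_counts(cm: CountMatrix, directory: str | Path) -> None:
    """Write a :class:`CountMatrix` as an uncompressed 10x MTX triplet."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), cm.counts.tocoo(), field="integer")
    with open(directory / "features.tsv", "w") as fh:
        for g in cm.gene_ids:
            fh.write(f"{g}\t{g}\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        for b in cm.barcodes:
            fh.write(f"{b}\n")


def read_dense_tsv(path: str | Path) -> CountMatrix:
    """Read a dense TSV (genes as rows, header row = barcodes)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.all(np.abs(values - np.round(values)) <= _INT_TOL):
        raise ValueError("count matrix contains non-integer values")
    return CountMatrix(
        sp.csr_matrix(np.round(values).astype(np.int64)),
        np.array(df.index, dtype=str),
        np.array(df.columns, dtype=str),
    )


def write_dense_tsv(cm: CountMatrix, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        cm.counts.toarray(), index=cm.gene_ids, columns=cm.barcodes
    ).to_csv(path, sep="\t")


def read_barcode_list(path: str | Path) -> list[str]:
    """One barcode per line; blank lines ignored."""
    with _open_maybe_gz(Path(path)) as fh:
        return [line.strip() for line in fh if line.strip()]


def select_group(cm: CountMatrix, rule: MarkerRule, label: str = "") -> CellGroup:
    """Cells with nonzero counts for *every* marker gene of the rule."""
    mask = np.ones(cm.n_cells, dtype=bool)
    for gene in rule.genes:
        mask &= cm.gene_row(gene) > 0
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("marker rule selects no cells")
    return CellGroup(cm, idx, label or "+".join(rule.genes))


def select_group_by_barcodes(cm: CountMatrix, barcodes: Iterable[str], label: str = "") -> CellGroup:
    wanted = set(barcodes)
    idx = np.flatnonzero(np.isin(cm.barcodes, list(wanted)))
    if idx.size == 0:
        raise ValueError("no matching barcodes")
    return CellGroup(cm, idx, label)


def _group_columns(cm: CountMatrix, groups: Sequence[CellGroup] | None) -> np.ndarray:
    if not groups:
        return np.arange(cm.n_cells)
    cols = np.unique(np.concatenate([g.member_indices for g in groups]))
    return cols


def filter_genes_min_total(
    cm: CountMatrix, groups: Sequence[CellGroup] | None = None, min_total: int = 30
) -> np.ndarray:
    """Genes with total count strictly greater than ``min_total`` across the
    referenced cells (union of the groups; all cells if none given)."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    cols = _group_columns(cm, groups)
    totals = np.asarray(cm.counts[:, cols].sum(axis=1)).ravel()
    return np.flatnonzero(totals > min_total)


def detection_fraction_filter(
    cm: CountMatrix, groups: Sequence[CellGroup] | None = None, min_frac: float = 0.10
) -> np.ndarray:
    """Genes detected (nonzero) in at least ``min_frac`` of the cells of each
    group (per-group criterion; all cells as one group if none given)."""
    if not 0.0 <= min_frac <= 1.0:
        raise ValueError("min_frac must be in [0, 1]")
    if not groups:
        groups = [CellGroup(cm, np.arange(cm.n_cells), "all")]
    mask = np.ones(cm.n_genes, dtype=bool)
    for g in groups:
        sub = cm.counts[:, g.member_indices]
        det = np.asarray((sub > 0).sum(axis=1)).ravel() / g.n_cells
        mask &= det >= min_frac
    return np.flatnonzero(mask)
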