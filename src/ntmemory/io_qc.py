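"""Single-cell count matrix container, 10x-style MTX I/O, and cell-level QC.

The container is genes x cells (10x convention); every other module in the
package consumes this orientation. QC follows the strict-inequality
convention: a cell is kept when its totals are strictly above the lower
bounds and, where upper bounds are set, strictly below them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .exceptions import FormatError

__all__ = [
    "CountMatrix",
    "QCThresholds",
    "QCReport",
    "read_10x_mtx",
    "write_10x_mtx",
    "read_cell_meta",
    "write_cell_meta",
    "compute_cell_metrics",
    "qc_filter",
]

META_COLUMNS = ("cell_id", "condition", "batch", "cluster")


@dataclass
class CountMatrix:
    """UMI counts, genes x cells.

    Parameters
    ----------
    gene_ids : array of unique gene identifiers (rows).
    cell_ids : array of unique cell barcodes (columns).
    counts : sparse genes x cells matrix of nonnegative integers.
    gene_symbols : optional display symbols, aligned with ``gene_ids``.
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    counts: sp.csr_matrix
    gene_symbols: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        if len(np.unique(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene identifiers")
        if len(np.unique(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell barcodes")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.floor(data))):
            raise FormatError("counts must be nonnegative integers")
        self.counts.data = data.astype(np.int64, copy=False)
        if self.gene_symbols is not None:
            self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
            if len(self.gene_symbols) != len(self.gene_ids):
                raise FormatError("gene_symbols length does not match gene_ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_totals(self) -> np.ndarray:
        """Total UMIs per cell (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with nonzero count per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        """New matrix restricted to the given cell positions (order preserved)."""
        return CountMatrix(
            gene_ids=self.gene_ids.copy(),
            cell_ids=self.cell_ids[index].copy(),
            counts=self.counts[:, index].copy(),
            gene_symbols=None if self.gene_symbols is None else self.gene_symbols.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Dense genes x cells DataFrame (small matrices only)."""
        return pd.DataFrame(
            self.counts.toarray(), index=self.gene_ids, columns=self.cell_ids
        )


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC bounds; lower bounds are exclusive (strict ``>``).

    Defaults keep cells with >6,000 UMIs and >2,000 detected genes, the
    filter that defines the retained high-quality cell set; the range-style
    alternative (e.g. 3-6k genes with 80-500k UMIs) is expressible through
    the optional upper bounds.
    """

    min_umi: int = 6000
    min_genes: int = 2000
    max_umi: Optional[int] = None
    max_genes: Optional[int] = None

    def __post_init__(self) -> None:
        if self.min_umi < 0 or self.min_genes < 0:
            raise ValueError("lower QC bounds must be nonnegative")
        if self.max_umi is not None and self.max_umi <= self.min_umi:
            raise ValueError("max_umi must exceed min_umi")
        if self.max_genes is not None and self.max_genes <= self.min_genes:
            raise ValueError("max_genes must exceed min_genes")


@dataclass
class QCReport:
    per_cell: pd.DataFrame  # cell_id, total_umis, detected_genes, kept
    n_in: int
    n_kept: int
    n_discarded: int
    per_batch: Optional[pd.DataFrame] = None
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        assert self.n_in == self.n_kept + self.n_discarded


def _find(path: Path, stem: str, alts: tuple[str, ...] = ()) -> Path:
    for name in (stem, stem + ".gz", *alts, *[a + ".gz" for a in alts]):
        p = path / name
        if p.exists():
            return p
    raise FormatError(f"missing file {stem}[.gz] in {path}")


def read_10x_mtx(path: str | Path) -> CountMatrix:
    """Read a 10x-style MTX triplet directory (plain or gzipped).

    Expects ``matrix.mtx``, ``barcodes.tsv`` and ``features.tsv`` (or
    ``genes.tsv``). The matrix header dimensions must match the barcode and
    feature files; entries must be nonnegative integers.
    """
    path = Path(path)
    mtx_file = _find(path, "matrix.mtx")
    bc_file = _find(path, "barcodes.tsv")
    ft_file = _find(path, "features.tsv", alts=("genes.tsv",))

    mat = scipy.io.mmread(str(mtx_file))
    barcodes = pd.read_csv(bc_file, sep="\t", header=None, dtype=str)[0].to_numpy()
    features = pd.read_csv(ft_file, sep="\t", header=None, dtype=str)
    gene_ids = features[0].to_numpy()
    gene_symbols = features[1].to_numpy() if features.shape[1] > 1 else None

    if mat.shape[0] != len(gene_ids):
        raise FormatError(
            f"{mtx_file.name} declares {mat.shape[0]} genes but "
            f"{ft_file.name} has {len(gene_ids)} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{mtx_file.name} declares {mat.shape[1]} cells but "
            f"{bc_file.name} has {len(barcodes)} rows"
        )
    data = np.asarray(mat.data if sp.issparse(mat) else mat)
    if data.size and np.any(data != np.floor(data)):
        raise FormatError(f"{mtx_file.name} contains non-integer entries")
    if len(np.unique(barcodes)) != len(barcodes):
        raise FormatError(f"{bc_file.name} contains duplicate barcodes")
    if len(np.unique(gene_ids)) != len(gene_ids):
        raise FormatError(f"{ft_file.name} contains duplicate gene identifiers")
    return CountMatrix(gene_ids, barcodes, sp.csr_matrix(mat), gene_symbols)


def write_10x_mtx(m: CountMatrix, path: str | Path) -> None:
    """Write a plain-text MTX triplet (always uncompressed, for diffability)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    coo = m.counts.tocoo()
    scipy.io.mmwrite(str(path / "matrix.mtx"), coo, field="integer")
    pd.Series(m.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)
    symbols = m.gene_symbols if m.gene_symbols is not None else m.gene_ids
    pd.DataFrame({"id": m.gene_ids, "symbol": symbols}).to_csv(
        path / "features.tsv", sep="\t", index=False, header=False
    )


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    """Read a cell-metadata TSV with required columns cell_id, condition, batch, cluster."""
    meta = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "condition": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if meta["cell_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate cell_id entries")
    return meta


def write_cell_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def compute_cell_metrics(m: CountMatrix) -> pd.DataFrame:
    """Per-cell total UMIs (column sum) and detected genes (nonzero entries)."""
    return pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "total_umis": m.cell_totals(),
            "detected_genes": m.genes_detected(),
        }
    )


def qc_filter(
    m: CountMatrix,
    thresholds: QCThresholds = QCThresholds(),
    meta: Optional[pd.DataFrame] = None,
) -> tuple[CountMatrix, QCReport]:
    """Keep cells passing all QC bounds; gene order is never touched.

    Zero surviving cells is reported as a warning, not an error. When
    ``meta`` is supplied a per-batch breakdown is included in the report.
    """
    metrics = compute_cell_metrics(m)
    keep = (metrics["total_umis"] > thresholds.min_umi) & (
        metrics["detected_genes"] > thresholds.min_genes
    )
    if thresholds.max_umi is not None:
        keep &= metrics["total_umis"] < thresholds.max_umi
    if thresholds.max_genes is not None:
        keep &= metrics["detected_genes"] < thresholds.max_genes
    metrics["kept"] = keep.to_numpy()

    per_batch = None
    if meta is not None:
        joined = metrics.merge(meta[["cell_id", "batch"]], on="cell_id", how="left")
        per_batch = (
            joined.groupby("batch", dropna=False)["kept"]
            .agg(cells_in="size", cells_kept="sum")
            .reset_index()
        )

    kept_idx = np.flatnonzero(metrics["kept"].to_numpy())
    filtered = m.subset_cells(kept_idx)
    warning = "no cells passed QC" if len(kept_idx) == 0 else None
    report = QCReport(
        per_cell=metrics,
        n_in=m.n_cells,
        n_kept=len(kept_idx),
        n_discarded=m.n_cells - len(kept_idx),
        per_batch=per_batch,
        warning=warning,
    )
    return filtered, report
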