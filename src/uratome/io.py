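"""Readers, writers and validated in-memory containers.

Count matrices travel as matrix-market coordinate files with two one-column
text sidecars (cell ids and gene symbols), or as dense delimited tables for
small inputs.  All other artifacts — transporter catalog, marker sets, symbol
maps, per-cell metadata, result tables — are TSV with a header row.

Gene symbols are upper-cased on ingest (HGNC convention) so marker and
catalog lookups are case-insensitive.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .transportome import TransporterCatalog, default_catalog

__all__ = [
    "ValidationError",
    "REGIONS",
    "CountMatrix",
    "NormalizedMatrix",
    "read_count_matrix",
    "write_count_matrix",
    "apply_symbol_map",
    "read_catalog",
    "read_symbol_map",
    "read_marker_table",
    "read_cell_meta",
    "write_table",
    "default_region_markers",
    "default_pt_segment_markers",
]


class ValidationError(ValueError):
    """Raised when an external artifact violates its contract."""


#: Anatomical region vocabulary.  ``PT`` is the coarse proximal-tubule label
#: produced by marker-based cluster annotation before the clusters are split
#: into the S1/S2/S3 segments.
REGIONS = (
    "Podo",
    "PT",
    "PT_S1",
    "PT_S2",
    "PT_S3",
    "LOH_DL",
    "LOH_AL",
    "DCT",
    "CNT",
    "PC",
    "ICA",
    "ICB",
    "EDC",
    "MGC",
    "PEC",
    "unassigned",
)


def _check_axis(ids, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if ids.size != len(set(ids)):
        counts = pd.Series(ids).value_counts()
        dups = counts[counts > 1].index.tolist()
        raise ValidationError(f"duplicate {what}(s): {dups}")
    return ids


@dataclasses.dataclass
class CountMatrix:
    """Raw counts, cells x genes, with unique cell ids and gene symbols."""

    cell_ids: np.ndarray
    gene_symbols: np.ndarray
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.cell_ids = _check_axis(self.cell_ids, "cell id")
        genes = np.asarray([str(g).upper() for g in self.gene_symbols], dtype=object)
        self.gene_symbols = _check_axis(genes, "gene symbol")
        m = sp.csr_matrix(self.counts)
        if m.shape != (len(self.cell_ids), len(self.gene_symbols)):
            raise ValidationError(
                f"matrix shape {m.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.gene_symbols)} genes"
            )
        if m.nnz and m.data.min() < 0:
            raise ValidationError("negative counts present")
        if m.nnz and np.any(m.data != np.round(m.data)):
            raise ValidationError("non-integer counts present")
        m.data = m.data.astype(np.int64)
        m.eliminate_zeros()
        self.counts = m

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    def total_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def subset_cells(self, cell_ids) -> "CountMatrix":
        idx = pd.Index(self.cell_ids).get_indexer(np.asarray(cell_ids, dtype=object))
        if (idx < 0).any():
            missing = np.asarray(cell_ids, dtype=object)[idx < 0]
            raise KeyError(f"unknown cell id(s): {missing[:5].tolist()}")
        return CountMatrix(
            np.asarray(cell_ids, dtype=object),
            self.gene_symbols.copy(),
            self.counts[idx],
        )


@dataclasses.dataclass
class NormalizedMatrix:
    """Log-normalized expression with the same axes as a :class:`CountMatrix`.

    Values are ln(1 + count * scale_factor / cell_total): zero exactly where
    the count is zero, strictly increasing with the count within a cell.
    """

    cell_ids: np.ndarray
    gene_symbols: np.ndarray
    values: sp.csr_matrix
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        self.cell_ids = _check_axis(self.cell_ids, "cell id")
        self.gene_symbols = _check_axis(
            np.asarray([str(g).upper() for g in self.gene_symbols], dtype=object),
            "gene symbol",
        )
        v = sp.csr_matrix(self.values, dtype=np.float64)
        if v.shape != (len(self.cell_ids), len(self.gene_symbols)):
            raise ValidationError("normalized matrix shape inconsistent with axes")
        self.values = v

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    def subset_cells(self, cell_ids) -> "NormalizedMatrix":
        idx = pd.Index(self.cell_ids).get_indexer(np.asarray(cell_ids, dtype=object))
        if (idx < 0).any():
            missing = np.asarray(cell_ids, dtype=object)[idx < 0]
            raise KeyError(f"unknown cell id(s): {missing[:5].tolist()}")
        return NormalizedMatrix(
            np.asarray(cell_ids, dtype=object),
            self.gene_symbols.copy(),
            self.values[idx],
            self.scale_factor,
        )


def _sidecar_paths(matrix_path: Path) -> tuple[Path, Path]:
    stem = matrix_path.with_suffix("")
    return Path(f"{stem}.cells.txt"), Path(f"{stem}.genes.txt")


def read_count_matrix(
    path,
    format: str = "mtx_triplet",
    *,
    cells_in_rows: bool | None = None,
    cells_path=None,
    genes_path=None,
) -> CountMatrix:
    """Read a count matrix from disk.

    Parameters
    ----------
    path
        The ``.mtx`` file (``mtx_triplet``) or the delimited table
        (``delimited_dense``; ``.tsv`` -> tab, otherwise comma).
    format
        ``"mtx_triplet"`` or ``"delimited_dense"``.
    cells_in_rows
        Orientation of the source.  Defaults to ``False`` for matrix-market
        (genes in rows, the deposited-data convention) and ``True`` for dense
        tables.  The returned matrix is always cells x genes.
    cells_path, genes_path
        Sidecar name files for ``mtx_triplet``; default to
        ``<stem>.cells.txt`` and ``<stem>.genes.txt`` next to the matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx_triplet":
        if cells_in_rows is None:
            cells_in_rows = False
        default_cells, default_genes = _sidecar_paths(path)
        cells_path = Path(cells_path) if cells_path else default_cells
        genes_path = Path(genes_path) if genes_path else default_genes
        for p, what in ((cells_path, "cell"), (genes_path, "gene")):
            if not p.exists():
                raise FileNotFoundError(f"missing {what}-name sidecar {p}")
        try:
            m = mmread(path)
        except ValueError as e:
            raise ValidationError(f"malformed matrix-market file {path}: {e}") from e
        cell_ids = np.loadtxt(cells_path, dtype=str, ndmin=1).astype(object)
        gene_symbols = np.loadtxt(genes_path, dtype=str, ndmin=1).astype(object)
        m = sp.csr_matrix(m if cells_in_rows else m.T)
        return CountMatrix(cell_ids, gene_symbols, m)
    if format == "delimited_dense":
        if cells_in_rows is None:
            cells_in_rows = True
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if not cells_in_rows:
            df = df.T
        return CountMatrix(
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
            sp.csr_matrix(df.to_numpy()),
        )
    raise ValueError(f"unknown format {format!r}")


def write_count_matrix(m: CountMatrix, path, format: str = "mtx_triplet") -> Path:
    """Write a count matrix; the inverse of :func:`read_count_matrix`.

    ``mtx_triplet`` writes genes in rows (the deposited-data convention) plus
    the two name sidecars.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "mtx_triplet":
        mmwrite(str(path), sp.coo_matrix(m.counts.T), field="integer")
        cells_path, genes_path = _sidecar_paths(path)
        cells_path.write_text("\n".join(map(str, m.cell_ids)) + "\n")
        genes_path.write_text("\n".join(map(str, m.gene_symbols)) + "\n")
        return path
    if format == "delimited_dense":
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
        df = pd.DataFrame(
            m.counts.toarray(), index=m.cell_ids, columns=m.gene_symbols
        )
        df.to_csv(path, sep=sep)
        return path
    raise ValueError(f"unknown format {format!r}")


def apply_symbol_map(m: CountMatrix, symbol_map) -> tuple[CountMatrix, int]:
    """Rename the gene axis through a (many-to-one) source-id -> symbol map.

    Rows mapping to the same target symbol are summed; source ids absent from
    the map are retained verbatim (so QC totals are unaffected by mapping
    coverage) and their number is returned and warned about.

    Parameters
    ----------
    symbol_map
        Mapping ``source_id -> target_symbol`` or a DataFrame with columns
        ``source_id`` and ``target_symbol``.

    Returns
    -------
    (CountMatrix, int)
        The renamed matrix and the count of unmapped source ids.
    """
    if isinstance(symbol_map, pd.DataFrame):
        symbol_map = dict(
            zip(symbol_map["source_id"].astype(str), symbol_map["target_symbol"].astype(str))
        )
    if not symbol_map:
        raise ValidationError("empty symbol map")
    symbol_map = {str(k).upper(): str(v).upper() for k, v in symbol_map.items()}

    n_unmapped = 0
    targets = []
    for g in m.gene_symbols:
        t = symbol_map.get(g)
        if t is None:
            n_unmapped += 1
            t = g
        targets.append(t)
    if n_unmapped:
        warnings.warn(f"{n_unmapped} gene identifier(s) not covered by the symbol map; kept as-is")

    new_genes = pd.unique(np.asarray(targets, dtype=object))
    col = pd.Index(new_genes).get_indexer(targets)
    # grouping matrix G (old genes x new genes): counts @ G sums duplicates
    g_mat = sp.csr_matrix(
        (np.ones(len(targets), dtype=np.int64), (np.arange(len(targets)), col)),
        shape=(len(targets), len(new_genes)),
    )
    summed = sp.csr_matrix(m.counts @ g_mat)
    return CountMatrix(m.cell_ids.copy(), new_genes, summed), n_unmapped


def read_catalog(path) -> TransporterCatalog:
    """Read a transporter catalog TSV (gene, side, direction[, km_uM])."""
    try:
        return TransporterCatalog.from_tsv(path)
    except ValueError as e:
        raise ValidationError(str(e)) from e


def read_symbol_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"source_id", "target_symbol"} - set(df.columns)
    if missing:
        raise ValidationError(f"symbol map missing columns: {sorted(missing)}")
    if df["source_id"].duplicated().any():
        dups = df.loc[df["source_id"].duplicated(), "source_id"].tolist()
        raise ValidationError(f"symbol map is not many-to-one; duplicated source ids: {dups}")
    return df


def read_marker_table(path, region_column: str = "region") -> pd.DataFrame:
    """Read a marker table TSV with columns (region|segment, gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {region_column, "gene"} - set(df.columns)
    if missing:
        raise ValidationError(f"marker table missing columns: {sorted(missing)}")
    df["gene"] = df["gene"].str.upper()
    return df


def read_cell_meta(path) -> pd.DataFrame:
    """Read per-cell metadata TSV: cell_id, dataset_id[, cluster_id, region]."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = {"cell_id", "dataset_id"} - set(df.columns)
    if missing:
        raise ValidationError(f"cell metadata missing columns: {sorted(missing)}")
    if df["cell_id"].duplicated().any():
        dups = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValidationError(f"duplicate cell id(s) in metadata: {dups[:5]}")
    if "region" not in df.columns:
        df["region"] = "unassigned"
    bad = set(df["region"]) - set(REGIONS)
    if bad:
        raise ValidationError(f"unknown region label(s): {sorted(bad)}")
    return df


def write_table(df: pd.DataFrame, path, header_comment: str | None = None) -> Path:
    """Write a result table as TSV, optionally with a leading comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def _packaged(name: str) -> pd.DataFrame:
    from importlib import resources

    with resources.as_file(resources.files("uratome.data").joinpath(name)) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def default_region_markers() -> pd.DataFrame:
    """Packaged default marker genes per anatomical region (region, gene)."""
    return _packaged("region_markers.tsv")


def default_pt_segment_markers() -> pd.DataFrame:
    """Packaged default S1/S3 proximal-tubule segment markers (segment, gene)."""
    return _packaged("pt_segment_markers.tsv")
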