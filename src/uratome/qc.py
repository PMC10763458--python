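"""Cell-level quality control and log-normalization.

Low-quality nuclei are removed on three per-cell metrics before any
expression analysis: the mitochondrial count fraction (high values indicate
dying or broken cells), and the number of detected genes, bounded below to
exclude empty droplets and above to exclude doublets/multiplets.  The upper
gene-count bound is per dataset because droplet chemistry and depth differ
between runs.

Boundary semantics are deliberately literal: a cell is removed when its
mitochondrial fraction is strictly greater than the threshold, or its
detected-gene count is strictly less than the minimum or strictly greater
than the maximum.  Cells sitting exactly on a boundary are kept.

Normalization is the per-cell "LogNormalize" rule: counts are scaled to a
fixed per-cell total (default 10,000) and natural-log transformed as
ln(1 + x).  Gene positivity downstream is defined on this scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, NormalizedMatrix, ValidationError

__all__ = ["QCThresholds", "compute_qc", "filter_cells", "lognormalize"]


@dataclass(frozen=True)
class QCThresholds:
    """Cell-filter thresholds.

    ``max_genes`` may be a single integer applied to every cell or a mapping
    ``dataset_id -> int``; with a mapping, an optional ``"default"`` key
    covers datasets not listed explicitly.
    """

    max_pct_mito: float = 0.05
    min_genes: int = 200
    max_genes: int | Mapping[str, int] = 6000

    def __post_init__(self) -> None:
        if not 0 <= self.max_pct_mito <= 1:
            raise ValueError("max_pct_mito must be a fraction in [0, 1]")
        limits = (
            [self.max_genes]
            if isinstance(self.max_genes, int)
            else list(self.max_genes.values())
        )
        if any(self.min_genes >= mx for mx in limits):
            raise ValueError("min_genes must be below every max_genes threshold")

    def resolve_max_genes(self, dataset_id: str) -> int:
        if isinstance(self.max_genes, int):
            return self.max_genes
        if dataset_id in self.max_genes:
            return int(self.max_genes[dataset_id])
        if "default" in self.max_genes:
            return int(self.max_genes["default"])
        raise ValidationError(
            f"no max_genes threshold for dataset {dataset_id!r} and no default"
        )


def compute_qc(m: CountMatrix, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell QC metrics.

    Returns a DataFrame with one row per cell: ``cell_id``, ``n_genes``
    (genes with count > 0), ``total_counts``, and ``pct_mito`` (mitochondrial
    counts / total counts, 0 for an empty cell).  Mitochondrial genes are
    identified by symbol prefix (default ``MT-``).
    """
    if not mito_prefix:
        raise ValueError("mito_prefix must be nonempty")
    counts = sp.csr_matrix(m.counts)
    n_genes = np.diff(counts.indptr)
    total = np.asarray(counts.sum(axis=1)).ravel()
    is_mito = np.array(
        [g.startswith(mito_prefix.upper()) for g in m.gene_symbols], dtype=bool
    )
    mito_total = np.asarray(counts[:, is_mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore"):
        pct = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "n_genes": n_genes.astype(int),
            "total_counts": total.astype(int),
            "pct_mito": pct,
        }
    )


#: Rejection reasons, in the order rules are checked; a removed cell reports
#: the first rule it fails.
_RULES = ("max_pct_mito", "min_genes", "max_genes")


def filter_cells(
    m: CountMatrix,
    qc: pd.DataFrame,
    thresholds: QCThresholds,
    dataset_ids: pd.Series | Mapping[str, str] | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Apply the QC thresholds; return the surviving matrix and a rejection report.

    A cell is kept iff pct_mito <= max_pct_mito and
    min_genes <= n_genes <= max_genes(dataset).  The report lists each
    removed cell with its dataset and the first failing rule (checked in the
    order mito, min_genes, max_genes).

    ``dataset_ids`` maps cell_id -> dataset_id and is required when
    ``thresholds.max_genes`` is per-dataset.
    """
    qc = qc.set_index("cell_id").reindex(m.cell_ids)
    if qc[["n_genes", "pct_mito"]].isna().any().any():
        raise ValidationError("QC metrics missing for some cells in the matrix")

    if dataset_ids is None:
        ds = pd.Series("default", index=pd.Index(m.cell_ids))
    else:
        ds = pd.Series(dataset_ids).reindex(m.cell_ids)
        if ds.isna().any():
            raise ValidationError("dataset_id missing for some cells")
    max_genes = ds.map(lambda d: thresholds.resolve_max_genes(str(d))).to_numpy()

    pct = qc["pct_mito"].to_numpy()
    ng = qc["n_genes"].to_numpy()
    fail_mito = pct > thresholds.max_pct_mito
    fail_min = ng < thresholds.min_genes
    fail_max = ng > max_genes
    removed = fail_mito | fail_min | fail_max

    reason = np.select(
        [fail_mito, fail_min, fail_max], _RULES, default=""
    )
    report = pd.DataFrame(
        {
            "cell_id": np.asarray(m.cell_ids)[removed],
            "dataset_id": ds.to_numpy()[removed],
            "reason": reason[removed],
        }
    )
    kept = m.subset_cells(np.asarray(m.cell_ids)[~removed])
    return kept, report


def lognormalize(
    m: CountMatrix, scale_factor: float = 10_000.0, log1p: bool = True
) -> NormalizedMatrix:
    """Per-cell scaling to a fixed total followed by natural-log transform.

    value(c, g) = ln(1 + count(c, g) * scale_factor / total(c)).

    With ``log1p=False`` the plain natural log of the scaled value is taken
    on nonzero entries only (zero counts stay exactly zero); this variant can
    produce negative values and is provided as a documented switch, not the
    default, because positivity cutoffs assume the log1p scale.

    Cells with zero total counts yield all-zero rows and a warning.  The
    sparsity pattern of the input is preserved exactly.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    counts = sp.csr_matrix(m.counts, dtype=np.float64)
    total = np.asarray(counts.sum(axis=1)).ravel()
    if (total == 0).any():
        warnings.warn(f"{int((total == 0).sum())} cell(s) with zero total counts")
    inv = np.divide(
        scale_factor, total, out=np.zeros_like(total, dtype=float), where=total > 0
    )
    scaled = sp.diags(inv) @ counts
    scaled = sp.csr_matrix(scaled)
    scaled.data = np.log1p(scaled.data) if log1p else np.log(scaled.data)
    return NormalizedMatrix(
        m.cell_ids.copy(), m.gene_symbols.copy(), scaled, float(scale_factor)
    )
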