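"""Transporter typing, expression binarization and per-cell transport-mode calls.

Renal urate handling is carried by a small set of SLC transporters whose
membrane side (apical vs basolateral) and flux direction (influx vs efflux)
jointly determine what a single cell can do with urate.  This module turns a
log-normalized expression matrix into, per cell:

* a boolean positivity profile over the transporter catalog (cutoff rule),
* an influx population call — AIP (apical-influx positive), BIP
  (basolateral-influx positive), DIP (dual positive) or DIN (dual negative),
* an efflux status (any apical-efflux gene positive, any basolateral-efflux
  gene positive), and
* a net transport mode — reabsorption, secretion, bidirectional or
  unfunctional — from a fixed decision table on (population, AE, BE).

The decision table encodes the physiological requirement that a complete
transcellular route needs an influx transporter on one membrane and an efflux
transporter on the opposite membrane: apical influx + basolateral efflux is
reabsorption (lumen to blood), basolateral influx + apical efflux is
secretion.  Dual-influx cells with no efflux transporter are ambiguous; the
``dip_no_efflux`` policy decides whether they count as bidirectional (the
default accounting) or are reported as undetermined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SIDES",
    "DIRECTIONS",
    "TRANSPORTER_TYPES",
    "POPULATIONS",
    "MODES",
    "TARGET_REGIONS",
    "TransporterCatalog",
    "default_catalog",
    "binarize",
    "classify_population",
    "efflux_status",
    "transport_mode",
    "classify_cells",
]

SIDES = ("apical", "basolateral")
DIRECTIONS = ("influx", "efflux")
TRANSPORTER_TYPES = ("AI", "AE", "BI", "BE")
POPULATIONS = ("AIP", "BIP", "DIP", "DIN")
MODES = ("reabsorption", "secretion", "bidirectional", "unfunctional")

#: Regions where the catalog transporters are specifically expressed and the
#: per-cell classification is meaningful: the three proximal-tubule segments
#: and the descending limb of the loop of Henle.
TARGET_REGIONS = ("PT_S1", "PT_S2", "PT_S3", "LOH_DL")

_TYPE_FROM_SIDE_DIR = {
    ("apical", "influx"): "AI",
    ("apical", "efflux"): "AE",
    ("basolateral", "influx"): "BI",
    ("basolateral", "efflux"): "BE",
}


@dataclass(frozen=True)
class TransporterCatalog:
    """Catalog of urate transporters with membrane side and flux direction.

    The ``type`` column is derived, never stored: (apical, influx) -> AI,
    (apical, efflux) -> AE, (basolateral, influx) -> BI,
    (basolateral, efflux) -> BE.  ``km_uM`` (Michaelis constant for urate,
    micromolar) is carried as annotation only; no kinetic inference is done.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        required = {"gene", "side", "direction"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        bad_side = set(t["side"]) - set(SIDES)
        if bad_side:
            raise ValueError(f"invalid membrane side(s): {sorted(bad_side)}")
        bad_dir = set(t["direction"]) - set(DIRECTIONS)
        if bad_dir:
            raise ValueError(f"invalid flux direction(s): {sorted(bad_dir)}")
        dup = t["gene"][t["gene"].duplicated()].tolist()
        if dup:
            raise ValueError(f"duplicate catalog gene(s): {dup}")
        t = t.copy()
        t["gene"] = t["gene"].str.upper()
        t["type"] = [
            _TYPE_FROM_SIDE_DIR[(s, d)] for s, d in zip(t["side"], t["direction"])
        ]
        if "km_uM" in t.columns:
            km = pd.to_numeric(t["km_uM"], errors="coerce")
            if (km.dropna() <= 0).any():
                raise ValueError("km_uM must be positive where given")
            t["km_uM"] = km
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def genes_of_type(self, ttype: str) -> list[str]:
        if ttype not in TRANSPORTER_TYPES:
            raise ValueError(f"unknown transporter type {ttype!r}")
        return self.table.loc[self.table["type"] == ttype, "gene"].tolist()

    @property
    def ai_genes(self) -> list[str]:
        return self.genes_of_type("AI")

    @property
    def ae_genes(self) -> list[str]:
        return self.genes_of_type("AE")

    @property
    def bi_genes(self) -> list[str]:
        return self.genes_of_type("BI")

    @property
    def be_genes(self) -> list[str]:
        return self.genes_of_type("BE")

    @property
    def apical_genes(self) -> list[str]:
        """All genes on the apical membrane (AI + AE)."""
        return self.ai_genes + self.ae_genes

    @classmethod
    def from_tsv(cls, path) -> "TransporterCatalog":
        table = pd.read_csv(path, sep="\t", comment="#")
        return cls(table)


def default_catalog() -> TransporterCatalog:
    """The packaged eight-gene catalog of renal urate transporters.

    AI: SLC22A11 (OAT4), SLC22A12 (URAT1); AE: SLC17A1 (NPT1), SLC17A3 (NPT4);
    BI: SLC22A6 (OAT1), SLC22A7 (OAT2), SLC22A8 (OAT3); BE: SLC2A9 (GLUT9).
    ABCG2, ABCC4 and SLC22A13 are deliberately absent: they are rarely
    expressed, or expressed outside the proximal-tubule/descending-limb
    regions, and play no role in the default classification.
    """
    with resources.as_file(
        resources.files("uratome.data").joinpath("catalog.tsv")
    ) as p:
        return TransporterCatalog.from_tsv(p)


def binarize(nm, genes: Sequence[str] | TransporterCatalog, cutoff: float = 0.5) -> pd.DataFrame:
    """Binarize normalized expression: positive iff value strictly > cutoff.

    Parameters
    ----------
    nm
        A :class:`~uratome.io.NormalizedMatrix` (log-normalized values).
    genes
        Gene symbols to binarize, or a catalog (its genes are used).
    cutoff
        Positivity threshold on the log-normalized scale (default 0.5).
        The rule is strict: a value exactly at the cutoff is negative.

    Returns
    -------
    pandas.DataFrame
        Boolean, cells x genes, indexed by cell id.  Genes absent from the
        matrix produce an all-negative column and a warning.  The cutoff used
        is recorded in ``result.attrs["cutoff"]``.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if isinstance(genes, TransporterCatalog):
        genes = genes.genes
    genes = [g.upper() for g in genes]
    gene_pos = {g: i for i, g in enumerate(nm.gene_symbols)}
    out = np.zeros((nm.n_cells, len(genes)), dtype=bool)
    missing = []
    for j, g in enumerate(genes):
        i = gene_pos.get(g)
        if i is None:
            missing.append(g)
            continue
        col = np.asarray(nm.values[:, i].todense()).ravel()
        out[:, j] = col > cutoff
    if missing:
        warnings.warn(
            f"{len(missing)} catalog gene(s) absent from matrix, treated as "
            f"all-negative: {missing}"
        )
    bp = pd.DataFrame(out, index=pd.Index(nm.cell_ids, name="cell_id"), columns=genes)
    bp.attrs["cutoff"] = float(cutoff)
    return bp


def classify_population(bp: pd.DataFrame, catalog: TransporterCatalog) -> pd.Series:
    """Call the influx population of every cell from its binary profile.

    ai = any apical-influx gene positive; bi = any basolateral-influx gene
    positive.  (ai, not bi) -> AIP; (not ai, bi) -> BIP; (ai, bi) -> DIP;
    (not ai, not bi) -> DIN.  The four populations partition the cells.
    """
    ai_genes = [g for g in catalog.ai_genes if g in bp.columns]
    bi_genes = [g for g in catalog.bi_genes if g in bp.columns]
    if not catalog.ai_genes or not catalog.bi_genes:
        raise ValueError("catalog must contain at least one AI and one BI gene")
    ai = bp[ai_genes].any(axis=1) if ai_genes else pd.Series(False, index=bp.index)
    bi = bp[bi_genes].any(axis=1) if bi_genes else pd.Series(False, index=bp.index)
    pop = np.where(ai & ~bi, "AIP", np.where(~ai & bi, "BIP", np.where(ai & bi, "DIP", "DIN")))
    return pd.Series(pop, index=bp.index, name="population")


def efflux_status(bp: pd.DataFrame, catalog: TransporterCatalog) -> tuple[pd.Series, pd.Series]:
    """Per-cell efflux flags: any AE gene positive, any BE gene positive."""
    ae_genes = [g for g in catalog.ae_genes if g in bp.columns]
    be_genes = [g for g in catalog.be_genes if g in bp.columns]
    ae = bp[ae_genes].any(axis=1) if ae_genes else pd.Series(False, index=bp.index)
    be = bp[be_genes].any(axis=1) if be_genes else pd.Series(False, index=bp.index)
    return ae.rename("ae_pos"), be.rename("be_pos")


def transport_mode(
    population,
    ae_pos,
    be_pos,
    dip_no_efflux: str = "bidirectional",
):
    """Net urate transport mode from (population, AE status, BE status).

    The decision table:

    ================  =======  =======  =================
    population        AE       BE       mode
    ================  =======  =======  =================
    AIP               any      +        reabsorption
    AIP               any      -        unfunctional
    BIP               +        any      secretion
    BIP               -        any      unfunctional
    DIP               +        +        bidirectional
    DIP               +        -        secretion
    DIP               -        +        reabsorption
    DIP               -        -        *policy*
    DIN               any      any      unfunctional
    ================  =======  =======  =================

    ``dip_no_efflux`` resolves the DIP row with no efflux transporter:
    ``"bidirectional"`` (default; such cells are counted as potentially
    transporting in either direction through transporter reversibility) or
    ``"undetermined"`` (reported verbatim as ``"undetermined"``).

    Accepts scalars or equal-length sequences; returns a scalar ``str`` or a
    :class:`pandas.Series` accordingly.
    """
    if dip_no_efflux not in ("bidirectional", "undetermined"):
        raise ValueError("dip_no_efflux must be 'bidirectional' or 'undetermined'")

    scalar = np.isscalar(population) or isinstance(population, str)
    pop = pd.Series([population] if scalar else list(population))
    ae = pd.Series([ae_pos] if scalar else list(ae_pos)).astype(bool)
    be = pd.Series([be_pos] if scalar else list(be_pos)).astype(bool)
    unknown = set(pop) - set(POPULATIONS)
    if unknown:
        raise ValueError(f"unknown population label(s): {sorted(unknown)}")

    mode = pd.Series("unfunctional", index=pop.index, dtype=object)
    mode[(pop == "AIP") & be] = "reabsorption"
    mode[(pop == "BIP") & ae] = "secretion"
    dip = pop == "DIP"
    mode[dip & ae & be] = "bidirectional"
    mode[dip & ae & ~be] = "secretion"
    mode[dip & ~ae & be] = "reabsorption"
    mode[dip & ~ae & ~be] = dip_no_efflux
    if scalar:
        return mode.iloc[0]
    if isinstance(population, pd.Series):
        mode.index = population.index
    return mode.rename("mode")


def classify_cells(
    nm,
    meta: pd.DataFrame,
    catalog: TransporterCatalog | None = None,
    cutoff: float = 0.5,
    dip_no_efflux: str = "bidirectional",
    regions: Iterable[str] = TARGET_REGIONS,
) -> pd.DataFrame:
    """Full per-cell classification restricted to the target regions.

    Composes :func:`binarize`, :func:`classify_population`,
    :func:`efflux_status` and :func:`transport_mode` for every cell whose
    annotated region is in ``regions`` (default: the three proximal-tubule
    segments plus the descending limb).

    Parameters
    ----------
    nm
        Log-normalized matrix.
    meta
        Per-cell metadata with columns ``cell_id`` and ``region``.
    catalog
        Transporter catalog; the packaged eight-gene default if omitted.

    Returns
    -------
    pandas.DataFrame
        Columns: cell_id, region, population, ae_pos, be_pos, mode.
    """
    if catalog is None:
        catalog = default_catalog()
    regions = tuple(regions)
    if not regions:
        raise ValueError("at least one target region is required")
    meta = meta.set_index("cell_id") if "cell_id" in meta.columns else meta
    region = meta["region"].reindex(nm.cell_ids)
    keep = region.isin(regions).to_numpy()
    if not keep.any():
        raise ValueError(f"no cells fall in target regions {regions}")

    sub = nm.subset_cells(np.asarray(nm.cell_ids)[keep])
    bp = binarize(sub, catalog, cutoff=cutoff)
    pop = classify_population(bp, catalog)
    ae, be = efflux_status(bp, catalog)
    mode = transport_mode(pop, ae, be, dip_no_efflux=dip_no_efflux)
    out = pd.DataFrame(
        {
            "cell_id": bp.index,
            "region": region[keep].to_numpy(),
            "population": pop.to_numpy(),
            "ae_pos": ae.to_numpy(),
            "be_pos": be.to_numpy(),
            "mode": mode.to_numpy(),
        }
    )
    return out
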