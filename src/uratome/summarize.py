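"""Downstream summary tables over the per-cell classification.

Everything here is plain counting over the per-cell calls and binary
profiles: population and transport-mode composition per region, the ratio of
reabsorbing to secreting cells along the tubule, how many distinct influx
transporters of one membrane side a cell co-expresses, how often the
basolateral efflux gene is present in secreting-competent cells, and how the
PDZ scaffold gene's positivity distributes over transporter multiplicity in
dual-influx cells.  Each statistic is defined so that fractions within a
stratum sum to one.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import dotplot_stats
from .io import NormalizedMatrix
from .transportome import MODES, POPULATIONS, TARGET_REGIONS, TransporterCatalog

__all__ = [
    "regional_summary",
    "influx_multiplicity",
    "be_in_secretors",
    "scaffold_crosstab",
    "population_expression_dotstats",
    "population_efflux_counts",
]

_EFFLUX_COMBOS = ("AE-BE-", "AE+BE-", "AE-BE+", "AE+BE+")


def _region_order(calls: pd.DataFrame) -> list[str]:
    known = [r for r in TARGET_REGIONS if r in set(calls["region"])]
    extra = sorted(set(calls["region"]) - set(TARGET_REGIONS))
    return known + extra


def _mode_labels(calls: pd.DataFrame) -> list[str]:
    labels = list(MODES)
    if "undetermined" in set(calls["mode"]):
        labels.append("undetermined")
    return labels


def regional_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Population and mode composition per region.

    One row per region: cell count, per-population counts and fractions,
    per-mode counts and fractions, and ``reabs_secr_ratio`` = reabsorption
    count / secretion count (NaN when the secretion count is zero).
    Population fractions and mode fractions each sum to 1 within a region.
    """
    if calls.empty:
        warnings.warn("no classified cells; empty summary")
        return pd.DataFrame()
    rows = []
    for region in _region_order(calls):
        sub = calls[calls["region"] == region]
        if len(sub) == 0:
            warnings.warn(f"region {region!r} has no cells; omitted")
            continue
        row: dict = {"region": region, "n_cells": len(sub)}
        for pop in POPULATIONS:
            n = int((sub["population"] == pop).sum())
            row[f"n_{pop}"] = n
            row[f"frac_{pop}"] = n / len(sub)
        for mode in _mode_labels(calls):
            n = int((sub["mode"] == mode).sum())
            row[f"n_{mode}"] = n
            row[f"frac_{mode}"] = n / len(sub)
        n_secr = row["n_secretion"]
        row["reabs_secr_ratio"] = (
            row["n_reabsorption"] / n_secr if n_secr > 0 else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _positive_counts(
    bp: pd.DataFrame, calls: pd.DataFrame, genes: Sequence[str]
) -> pd.Series:
    genes = [g for g in genes if g in bp.columns]
    return bp.loc[calls["cell_id"], genes].sum(axis=1).set_axis(calls.index)


def influx_multiplicity(
    bp: pd.DataFrame,
    calls: pd.DataFrame,
    catalog: TransporterCatalog,
    which: str = "BI",
) -> pd.DataFrame:
    """How many distinct influx transporters of one side a cell co-expresses.

    Per (region, population): the distribution of the number of positive
    ``which``-type genes bucketed as 0 / 1 / 2+ (axis ``"multiplicity"``).
    For ``which="AI"`` an additional axis ``"ai_combination"`` breaks the
    AI-positive cells into SLC22A11-only / SLC22A12-only / both.

    Returns a tidy frame: region, population, axis, category, n, frac; the
    fractions within each (region, population, axis) stratum sum to 1.
    """
    if which not in ("AI", "BI"):
        raise ValueError("which must be 'AI' or 'BI'")
    genes = catalog.ai_genes if which == "AI" else catalog.bi_genes
    k = _positive_counts(bp, calls, genes)
    bucket = pd.Series(
        np.select([k == 0, k == 1], ["0", "1"], default="2+"), index=calls.index
    )

    rows = []
    for (region, pop), idx in calls.groupby(["region", "population"]).groups.items():
        sub = bucket.loc[idx]
        for cat in ("0", "1", "2+"):
            n = int((sub == cat).sum())
            rows.append(
                {
                    "region": region,
                    "population": pop,
                    "axis": "multiplicity",
                    "category": cat,
                    "n": n,
                    "frac": n / len(sub),
                }
            )
        if which == "AI":
            prof = bp.loc[calls.loc[idx, "cell_id"]]
            a11 = prof.get("SLC22A11", pd.Series(False, index=prof.index))
            a12 = prof.get("SLC22A12", pd.Series(False, index=prof.index))
            pos = (a11 | a12).to_numpy()
            n_pos = int(pos.sum())
            combos = {
                "SLC22A11_only": int((a11 & ~a12).sum()),
                "SLC22A12_only": int((~a11 & a12).sum()),
                "both": int((a11 & a12).sum()),
            }
            for cat, n in combos.items():
                rows.append(
                    {
                        "region": region,
                        "population": pop,
                        "axis": "ai_combination",
                        "category": cat,
                        "n": n,
                        "frac": n / n_pos if n_pos else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def be_in_secretors(
    calls: pd.DataFrame, bp: pd.DataFrame, be_gene: str = "SLC2A9"
) -> pd.DataFrame:
    """Fraction of AE-positive BIP cells that also express the BE gene.

    These are the secretion-competent cells in which basolateral efflux
    capacity would route urate back toward the blood, attenuating secretion.
    Per region: the BIP & AE+ cell count, the count of those positive for
    ``be_gene``, and their ratio (NaN with ``undefined=True`` when the
    denominator is zero).
    """
    be_gene = be_gene.upper()
    rows = []
    for region in _region_order(calls):
        sub = calls[(calls["region"] == region)]
        den = sub[(sub["population"] == "BIP") & sub["ae_pos"]]
        n_den = len(den)
        if n_den == 0:
            warnings.warn(f"region {region!r}: no BIP AE+ cells; fraction undefined")
            rows.append(
                {
                    "region": region,
                    "n_bip_ae_pos": 0,
                    "n_be_pos": 0,
                    "frac_be_pos": np.nan,
                    "undefined": True,
                }
            )
            continue
        if be_gene in bp.columns:
            n_pos = int(bp.loc[den["cell_id"], be_gene].sum())
        else:
            n_pos = 0
        rows.append(
            {
                "region": region,
                "n_bip_ae_pos": n_den,
                "n_be_pos": n_pos,
                "frac_be_pos": n_pos / n_den,
                "undefined": False,
            }
        )
    return pd.DataFrame(rows)


def scaffold_crosstab(
    bp: pd.DataFrame,
    calls: pd.DataFrame,
    catalog: TransporterCatalog,
    scaffold_gene: str = "PDZK1",
) -> dict[str, pd.DataFrame]:
    """Cross-tabulations of a scaffold gene's positivity in the DIP population.

    The scaffold (default PDZK1) clusters transporters into functional units
    on the apical membrane, so its co-occurrence with transporter
    multiplicity is of interest.  Returns four tables:

    - ``by_population``: scaffold-positive fraction in each population.
    - ``by_apical_count``: DIP cells stratified by scaffold status; within
      each stratum, the distribution of the number of positive apical
      transporter genes (AI + AE).
    - ``by_bi_multiplicity``: same strata, distribution of BI multiplicity
      bucketed 0 / 1 / 2+.
    - ``by_efflux_combo``: same strata, distribution over the four efflux
      combinations AE-BE-, AE+BE-, AE-BE+, AE+BE+.

    Within-stratum fractions each sum to 1.  A scaffold gene absent from the
    profile yields all-negative status and a warning.
    """
    scaffold_gene = scaffold_gene.upper()
    if scaffold_gene in bp.columns:
        scaff = bp.loc[calls["cell_id"], scaffold_gene].to_numpy()
    else:
        warnings.warn(f"scaffold gene {scaffold_gene!r} absent; treated as all-negative")
        scaff = np.zeros(len(calls), dtype=bool)
    scaff = pd.Series(scaff, index=calls.index)

    pop_rows = []
    for pop in POPULATIONS:
        idx = calls.index[calls["population"] == pop]
        n = len(idx)
        n_pos = int(scaff.loc[idx].sum())
        pop_rows.append(
            {
                "population": pop,
                "n_cells": n,
                "n_scaffold_pos": n_pos,
                "frac_scaffold_pos": n_pos / n if n else np.nan,
            }
        )
    by_population = pd.DataFrame(pop_rows)

    dip_idx = calls.index[calls["population"] == "DIP"]
    dip_calls = calls.loc[dip_idx]
    dip_scaff = scaff.loc[dip_idx]
    apical = _positive_counts(bp, dip_calls, catalog.apical_genes)
    bi = _positive_counts(bp, dip_calls, catalog.bi_genes)
    bi_bucket = pd.Series(
        np.select([bi == 0, bi == 1], ["0", "1"], default="2+"), index=dip_idx
    )
    combo = pd.Series(
        np.array(_EFFLUX_COMBOS, dtype=object)[
            dip_calls["ae_pos"].to_numpy().astype(int)
            + 2 * dip_calls["be_pos"].to_numpy().astype(int)
        ],
        index=dip_idx,
    )

    def strata_table(values: pd.Series, categories: Sequence[str]) -> pd.DataFrame:
        rows = []
        for status, mask in (("positive", dip_scaff), ("negative", ~dip_scaff)):
            sel = values[mask.to_numpy()]
            total = len(sel)
            for cat in categories:
                n = int((sel == cat).sum())
                rows.append(
                    {
                        "scaffold": status,
                        "category": cat,
                        "n": n,
                        "frac": n / total if total else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    apical_cats = [str(i) for i in range(len(catalog.apical_genes) + 1)]
    by_apical = strata_table(apical.astype(int).astype(str), apical_cats)
    by_bi = strata_table(bi_bucket, ("0", "1", "2+"))
    by_combo = strata_table(combo, _EFFLUX_COMBOS)

    return {
        "by_population": by_population,
        "by_apical_count": by_apical,
        "by_bi_multiplicity": by_bi,
        "by_efflux_combo": by_combo,
    }


def average_mode_proportions(
    calls: pd.DataFrame, regions: Sequence[str] = TARGET_REGIONS
) -> dict[str, float]:
    """Unweighted mean, across regions, of mode fractions among functional cells.

    For each region the reabsorption / secretion / bidirectional fractions
    are computed over the functional cells only (unfunctional and
    undetermined cells excluded), then averaged across regions with equal
    weight, so the three returned fractions sum to 1.  Regions without
    functional cells are skipped with a warning.
    """
    functional = ("reabsorption", "secretion", "bidirectional")
    per_region = []
    for region in regions:
        sub = calls[(calls["region"] == region) & calls["mode"].isin(functional)]
        if len(sub) == 0:
            warnings.warn(f"region {region!r} has no functional cells; skipped")
            continue
        per_region.append(
            {m: float((sub["mode"] == m).mean()) for m in functional}
        )
    if not per_region:
        raise ValueError("no region has functional cells")
    return {
        m: float(np.mean([r[m] for r in per_region])) for m in functional
    }


def population_expression_dotstats(
    nm: NormalizedMatrix, calls: pd.DataFrame, genes: Sequence[str]
) -> pd.DataFrame:
    """Percent-expressed / mean expression per (population, region) group.

    Same contract as :func:`uratome.annotate.dotplot_stats`, with groups
    formed by crossing the population call with the region.  Empty groups
    cannot occur (groups are formed from the calls themselves).
    """
    sub = nm.subset_cells(calls["cell_id"].to_numpy())
    labels = (
        calls["population"].astype(str) + "|" + calls["region"].astype(str)
    ).to_numpy()
    groups = pd.Series(labels, index=calls["cell_id"].to_numpy())
    stats = dotplot_stats(sub, groups, genes)
    split = stats["cluster_id"].str.split("|", expand=True)
    stats.insert(0, "population", split[0])
    stats.insert(1, "region", split[1])
    return stats.drop(columns="cluster_id")


def population_efflux_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Cell counts per (region, population, AE status, BE status, mode).

    The long-format breakdown of the classification: each row is one
    combination actually observed, with its cell count.
    """
    out = (
        calls.groupby(["region", "population", "ae_pos", "be_pos", "mode"])
        .size()
        .rename("n_cells")
        .reset_index()
    )
    return out.sort_values(["region", "population", "ae_pos", "be_pos"]).reset_index(
        drop=True
    )
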