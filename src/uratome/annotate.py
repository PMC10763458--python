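"""Marker-based cluster annotation: anatomical regions and PT segments.

Unsupervised clustering is an input here, not a product: every cell arrives
with a precomputed cluster label, and this module assigns each cluster an
anatomical region by scoring marker-gene expression.  The score for a
(cluster, region) pair is the mean fraction of the cluster's cells expressing
that region's marker genes (the "dot size" statistic of a dot plot); ties are
broken by mean average expression, then by lexical region order, and every
tie is logged.  The winning region must have a nonzero score, otherwise the
cluster stays unassigned.

Proximal-tubule clusters are subsequently split into the S1/S2/S3 segments.
Only S1 and S3 have specific markers, so the rule is: of exactly three PT
clusters, the best S1 scorer becomes S1, the best S3 scorer among the rest
becomes S3, and the remaining cluster is S2 by elimination.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import NormalizedMatrix

__all__ = ["dotplot_stats", "assign_regions", "assign_pt_segments"]

logger = logging.getLogger(__name__)


def dotplot_stats(
    nm: NormalizedMatrix, groups: pd.Series, genes: Sequence[str]
) -> pd.DataFrame:
    """Percent-expressed and mean expression per (cluster, gene).

    ``pct_exp`` is the fraction of the cluster's cells with normalized value
    > 0; ``avg_exp`` is the mean normalized value over all the cluster's
    cells (zeros included).  Genes absent from the matrix are warned about
    and omitted from the output.

    Parameters
    ----------
    groups
        Series mapping cell_id -> cluster label, covering every matrix cell.
    """
    groups = pd.Series(groups).reindex(nm.cell_ids)
    if groups.isna().any():
        raise ValueError("every cell needs a cluster label")
    genes = [g.upper() for g in genes]
    gene_pos = {g: i for i, g in enumerate(nm.gene_symbols)}
    missing = [g for g in genes if g not in gene_pos]
    if missing:
        warnings.warn(f"gene(s) absent from matrix, omitted from stats: {missing}")
    present = [g for g in genes if g in gene_pos]

    rows = []
    group_index = {
        label: np.flatnonzero((groups == label).to_numpy())
        for label in pd.unique(groups)
    }
    for label, idx in group_index.items():
        if idx.size == 0:
            raise ValueError(f"empty cluster {label!r}")
        for g in present:
            col = np.asarray(nm.values[idx, gene_pos[g]].todense()).ravel()
            rows.append(
                {
                    "cluster_id": label,
                    "gene": g,
                    "pct_exp": float((col > 0).mean()),
                    "avg_exp": float(col.mean()),
                }
            )
    return pd.DataFrame(rows, columns=["cluster_id", "gene", "pct_exp", "avg_exp"])


def _marker_scores(
    stats: pd.DataFrame, markers: pd.DataFrame, region_column: str
) -> pd.DataFrame:
    """Mean pct_exp and mean avg_exp of each label's markers, per cluster."""
    merged = markers.merge(stats, on="gene", how="inner")
    scores = (
        merged.groupby(["cluster_id", region_column], sort=True)[["pct_exp", "avg_exp"]]
        .mean()
        .reset_index()
        .rename(columns={"pct_exp": "score", "avg_exp": "avg_score"})
    )
    return scores


def assign_regions(
    stats: pd.DataFrame, markers: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each cluster the region whose markers it expresses most broadly.

    Parameters
    ----------
    stats
        Output of :func:`dotplot_stats` over (at least) the marker genes.
    markers
        Marker table with columns ``region`` and ``gene``.

    Returns
    -------
    (assignment, scores)
        ``assignment`` maps cluster_id -> region (``"unassigned"`` when every
        region scores zero); ``scores`` is the full audit table of per
        (cluster, region) scores.
    """
    if markers.empty:
        raise ValueError("marker table is empty")
    scores = _marker_scores(stats, markers, "region")
    assignment = {}
    for cluster, grp in scores.groupby("cluster_id", sort=False):
        ranked = grp.sort_values(
            ["score", "avg_score", "region"], ascending=[False, False, True]
        )
        best = ranked.iloc[0]
        if best["score"] == 0:
            warnings.warn(f"cluster {cluster!r}: all marker scores zero; unassigned")
            assignment[cluster] = "unassigned"
            continue
        runner_up = ranked.iloc[1] if len(ranked) > 1 else None
        if runner_up is not None and runner_up["score"] == best["score"]:
            logger.info(
                "cluster %r: region tie between %r and %r broken by avg_exp/lexical order",
                cluster,
                best["region"],
                runner_up["region"],
            )
        assignment[cluster] = best["region"]
    return pd.Series(assignment, name="region"), scores


def assign_pt_segments(
    stats: pd.DataFrame,
    s1_markers: Iterable[str],
    s3_markers: Iterable[str],
    pt_clusters: Sequence[str],
) -> dict[str, str]:
    """Split exactly three proximal-tubule clusters into S1, S2 and S3.

    The cluster with the highest mean S1-marker pct_exp becomes ``PT_S1``;
    among the remaining two, the highest mean S3-marker pct_exp becomes
    ``PT_S3``; the last is ``PT_S2`` (no specific S2 markers exist).  When
    the S1 and S3 argmax land on the same cluster, the S1 claim wins and S3
    is taken from the remaining clusters; this, and exact ties, are logged.
    """
    pt_clusters = list(pt_clusters)
    if len(pt_clusters) != 3:
        raise ValueError(
            f"PT segment assignment is defined for exactly 3 clusters, got {len(pt_clusters)}"
        )

    def seg_rank(genes: Iterable[str], among: Sequence[str]) -> list[str]:
        genes = [g.upper() for g in genes]
        sub = stats[stats["cluster_id"].isin(among) & stats["gene"].isin(genes)]
        agg = (
            sub.groupby("cluster_id")[["pct_exp", "avg_exp"]]
            .mean()
            .reindex(among)
            .fillna(0.0)
        )
        ranked = agg.sort_values(["pct_exp", "avg_exp"], ascending=False)
        if len(ranked) > 1 and ranked["pct_exp"].iloc[0] == ranked["pct_exp"].iloc[1]:
            logger.info(
                "PT segment tie between %r and %r broken by avg_exp/cluster order",
                ranked.index[0],
                ranked.index[1],
            )
        return [str(c) for c in ranked.index]

    s1_order = seg_rank(s1_markers, pt_clusters)
    s1 = s1_order[0]
    s3_global = seg_rank(s3_markers, pt_clusters)[0]
    if s3_global == s1:
        logger.info(
            "cluster %r maximizes both S1 and S3 scores; S1 claim wins, "
            "S3 taken from the remaining clusters",
            s1,
        )
    rest = [c for c in pt_clusters if c != s1]
    s3 = seg_rank(s3_markers, rest)[0]
    s2 = next(c for c in rest if c != s3)
    return {s1: "PT_S1", s2: "PT_S2", s3: "PT_S3"}
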