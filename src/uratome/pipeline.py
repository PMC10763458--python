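"""One-shot orchestration: QC -> normalize -> annotate -> classify -> summarize.

A run is fully described by a :class:`RunConfig` (serializable to YAML).  The
pipeline is deterministic given its inputs and config; every output table
carries the config's SHA-256 hash in a leading comment line, and the resolved
config is written into the output directory alongside the tables, so any
result file can be traced back to the exact settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import annotate, io, qc, summarize, transportome

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    counts_path: str | None = None
    counts_format: str = "mtx_triplet"
    cells_in_rows: bool | None = None
    meta_path: str | None = None
    symbol_map_path: str | None = None
    catalog_path: str | None = None
    region_markers_path: str | None = None
    pt_markers_path: str | None = None
    mito_prefix: str = "MT-"
    max_pct_mito: float = 0.05
    min_genes: int = 200
    max_genes: int | Mapping[str, int] = 6000
    scale_factor: float = 10_000.0
    cutoff: float = 0.5
    dip_no_efflux: str = "bidirectional"
    regions: tuple[str, ...] = transportome.TARGET_REGIONS
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config field(s): {sorted(unknown)}")
        if "regions" in raw:
            raw["regions"] = tuple(raw["regions"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = list(d["regions"])
        if isinstance(d["max_genes"], Mapping):
            d["max_genes"] = dict(d["max_genes"])
        return d

    def config_hash(self) -> str:
        # out_dir is where results land, not what they are; exclude it so
        # identical analyses hash identically wherever they are written
        d = self.to_dict()
        d.pop("out_dir", None)
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _require(cfg: RunConfig, name: str) -> str:
    value = getattr(cfg, name)
    if value is None:
        raise PipelineError(f"config field {name!r} is required")
    return value


def _resolve_input(cfg: RunConfig, name: str) -> Path | None:
    value = getattr(cfg, name)
    if value is None:
        return None
    p = Path(value)
    if not p.exists():
        raise PipelineError(f"{name}: file not found: {p}")
    return p


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages and write every result table to ``cfg.out_dir``.

    Outputs: ``qc_metrics.tsv``, ``rejections.tsv``, ``cluster_scores.tsv``
    (when annotation ran), ``calls.tsv``, ``regional_summary.tsv``,
    ``multiplicity_ai.tsv`` / ``multiplicity_bi.tsv``, ``be_in_secretors.tsv``,
    ``scaffold_*.tsv``, ``population_dotstats.tsv``,
    ``population_efflux_counts.tsv``, ``config.yaml`` and ``run_log.txt``.

    Region labels are taken from the metadata when present; otherwise the
    clusters are annotated from marker tables (packaged defaults unless
    overridden), with proximal-tubule clusters split into S1/S2/S3 whenever
    exactly three clusters map to the coarse PT label.
    """
    out_dir = Path(_require(cfg, "out_dir"))
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    log_lines: list[str] = [f"config_hash={chash}"]

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(f"stage {name!r}: {exc}") from exc
                return False

        return _Ctx()

    def emit(df: pd.DataFrame, name: str) -> None:
        io.write_table(df, out_dir / name, header_comment=f"config_sha256={chash}")

    with stage("read"):
        counts_path = Path(_require(cfg, "counts_path"))
        if not counts_path.exists():
            raise PipelineError(f"counts_path: file not found: {counts_path}")
        matrix = io.read_count_matrix(
            counts_path, cfg.counts_format, cells_in_rows=cfg.cells_in_rows
        )
        meta = io.read_cell_meta(Path(_require(cfg, "meta_path")))
        smap_path = _resolve_input(cfg, "symbol_map_path")
        if smap_path is not None:
            matrix, n_unmapped = io.apply_symbol_map(matrix, io.read_symbol_map(smap_path))
            log_lines.append(f"symbol_map: {n_unmapped} unmapped identifiers kept")
        catalog_path = _resolve_input(cfg, "catalog_path")
        catalog = (
            io.read_catalog(catalog_path)
            if catalog_path
            else transportome.default_catalog()
        )
        log_lines.append(f"input: {matrix.n_cells} cells x {matrix.n_genes} genes")

    with stage("qc"):
        metrics = qc.compute_qc(matrix, mito_prefix=cfg.mito_prefix)
        thresholds = qc.QCThresholds(
            max_pct_mito=cfg.max_pct_mito,
            min_genes=cfg.min_genes,
            max_genes=cfg.max_genes,
        )
        dataset_ids = meta.set_index("cell_id")["dataset_id"]
        filtered, rejections = qc.filter_cells(matrix, metrics, thresholds, dataset_ids)
        emit(metrics, "qc_metrics.tsv")
        emit(rejections, "rejections.tsv")
        log_lines.append(
            f"qc: kept {filtered.n_cells}/{matrix.n_cells} cells "
            f"({len(rejections)} removed)"
        )

    with stage("normalize"):
        nm = qc.lognormalize(filtered, scale_factor=cfg.scale_factor)

    with stage("annotate"):
        meta_kept = meta[meta["cell_id"].isin(filtered.cell_ids)].copy()
        has_regions = (meta_kept["region"] != "unassigned").any()
        if not has_regions:
            if "cluster_id" not in meta_kept.columns:
                raise PipelineError(
                    "metadata has neither region labels nor cluster_id"
                )
            rm_path = _resolve_input(cfg, "region_markers_path")
            markers = (
                io.read_marker_table(rm_path)
                if rm_path
                else io.default_region_markers()
            )
            pm_path = _resolve_input(cfg, "pt_markers_path")
            pt_markers = (
                io.read_marker_table(pm_path, region_column="segment")
                if pm_path
                else io.default_pt_segment_markers()
            )
            groups = meta_kept.set_index("cell_id")["cluster_id"]
            genes = sorted(set(markers["gene"]) | set(pt_markers["gene"]))
            stats = annotate.dotplot_stats(nm, groups, genes)
            assignment, scores = annotate.assign_regions(stats, markers)
            pt_clusters = assignment.index[assignment == "PT"].tolist()
            if len(pt_clusters) == 3:
                s1 = pt_markers.loc[pt_markers["segment"] == "PT_S1", "gene"]
                s3 = pt_markers.loc[pt_markers["segment"] == "PT_S3", "gene"]
                segs = annotate.assign_pt_segments(stats, s1, s3, pt_clusters)
                for c in pt_clusters:
                    assignment[c] = segs[c]
            meta_kept["region"] = (
                meta_kept["cluster_id"].map(assignment).fillna("unassigned")
            )
            emit(scores, "cluster_scores.tsv")
            log_lines.append(
                "annotate: " + ", ".join(f"{c}->{r}" for c, r in assignment.items())
            )
        else:
            log_lines.append("annotate: regions taken from metadata")

    with stage("classify"):
        calls = transportome.classify_cells(
            nm,
            meta_kept,
            catalog=catalog,
            cutoff=cfg.cutoff,
            dip_no_efflux=cfg.dip_no_efflux,
            regions=cfg.regions,
        )
        bp = transportome.binarize(
            nm.subset_cells(calls["cell_id"].to_numpy()),
            list(catalog.genes) + ["PDZK1"],
            cutoff=cfg.cutoff,
        )
        emit(calls, "calls.tsv")
        log_lines.append(f"classify: {len(calls)} cells in {cfg.regions}")

    with stage("summarize"):
        emit(summarize.regional_summary(calls), "regional_summary.tsv")
        emit(
            summarize.influx_multiplicity(bp, calls, catalog, which="AI"),
            "multiplicity_ai.tsv",
        )
        emit(
            summarize.influx_multiplicity(bp, calls, catalog, which="BI"),
            "multiplicity_bi.tsv",
        )
        emit(summarize.be_in_secretors(calls, bp), "be_in_secretors.tsv")
        tabs = summarize.scaffold_crosstab(bp, calls, catalog)
        for key, df in tabs.items():
            emit(df, f"scaffold_{key}.tsv")
        emit(
            summarize.population_expression_dotstats(
                nm, calls, list(catalog.genes) + ["PDZK1"]
            ),
            "population_dotstats.tsv",
        )
        emit(summarize.population_efflux_counts(calls), "population_efflux_counts.tsv")

    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out_dir
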