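"""Synthetic single-nucleus count data with planted ground truth.

The generator emulates exactly the structure the classification pipeline
assumes, so every stage can be tested end-to-end without external downloads:

* negative-binomial background counts with log-normal library sizes,
* a mitochondrial gene fraction per cell, including a contaminating
  high-mito subpopulation, plus planted low-gene and doublet-like high-gene
  cells so each QC rule has known violators,
* region marker genes enriched in their home region's clusters (proximal
  tubule segments share the coarse PT markers and differ in S1/S3 segment
  markers),
* per-cell transporter positivity planted directly on the log-normalized
  scale and inverted to counts, so a planted positive is guaranteed to clear
  the 0.5 positivity cutoff and a planted negative is an exact zero count,
* co-positivity couplings: basolateral-efflux positivity conditioned on the
  cell's population and apical-efflux status, and scaffold (PDZK1)
  positivity increasing with the number of apical transporters in
  dual-influx cells.

``GeneratorConfig()`` (equivalently :func:`reference_config`) carries the
reference study condition: ~10,000 cells across the three proximal-tubule
segments and the descending limb (plus two small out-of-scope regions), with
basolateral-influx-positive and dual-influx-positive cells dominant in S1
(planted fractions 0.44 and 0.47) and declining toward the descending limb,
the apical-influx-only population smallest throughout, a 0.70
SLC2A9-positive rate among secretion-competent BIP cells, and a
reabsorbing:secreting cell ratio increasing along the tubule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix
from .qc import QCThresholds
from .transportome import (
    POPULATIONS,
    classify_population,
    default_catalog,
    efflux_status,
    transport_mode,
)

__all__ = ["GeneratorConfig", "SyntheticDataset", "generate", "reference_config"]

MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CYB", "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8",
)

_QC_CLASSES = ("pass", "high_mito", "low_genes", "high_genes")


def _default_cells_per_region() -> dict[str, int]:
    return {
        "PT_S1": 2900,
        "PT_S2": 2700,
        "PT_S3": 2500,
        "LOH_DL": 1500,
        "LOH_AL": 300,
        "DCT": 100,
    }


def _default_population_probs() -> dict[str, dict[str, float]]:
    return {
        "PT_S1": {"AIP": 0.029, "BIP": 0.44, "DIP": 0.47, "DIN": 0.061},
        "PT_S2": {"AIP": 0.074, "BIP": 0.50, "DIP": 0.30, "DIN": 0.126},
        "PT_S3": {"AIP": 0.05, "BIP": 0.50, "DIP": 0.35, "DIN": 0.10},
        "LOH_DL": {"AIP": 0.04, "BIP": 0.14, "DIP": 0.054, "DIN": 0.766},
        "LOH_AL": {"AIP": 0.01, "BIP": 0.04, "DIP": 0.01, "DIN": 0.94},
        "DCT": {"AIP": 0.01, "BIP": 0.04, "DIP": 0.01, "DIN": 0.94},
    }


def _default_marker_map() -> dict[str, tuple[str, ...]]:
    return {
        "PT_S1": ("CUBN", "LRP2", "SLC5A2", "SLC5A12"),
        "PT_S2": ("CUBN", "LRP2"),
        "PT_S3": ("CUBN", "LRP2", "SLC7A13", "SLC5A10"),
        "LOH_DL": ("AQP1", "SLC14A2"),
        "LOH_AL": ("UMOD", "SLC12A1"),
        "DCT": ("SLC12A3", "TRPM6"),
    }


def _default_cluster_map() -> dict[str, str]:
    return {
        "PT_S1": "PTa",
        "PT_S2": "PTb",
        "PT_S3": "PTc",
        "LOH_DL": "DL",
        "LOH_AL": "AL",
        "DCT": "DCTc",
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """All generator knobs; the defaults are the reference study condition."""

    seed: int = 0
    cells_per_region: Mapping[str, int] = field(default_factory=_default_cells_per_region)
    dataset_ids: tuple[str, ...] = ("kidney1", "kidney2", "kidney3")
    cluster_of_region: Mapping[str, str] = field(default_factory=_default_cluster_map)

    # background count model
    n_background_genes: int = 800
    n_extended_genes: int = 400
    low_gene_pool: int = 150
    nb_dispersion: float = 0.3
    library_log_mean: float = 7.7
    library_log_sd: float = 0.35
    library_clip: tuple[float, float] = (800.0, 4000.0)
    high_gene_library: float = 6000.0
    low_gene_library: float = 300.0

    # QC structure: planted violator rates and the thresholds that define them
    frac_high_mito: float = 0.05
    frac_low_genes: float = 0.02
    frac_high_genes: float = 0.02
    mito_fraction_range: tuple[float, float] = (0.005, 0.035)
    contaminant_mito_range: tuple[float, float] = (0.08, 0.15)
    qc_min_genes: int = 200
    qc_max_pct_mito: float = 0.05
    qc_max_genes: Mapping[str, int] = field(
        default_factory=lambda: {"kidney1": 1000, "kidney2": 1000, "kidney3": 950}
    )

    # planted population structure
    population_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_population_probs
    )
    ai_pattern: Mapping[str, float] = field(
        default_factory=lambda: {"SLC22A11": 0.80, "SLC22A12": 0.15, "both": 0.05}
    )
    bi_multi2_prob: Mapping[str, float] = field(
        default_factory=lambda: {
            "PT_S1": 0.60, "PT_S2": 0.33, "PT_S3": 0.60, "LOH_DL": 0.17,
            "default": 0.20,
        }
    )
    bi_triple_given_multi: float = 0.15
    bi_single_weights: Mapping[str, float] = field(
        default_factory=lambda: {"SLC22A6": 0.7, "SLC22A8": 0.2, "SLC22A7": 0.1}
    )
    bi_pair_weights: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("SLC22A6", "SLC22A8"): 0.6,
            ("SLC22A6", "SLC22A7"): 0.3,
            ("SLC22A7", "SLC22A8"): 0.1,
        }
    )
    ae_pattern: Mapping[str, float] = field(
        default_factory=lambda: {"SLC17A1": 0.55, "SLC17A3": 0.25, "both": 0.20}
    )
    p_ae_given_aip: float = 0.2
    p_be_given_aip: Mapping[str, float] = field(
        default_factory=lambda: {
            "PT_S1": 0.49, "PT_S2": 0.48, "PT_S3": 0.86, "LOH_DL": 0.85,
            "default": 0.50,
        }
    )
    p_ae_given_bip: float = 0.8
    p_be_given_bip_ae_pos: float = 0.70
    p_be_given_bip_ae_neg: float = 0.50
    dip_be_only_prob: Mapping[str, float] = field(
        default_factory=lambda: {
            "PT_S1": 0.02, "PT_S2": 0.04, "PT_S3": 0.10, "LOH_DL": 0.15,
            "default": 0.05,
        }
    )
    dip_both_prob: float = 0.50
    dip_ae_only_prob: float = 0.25
    p_ae_given_din: float = 0.05
    p_be_given_din: float = 0.10

    # scaffold coupling
    scaffold_gene: str = "PDZK1"
    scaffold_base_dip: float = 0.35
    scaffold_per_apical: float = 0.12
    scaffold_cap: float = 0.90
    scaffold_probs_other: Mapping[str, float] = field(
        default_factory=lambda: {"AIP": 0.30, "BIP": 0.20, "DIN": 0.10}
    )

    # marker planting and positive expression levels (log-normalized scale)
    region_marker_map: Mapping[str, tuple[str, ...]] = field(
        default_factory=_default_marker_map
    )
    marker_pos_prob_in: float = 0.8
    marker_pos_prob_out: float = 0.05
    marker_level_range: tuple[float, float] = (1.0, 2.5)
    positive_level_range: tuple[float, float] = (1.2, 3.0)
    scale_factor: float = 10_000.0
    dip_no_efflux: str = "bidirectional"

    def __post_init__(self) -> None:
        if self.low_gene_pool > self.n_background_genes:
            raise ValueError("low_gene_pool exceeds the background gene count")
        frac = self.frac_high_mito + self.frac_low_genes + self.frac_high_genes
        if not 0 <= frac < 1:
            raise ValueError("planted QC-violator fractions must sum to < 1")
        for region, probs in self.population_probs.items():
            s = sum(probs.get(p, 0.0) for p in POPULATIONS)
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"population probabilities for {region!r} sum to {s}")
        for region in self.cells_per_region:
            if region not in self.population_probs:
                raise ValueError(f"no population probabilities for region {region!r}")
            if region not in self.region_marker_map:
                raise ValueError(f"no marker genes for region {region!r}")
        catalog_genes = set(default_catalog().genes) | {self.scaffold_gene.upper()}
        marker_genes = {
            g.upper() for genes in self.region_marker_map.values() for g in genes
        }
        overlap = catalog_genes & marker_genes
        if overlap:
            raise ValueError(
                f"marker genes collide with catalog/scaffold genes: {sorted(overlap)}"
            )
        if not (self.dip_both_prob + self.dip_ae_only_prob
                + max(v for v in self.dip_be_only_prob.values())) <= 1.0:
            raise ValueError("DIP efflux-combination probabilities exceed 1")

    @property
    def n_cells(self) -> int:
        return int(sum(self.cells_per_region.values()))

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(
            max_pct_mito=self.qc_max_pct_mito,
            min_genes=self.qc_min_genes,
            max_genes=dict(self.qc_max_genes),
        )


def reference_config(seed: int = 0) -> GeneratorConfig:
    """The reference study condition (the dataclass defaults), ~10,000 cells."""
    return GeneratorConfig(seed=seed)


@dataclass
class SyntheticDataset:
    """Generator output: counts, metadata, per-cell ground truth, config."""

    matrix: CountMatrix
    meta: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig


def _lookup(table: Mapping[str, float], region: str) -> float:
    if region in table:
        return float(table[region])
    if "default" in table:
        return float(table["default"])
    raise KeyError(f"no value for region {region!r} and no default")


def _choice(rng, options: Sequence, weights: Sequence[float], size: int):
    w = np.asarray(weights, dtype=float)
    return rng.choice(len(options), size=size, p=w / w.sum())


def _plant_counts(rng, levels: np.ndarray, totals: np.ndarray, sf: float) -> np.ndarray:
    """Invert a target log-normalized level to a raw count (at least 1)."""
    return np.maximum(1, np.round((np.expm1(levels)) * totals / sf)).astype(np.int64)


def generate(config: GeneratorConfig, seed: int | None = None) -> SyntheticDataset:
    """Draw one synthetic dataset; fully determined by the seed.

    Returns counts (cells x genes), per-cell metadata (cluster labels, no
    region annotation), and the ground-truth table with the planted region,
    transporter positivity vector, implied population / efflux status /
    transport mode, and the QC class (``pass`` or the violated rule).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    catalog = default_catalog()
    scaffold = config.scaffold_gene.upper()

    marker_genes = sorted(
        {g.upper() for genes in config.region_marker_map.values() for g in genes}
    )
    planted_genes = catalog.genes + [scaffold] + marker_genes
    bg_genes = [f"BG{i:04d}" for i in range(config.n_background_genes)]
    ext_genes = [f"EXT{i:04d}" for i in range(config.n_extended_genes)]
    genes = planted_genes + list(MITO_GENES) + bg_genes + ext_genes
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    regions_order = list(config.cells_per_region)
    region = np.concatenate(
        [np.repeat(r, config.cells_per_region[r]) for r in regions_order]
    ).astype(object)
    n = len(region)
    cell_ids = np.array([f"cell_{i + 1:06d}" for i in range(n)], dtype=object)
    dataset_id = np.array(
        [config.dataset_ids[i % len(config.dataset_ids)] for i in range(n)],
        dtype=object,
    )
    cluster_id = np.array(
        [config.cluster_of_region[r] for r in region], dtype=object
    )

    # --- QC classes and library sizes -----------------------------------
    p_violate = (config.frac_high_mito, config.frac_low_genes, config.frac_high_genes)
    qc_class = np.array(_QC_CLASSES, dtype=object)[
        rng.choice(4, size=n, p=(1 - sum(p_violate), *p_violate))
    ]
    lib = np.clip(
        rng.lognormal(config.library_log_mean, config.library_log_sd, n),
        *config.library_clip,
    )
    lib[qc_class == "low_genes"] = config.low_gene_library
    lib[qc_class == "high_genes"] = config.high_gene_library

    counts = np.zeros((n, n_genes), dtype=np.int64)
    bg_slice = slice(gene_pos[bg_genes[0]], gene_pos[bg_genes[-1]] + 1)
    ext_slice = slice(gene_pos[ext_genes[0]], gene_pos[ext_genes[-1]] + 1)
    w_bg = rng.gamma(2.0, 1.0, config.n_background_genes)
    w_ext = rng.gamma(2.0, 1.0, config.n_extended_genes)

    def nb_block(lib_sizes: np.ndarray, weights: np.ndarray) -> np.ndarray:
        w = weights / weights.sum()
        mu = np.outer(lib_sizes, w)
        d = config.nb_dispersion
        lam = rng.gamma(1.0 / d, d * mu)
        return rng.poisson(lam)

    normal_pool = np.isin(qc_class, ("pass", "high_mito"))
    low = qc_class == "low_genes"
    high = qc_class == "high_genes"
    if normal_pool.any():
        counts[np.ix_(normal_pool, np.arange(*bg_slice.indices(n_genes)))] = nb_block(
            lib[normal_pool], w_bg
        )
    if low.any():
        sub = np.arange(bg_slice.start, bg_slice.start + config.low_gene_pool)
        counts[np.ix_(low, sub)] = nb_block(lib[low], w_bg[: config.low_gene_pool])
    if high.any():
        both = np.arange(bg_slice.start, ext_slice.stop)
        counts[np.ix_(high, both)] = nb_block(
            lib[high], np.concatenate([w_bg, w_ext])
        )

    # --- mitochondrial fraction (deterministic totals, multinomial split) --
    base_total = counts.sum(axis=1)
    m_target = rng.uniform(*config.mito_fraction_range, n)
    hm = qc_class == "high_mito"
    m_target[hm] = rng.uniform(*config.contaminant_mito_range, hm.sum())
    mito_total = np.round(base_total * m_target / (1 - m_target)).astype(np.int64)
    mito_block = rng.multinomial(
        mito_total, np.full(len(MITO_GENES), 1 / len(MITO_GENES))
    )
    mito_cols = [gene_pos[g] for g in MITO_GENES]
    counts[:, mito_cols] = mito_block

    # --- planted transporter / scaffold positivity ----------------------
    truth_genes = catalog.genes + [scaffold]
    positivity = pd.DataFrame(
        False, index=pd.Index(cell_ids, name="cell_id"), columns=truth_genes
    )
    population = np.empty(n, dtype=object)

    for r in regions_order:
        mask = region == r
        idx = np.flatnonzero(mask)
        nr = idx.size
        probs = [config.population_probs[r][p] for p in POPULATIONS]
        pop_r = np.array(POPULATIONS, dtype=object)[_choice(rng, POPULATIONS, probs, nr)]
        population[idx] = pop_r

        ai_pos = np.isin(pop_r, ("AIP", "DIP"))
        bi_pos = np.isin(pop_r, ("BIP", "DIP"))

        # AI gene pattern among AI-positive cells
        ai_opts = ("SLC22A11", "SLC22A12", "both")
        ai_w = [config.ai_pattern["SLC22A11"], config.ai_pattern["SLC22A12"],
                config.ai_pattern["both"]]
        ai_pick = _choice(rng, ai_opts, ai_w, nr)
        a11 = ai_pos & np.isin(ai_pick, (0, 2))
        a12 = ai_pos & np.isin(ai_pick, (1, 2))

        # BI multiplicity and gene pattern among BI-positive cells
        p2 = _lookup(config.bi_multi2_prob, r)
        multi = rng.random(nr) < p2
        triple = multi & (rng.random(nr) < config.bi_triple_given_multi)
        singles = list(config.bi_single_weights)
        s_pick = _choice(rng, singles, list(config.bi_single_weights.values()), nr)
        pairs = list(config.bi_pair_weights)
        p_pick = _choice(rng, pairs, list(config.bi_pair_weights.values()), nr)
        bi_genes = {g: np.zeros(nr, dtype=bool) for g in ("SLC22A6", "SLC22A7", "SLC22A8")}
        for j, g in enumerate(singles):
            bi_genes[g] |= ~multi & (s_pick == j)
        for j, (g1, g2) in enumerate(pairs):
            hit = multi & ~triple & (p_pick == j)
            bi_genes[g1] |= hit
            bi_genes[g2] |= hit
        for g in bi_genes:
            bi_genes[g] |= triple
            bi_genes[g] &= bi_pos

        # efflux status per population
        u_ae, u_be = rng.random(nr), rng.random(nr)
        is_aip = pop_r == "AIP"
        is_bip = pop_r == "BIP"
        is_dip = pop_r == "DIP"
        is_din = pop_r == "DIN"
        ae = np.zeros(nr, dtype=bool)
        be = np.zeros(nr, dtype=bool)
        ae[is_aip] = u_ae[is_aip] < config.p_ae_given_aip
        be[is_aip] = u_be[is_aip] < _lookup(config.p_be_given_aip, r)
        ae[is_bip] = u_ae[is_bip] < config.p_ae_given_bip
        p_be_bip = np.where(
            ae, config.p_be_given_bip_ae_pos, config.p_be_given_bip_ae_neg
        )
        be[is_bip] = u_be[is_bip] < p_be_bip[is_bip]
        p_beo = _lookup(config.dip_be_only_prob, r)
        combo_w = [
            config.dip_both_prob,
            config.dip_ae_only_prob,
            p_beo,
            1 - config.dip_both_prob - config.dip_ae_only_prob - p_beo,
        ]
        combo = _choice(rng, ("both", "ae", "be", "none"), combo_w, nr)
        ae[is_dip] = np.isin(combo, (0, 1))[is_dip]
        be[is_dip] = np.isin(combo, (0, 2))[is_dip]
        ae[is_din] = u_ae[is_din] < config.p_ae_given_din
        be[is_din] = u_be[is_din] < config.p_be_given_din

        # AE gene pattern among AE-positive cells
        ae_opts = ("SLC17A1", "SLC17A3", "both")
        ae_w = [config.ae_pattern["SLC17A1"], config.ae_pattern["SLC17A3"],
                config.ae_pattern["both"]]
        ae_pick = _choice(rng, ae_opts, ae_w, nr)
        g171 = ae & np.isin(ae_pick, (0, 2))
        g173 = ae & np.isin(ae_pick, (1, 2))

        # scaffold positivity: coupled to apical multiplicity in DIP cells
        apical_count = (
            a11.astype(int) + a12.astype(int) + g171.astype(int) + g173.astype(int)
        )
        p_scaff = np.zeros(nr)
        p_scaff[is_dip] = np.minimum(
            config.scaffold_cap,
            config.scaffold_base_dip
            + config.scaffold_per_apical * apical_count[is_dip],
        )
        for p_name, p_val in config.scaffold_probs_other.items():
            p_scaff[pop_r == p_name] = p_val
        scaff = rng.random(nr) < p_scaff

        positivity.iloc[idx, positivity.columns.get_loc("SLC22A11")] = a11
        positivity.iloc[idx, positivity.columns.get_loc("SLC22A12")] = a12
        for g, v in bi_genes.items():
            positivity.iloc[idx, positivity.columns.get_loc(g)] = v
        positivity.iloc[idx, positivity.columns.get_loc("SLC17A1")] = g171
        positivity.iloc[idx, positivity.columns.get_loc("SLC17A3")] = g173
        positivity.iloc[idx, positivity.columns.get_loc("SLC2A9")] = be
        positivity.iloc[idx, positivity.columns.get_loc(scaffold)] = scaff

    # invert planted positives to counts on the current per-cell totals
    totals_now = counts.sum(axis=1)
    for g in truth_genes:
        pos = positivity[g].to_numpy()
        if not pos.any():
            continue
        levels = rng.uniform(*config.positive_level_range, int(pos.sum()))
        counts[pos, gene_pos[g]] = _plant_counts(
            rng, levels, totals_now[pos], config.scale_factor
        )

    # --- region marker genes ---------------------------------------------
    in_region = {
        g: np.zeros(n, dtype=bool) for g in marker_genes
    }
    for r in regions_order:
        for g in config.region_marker_map[r]:
            in_region[g.upper()] |= region == r
    for g in marker_genes:
        p = np.where(in_region[g], config.marker_pos_prob_in, config.marker_pos_prob_out)
        pos = rng.random(n) < p
        if not pos.any():
            continue
        levels = rng.uniform(*config.marker_level_range, int(pos.sum()))
        counts[pos, gene_pos[g]] = _plant_counts(
            rng, levels, totals_now[pos], config.scale_factor
        )

    matrix = CountMatrix(cell_ids, np.array(genes, dtype=object), sp.csr_matrix(counts))
    meta = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "dataset_id": dataset_id,
            "cluster_id": cluster_id,
            "region": "unassigned",
        }
    )

    pop_series = classify_population(positivity, catalog)
    ae_s, be_s = efflux_status(positivity, catalog)
    mode = transport_mode(pop_series, ae_s, be_s, dip_no_efflux=config.dip_no_efflux)
    assert (pop_series.to_numpy() == population).all()

    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "dataset_id": dataset_id,
            "cluster_id": cluster_id,
            "region": region,
            "population": pop_series.to_numpy(),
            "ae_pos": ae_s.to_numpy(),
            "be_pos": be_s.to_numpy(),
            "mode": mode.to_numpy(),
            "qc_class": qc_class,
        }
    )
    for g in truth_genes:
        truth[f"pos_{g}"] = positivity[g].to_numpy()
    return SyntheticDataset(matrix=matrix, meta=meta, truth=truth, config=config)
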