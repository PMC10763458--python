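# Methods

## Pipeline model

The analysis treats urate handling as a per-cell boolean circuit over
transporter expression.  Stages, in order:

1. **QC.** Per cell: detected genes (`n_genes`, strictly positive raw
   counts), total counts, and mitochondrial fraction (`pct_mito`, symbols
   prefixed `MT-`).  A cell is removed iff `pct_mito > max_pct_mito`
   (default 0.05), `n_genes < min_genes` (default 200), or
   `n_genes > max_genes` for its dataset (per-dataset upper thresholds,
   since depth and doublet rates are run-specific; default 6000 when no
   mapping is supplied).  All boundaries are strict — a cell exactly at a
   threshold is kept — because the filter definitions use strict
   inequalities ("more than", "less than") and equality has no natural
   assignment; we resolve it conservatively toward keeping data.  "Gene
   counts" is read as detected genes rather than total UMIs, following the
   standard tutorial convention the filter derives from; this is a
   documented reading, not a certainty.
2. **Normalization.** LogNormalize: value = ln(1 + count·SF/total), SF =
   10,000.  Plain ln of the scaled value is available as a switch
   (`log1p=False`) but is not the default since it is undefined at zero and
   the positivity cutoff is calibrated on the log1p scale.  Zero-total cells
   yield all-zero rows with a warning rather than an error.
3. **Region annotation.** Cluster labels are an *input* (the unsupervised
   clustering/integration stack that produces them is deliberately outside
   the tested core; any standard recipe works).  Each cluster is scored
   against each candidate region as the mean percent-expressed of that
   region's marker genes; ties break by mean average expression, then
   lexical region order, and are logged.  A cluster whose best score is zero
   stays `unassigned`.  Proximal-tubule clusters (coarse `PT` label, markers
   CUBN/LRP2) are split S1/S2/S3: best S1-marker scorer → S1, best S3 scorer
   among the rest → S3, remainder → S2, since only S1 and S3 have specific
   markers.  This scoring rule is a deterministic, auditable formalization
   of what is usually done by eye; it reproduces manual annotation whenever
   markers are specific.  The packaged marker tables (regions: e.g. NPHS1/2
   for podocytes, UMOD/SLC12A1 for the ascending limb; segments:
   SLC5A2/SLC5A12 for S1, SLC7A13/SLC5A10 for S3) are defaults drawn from
   the human-kidney single-cell literature and are meant to be replaced by
   the user's own lists when they differ.
4. **Binarization & classification.** Positivity is `value > cutoff` with
   cutoff 0.5 — strict, so a value exactly at the cutoff is negative
   (equality has measure ≈ 0 on this scale; the choice is conservative).
   Population = set logic over AI/BI positivity; mode = decision-table
   lookup on (population, any-AE, any-BE).  The one genuinely ambiguous
   cell: DIP with no efflux transporter.  Physiologically such a cell can
   still flux urate if an influx transporter reverses when the intracellular
   concentration exceeds its equilibrium; the default policy therefore
   counts it as `bidirectional`, with `undetermined` available for analyses
   that prefer not to assume reversibility.  Classification is restricted by
   default to PT_S1/S2/S3 and LOH_DL, the regions where the catalog
   transporters are specifically expressed; the region list is a parameter.
5. **Summaries.** Pure counting: regional population/mode composition,
   reabsorption:secretion cell ratio (NaN when no secreting cells), influx
   multiplicity (0/1/2+ distinct positive genes of one membrane side),
   SLC2A9 positivity among BIP:AE⁺ cells, scaffold (PDZK1, same 0.5 cutoff
   — one positivity rule for all genes) cross-tabs within DIP, and a
   long-format population × efflux-status × region count table.  "Average
   mode proportions" are the unweighted mean across the four regions of
   mode fractions among *functional* (non-unfunctional) cells; computed this
   way the three proportions sum to 100%, which is the reading under which
   a printed secretion/bidirectional/reabsorption triplet can total 100%.

The eight-gene catalog ships with Km-for-urate annotations (µM) for
reference only; no kinetic or flux-magnitude inference is performed, and
transporters outside the eight (ABCG2, ABCC4, SLC22A13 — rarely expressed
or confined to intercalated cells) are representable in a user catalog but
excluded from the default.

## Synthetic data: what it emulates, and what it does not

`GeneratorConfig()` — equivalently `reference_config()` — is the reference
condition used throughout the tests and the acceptance script: 10,000 cells
(PT_S1 2900, PT_S2 2700, PT_S3 2500, LOH_DL 1500, plus small LOH_AL/DCT
blocks that exercise region scoping), three synthetic dataset ids with
per-dataset gene-count ceilings, ~800 negative-binomial background genes
(dispersion 0.3) with log-normal library sizes (median ≈ 2,200 counts,
clipped to [800, 4000]), 13 `MT-` genes planted to a target mitochondrial
fraction per cell (0.5–3.5% normally; 8–15% in a 5% contaminant
subpopulation), and 2% each of planted low-gene and high-gene (doublet-like)
violators.  Violator construction is deterministic with margin — e.g. the
low-gene pool (150 genes + planted) cannot reach the 200-gene floor — so the
truth flag and the filter decision must agree exactly, which is what the QC
exactness tests assert.

Transporter positivity is planted on the *normalized* scale (positive levels
drawn U(1.2, 3.0), well above the 0.5 cutoff) and inverted to counts;
negatives are exact zero counts.  Cutoff behavior is therefore controlled by
construction and label recovery through the pipeline is exact, which is what
makes fraction-recovery tests pure binomial-sampling checks.  Planted
structure mirrors the reference condition: S1 populations
AIP/BIP/DIP/DIN = 0.029/0.44/0.47/0.061 declining toward the DL
(0.04/0.14/0.054/0.766); SLC22A11 dominant among AI genes (80% single,
5% both); BI co-expression (≥2 genes) at 60/33/60/17% across S1/S2/S3/DL;
P(SLC2A9⁺ | BIP, AE⁺) = 0.70; AIP BE-positivity and DIP efflux mixtures
chosen per region so the expected reabsorption:secretion ratio rises
≈ 0.05 → 0.10 → 0.16 → 0.33 along S1→DL; PDZK1 positivity in DIP rising
with apical transporter count (0.35 + 0.12·k, capped at 0.9, ≈ 60%
overall).  Region markers are planted at 80% in-region vs 5% out-of-region
positivity.

What the generator does **not** emulate: batch effects, ambient RNA,
doublets beyond the high-gene class, gene–gene correlation in the
background, dropout structure tied to expression level, or continuous
(rather than planted-binary) transporter expression near the cutoff.
Passing the recovery tests therefore shows the pipeline implements its
definitions correctly and is unbiased under clean detection; it does not
show robustness to the measurement noise of real tissue, where cells near
the cutoff will flip with sequencing depth.

## Numerical and design notes

- Counts are validated as non-negative integers; gene symbols are
  upper-cased on ingest and duplicate identifiers are hard errors naming
  the offender.  Symbol mapping (many-to-one) sums counts of collapsing
  rows and keeps unmapped identifiers verbatim so QC totals do not depend
  on mapping coverage; the summation rule for ambiguous mappings is a
  package choice.
- The QC rejection report lists the *first* failing rule per cell, checked
  in the order mito → min genes → max genes.
- `filter_cells` is idempotent, and normalization commutes with cell
  filtering (both per-cell); these are tested invariants.
- Fraction tables are exact rational counts; sums-to-one checks hold to
  1e-12.  Zero denominators yield NaN plus an explicit `undefined` flag
  rather than raising.
- Pipeline outputs are byte-deterministic given config + inputs; each table
  carries a SHA-256 config hash (output directory excluded from the hash).
- Test and acceptance problem sizes: unit fixtures run at ~1,000 cells;
  partition/conservation checks at 20 × 2,000 cells; parameter recovery at
  20 × 10,000 cells.  These sizes make binomial standard errors small
  relative to the planted effects while keeping the suite fast.

## Known limitations

- mRNA positivity is a proxy for functional membrane protein; the mode
  labels are transcriptional predictions, not flux measurements.
- The 0.5 cutoff is a global constant; per-gene or per-dataset cutoffs are
  not modeled.
- PT segment assignment is defined only for exactly three PT clusters, by
  construction of the S2-by-elimination rule.
- Marker defaults are literature-derived conveniences; regional annotation
  quality on real data is bounded by the marker lists supplied.
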