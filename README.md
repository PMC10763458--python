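# uratome

Cell-level classification of renal urate transport from single-nucleus
RNA-seq.

## The problem

Renal urate excretion is a reabsorption-dominant balance of transcellular
reabsorption and secretion across the proximal tubule (PT) and, to a lesser
degree, the descending limb of the loop of Henle (DL).  Both processes
require a pair of transporters in the *same* cell: an influx transporter on
one membrane and an efflux transporter on the opposite membrane.  Whether
individual tubular cells actually carry such complete transporter sets — and
in which direction each cell can move urate — is a single-cell question.

`uratome` answers it from single-nucleus RNA-seq count matrices.  Eight SLC
transporters are classified by membrane side and flux direction:

| type | meaning            | genes                        |
|------|--------------------|------------------------------|
| AI   | apical influx      | SLC22A11 (OAT4), SLC22A12 (URAT1) |
| AE   | apical efflux      | SLC17A1 (NPT1), SLC17A3 (NPT4) |
| BI   | basolateral influx | SLC22A6 (OAT1), SLC22A7 (OAT2), SLC22A8 (OAT3) |
| BE   | basolateral efflux | SLC2A9 (GLUT9)               |

Each QC-passing cell is binarized per gene on the log-normalized scale
(positive iff value > 0.5, where value = ln(1 + 10⁴·count/total)), called
into an influx population —

* **AIP**: ≥1 AI gene positive, all BI negative
* **BIP**: ≥1 BI gene positive, all AI negative
* **DIP**: both sides positive
* **DIN**: neither side positive

— and assigned a net transport mode by a fixed decision table on
(population, AE status, BE status): AIP+BE → **reabsorption**, BIP+AE →
**secretion**, DIP with both efflux types → **bidirectional**, DIP with one
efflux type → that direction, anything without a complete route →
**unfunctional** (DIP with no efflux gene is counted as bidirectional by
default, reflecting transporter reversibility; a policy switch reports it as
undetermined instead).  Summary tables then give population and mode
composition per region, reabsorption:secretion cell ratios along the
nephron, transporter co-expression multiplicity, SLC2A9 positivity in
secretion-competent BIP cells, and PDZK1 scaffold cross-tabulations in the
DIP population.

The package is aimed at anyone quantifying transporter-defined cell states
in kidney (or adapting the same set logic to another polarized epithelium):
the transporter catalog, marker tables, cutoff, and region scope are all
data, not code.

## Worked example

Everything is testable offline: the `synthetic` module generates count
matrices with planted region markers, QC violators, and per-cell transporter
positivity with known labels.

```python
from uratome import reference_config, synthetic, qc, transportome, summarize

ds = synthetic.generate(reference_config(seed=1))          # ~10,000 cells
metrics = qc.compute_qc(ds.matrix)
kept, rejected = qc.filter_cells(
    ds.matrix, metrics, ds.config.qc_thresholds(),
    ds.meta.set_index("cell_id")["dataset_id"],
)
nm = qc.lognormalize(kept)
meta = ds.meta.assign(
    region=ds.meta["cell_id"].map(ds.truth.set_index("cell_id")["region"])
)
calls = transportome.classify_cells(nm, meta)
rs = summarize.regional_summary(calls).set_index("region")
print(rs[["n_cells", "frac_BIP", "frac_DIP", "reabs_secr_ratio"]].round(3))
```

prints (seed 1):

```
        n_cells  frac_BIP  frac_DIP  reabs_secr_ratio
region
PT_S1      2632     0.437     0.470             0.051
PT_S2      2464     0.496     0.291             0.109
PT_S3      2256     0.487     0.343             0.188
LOH_DL     1349     0.120     0.050             0.336
```

Read: BIP and DIP dominate the early proximal tubule (planted fractions
0.44 / 0.47 at S1) and fall toward the descending limb, while the ratio of
reabsorbing to secreting cells rises monotonically along the tubule — the
planted gradients, recovered through the full pipeline.  With real data,
replace the generator output with `io.read_count_matrix(...)` (matrix-market
plus cell/gene sidecars, or a dense TSV) and a metadata TSV; if `region` is
not pre-assigned, cluster labels plus the packaged marker tables drive
annotation (`uratome run --config run.yaml` does all stages).

A CLI mirrors the library: `uratome simulate|qc|classify|summarize|run`.

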