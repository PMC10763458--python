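import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from uratome import qc, synthetic, transportome
from uratome.io import CountMatrix


SMALL_REGIONS = {
    "PT_S1": 290,
    "PT_S2": 270,
    "PT_S3": 250,
    "LOH_DL": 150,
    "LOH_AL": 30,
    "DCT": 10,
}


def small_config(seed: int = 7, **overrides) -> synthetic.GeneratorConfig:
    """The reference condition scaled to ~1,000 cells for fast tests."""
    return dataclasses.replace(
        synthetic.GeneratorConfig(seed=seed),
        cells_per_region=overrides.pop("cells_per_region", SMALL_REGIONS),
        **overrides,
    )


def make_counts(array, cell_ids=None, gene_symbols=None) -> CountMatrix:
    a = np.asarray(array)
    cells = cell_ids or [f"c{i}" for i in range(a.shape[0])]
    genes = gene_symbols or [f"G{j}" for j in range(a.shape[1])]
    return CountMatrix(
        np.asarray(cells, dtype=object),
        np.asarray(genes, dtype=object),
        sp.csr_matrix(a),
    )


@pytest.fixture(scope="session")
def small_ds() -> synthetic.SyntheticDataset:
    return synthetic.generate(small_config(seed=7))


@pytest.fixture(scope="session")
def classified(small_ds):
    """QC'd, normalized and classified version of the small dataset."""
    cfg = small_ds.config
    metrics = qc.compute_qc(small_ds.matrix)
    filt, rej = qc.filter_cells(
        small_ds.matrix,
        metrics,
        cfg.qc_thresholds(),
        small_ds.meta.set_index("cell_id")["dataset_id"],
    )
    nm = qc.lognormalize(filt)
    meta = small_ds.meta.copy()
    meta["region"] = meta["cell_id"].map(small_ds.truth.set_index("cell_id")["region"])
    catalog = transportome.default_catalog()
    calls = transportome.classify_cells(nm, meta)
    bp = transportome.binarize(
        nm.subset_cells(calls["cell_id"].to_numpy()),
        list(catalog.genes) + ["PDZK1"],
    )
    truth = small_ds.truth.set_index("cell_id").loc[calls["cell_id"]]
    return {
        "nm": nm,
        "meta": meta,
        "calls": calls,
        "bp": bp,
        "catalog": catalog,
        "truth": truth,
        "rejections": rej,
    }
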