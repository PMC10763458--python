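import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from uratome import qc, transportome
from uratome.io import NormalizedMatrix
from uratome.transportome import (
    POPULATIONS,
    binarize,
    classify_cells,
    classify_population,
    default_catalog,
    efflux_status,
    transport_mode,
)

from conftest import make_counts


# Independently hand-coded decision table: (population, ae, be) -> mode.
# Reabsorption needs apical influx + basolateral efflux; secretion needs
# basolateral influx + apical efflux; dual-influx cells may do either or both.
ORACLE = {
    ("AIP", False, False): "unfunctional",
    ("AIP", True, False): "unfunctional",
    ("AIP", True, True): "reabsorption",
    ("AIP", False, True): "reabsorption",
    ("BIP", False, False): "unfunctional",
    ("BIP", True, False): "secretion",
    ("BIP", True, True): "secretion",
    ("BIP", False, True): "unfunctional",
    ("DIP", False, False): None,  # policy-dependent
    ("DIP", True, False): "secretion",
    ("DIP", True, True): "bidirectional",
    ("DIP", False, True): "reabsorption",
    ("DIN", False, False): "unfunctional",
    ("DIN", True, False): "unfunctional",
    ("DIN", True, True): "unfunctional",
    ("DIN", False, True): "unfunctional",
}


def nm_from_dense(values, genes):
    values = np.asarray(values, dtype=float)
    return NormalizedMatrix(
        np.asarray([f"c{i}" for i in range(values.shape[0])], dtype=object),
        np.asarray(genes, dtype=object),
        sp.csr_matrix(values),
    )


class TestBinarize:
    def test_strict_cutoff_boundary(self):
        nm = nm_from_dense([[0.6, 0.5, 0.4999]], ["A", "B", "C"])
        bp = binarize(nm, ["A", "B", "C"], cutoff=0.5)
        assert bp.iloc[0].tolist() == [True, False, False]
        assert bp.attrs["cutoff"] == 0.5

    def test_missing_gene_all_negative_with_warning(self):
        nm = nm_from_dense([[1.0]], ["A"])
        with pytest.warns(UserWarning, match="absent"):
            bp = binarize(nm, ["A", "MISSING"])
        assert bp["MISSING"].tolist() == [False]
        assert bp["A"].tolist() == [True]

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(3)
        vals = rng.random((20, 6)) * 2
        genes = [f"G{j}" for j in range(6)]
        nm = nm_from_dense(vals, genes)
        bp = binarize(nm, genes, cutoff=0.7)
        for i in range(20):
            for j in range(6):
                assert bp.iloc[i, j] == (vals[i, j] > 0.7)


class TestClassifyPopulation:
    @pytest.fixture()
    def catalog(self):
        return default_catalog()

    def _profile(self, positives):
        cols = default_catalog().genes
        return pd.DataFrame(
            [[g in positives for g in cols]], index=["cell"], columns=cols
        )

    @pytest.mark.parametrize(
        "positives,expected",
        [
            (("SLC22A11",), "AIP"),
            (("SLC22A11", "SLC22A6"), "DIP"),
            ((), "DIN"),
            (("SLC22A7",), "BIP"),
            (("SLC17A1", "SLC2A9"), "DIN"),  # efflux genes alone do not count
        ],
    )
    def test_examples(self, catalog, positives, expected):
        assert classify_population(self._profile(positives), catalog).iloc[0] == expected

    def test_exhaustive_influx_patterns_match_rule(self, catalog):
        """All 2^5 influx on/off patterns agree with the set-logic definition."""
        influx = ["SLC22A11", "SLC22A12", "SLC22A6", "SLC22A7", "SLC22A8"]
        for pattern in itertools.product([False, True], repeat=5):
            positives = tuple(g for g, on in zip(influx, pattern) if on)
            ai = bool(set(positives) & {"SLC22A11", "SLC22A12"})
            bi = bool(set(positives) & {"SLC22A6", "SLC22A7", "SLC22A8"})
            expected = {(True, False): "AIP", (False, True): "BIP",
                        (True, True): "DIP", (False, False): "DIN"}[(ai, bi)]
            assert classify_population(self._profile(positives), catalog).iloc[0] == expected


class TestTransportMode:
    @pytest.mark.parametrize("pop,ae,be", list(ORACLE))
    def test_matches_hand_coded_oracle(self, pop, ae, be):
        expected = ORACLE[(pop, ae, be)]
        if expected is None:
            assert transport_mode(pop, ae, be, "bidirectional") == "bidirectional"
            assert transport_mode(pop, ae, be, "undetermined") == "undetermined"
        else:
            assert transport_mode(pop, ae, be, "bidirectional") == expected
            assert transport_mode(pop, ae, be, "undetermined") == expected

    def test_vectorized_agrees_with_scalar(self):
        combos = list(ORACLE)
        pops, aes, bes = zip(*combos)
        vec = transport_mode(pd.Series(pops), pd.Series(aes), pd.Series(bes))
        for k, combo in enumerate(combos):
            assert vec.iloc[k] == transport_mode(*combo)

    def test_rejects_unknown_inputs(self):
        with pytest.raises(ValueError, match="policy|dip_no_efflux"):
            transport_mode("DIP", False, False, "maybe")
        with pytest.raises(ValueError, match="population"):
            transport_mode("XIP", False, False)


class TestClassifyCells:
    def test_recovers_planted_labels_exactly(self, classified):
        calls, truth = classified["calls"], classified["truth"]
        assert (calls["population"].to_numpy() == truth["population"].to_numpy()).all()
        assert (calls["mode"].to_numpy() == truth["mode"].to_numpy()).all()
        assert (calls["ae_pos"].to_numpy() == truth["ae_pos"].to_numpy()).all()
        assert set(calls["region"]) == {"PT_S1", "PT_S2", "PT_S3", "LOH_DL"}

    def test_populations_partition_the_cells(self, classified):
        counts = classified["calls"]["population"].value_counts()
        assert counts.sum() == len(classified["calls"])
        assert set(counts.index) <= set(POPULATIONS)

    def test_no_cells_in_target_regions_is_an_error(self, classified):
        nm, meta = classified["nm"], classified["meta"]
        with pytest.raises(ValueError, match="target region"):
            classify_cells(nm, meta, regions=("Podo",))
        with pytest.raises(ValueError, match="at least one"):
            classify_cells(nm, meta, regions=())

    def test_huge_cutoff_gives_all_din_unfunctional(self, classified):
        calls = classify_cells(classified["nm"], classified["meta"], cutoff=1e9)
        assert (calls["population"] == "DIN").all()
        assert (calls["mode"] == "unfunctional").all()

    def test_invariant_to_cell_order_and_foreign_genes(self, classified):
        nm, meta = classified["nm"], classified["meta"]
        rng = np.random.default_rng(0)
        perm = rng.permutation(nm.n_cells)
        shuffled = nm.subset_cells(np.asarray(nm.cell_ids)[perm])
        a = classify_cells(nm, meta).set_index("cell_id")
        b = classify_cells(shuffled, meta).set_index("cell_id").loc[a.index]
        pd.testing.assert_frame_equal(a, b)
        # doubling a non-catalog gene's values changes nothing
        mutated = NormalizedMatrix(
            nm.cell_ids.copy(), nm.gene_symbols.copy(), nm.values.copy()
        )
        j = list(nm.gene_symbols).index("BG0000")
        mutated.values[:, j] = mutated.values[:, j] * 2
        c = classify_cells(mutated, meta).set_index("cell_id").loc[a.index]
        pd.testing.assert_frame_equal(a, c)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    data=st.data(),
    n_cells=st.integers(2, 12),
    lo=st.floats(0.1, 1.0),
)
def test_raising_cutoff_only_shrinks_positive_sets(data, n_cells, lo):
    """DIN cells can never leave DIN when the cutoff increases."""
    genes = default_catalog().genes
    vals = data.draw(
        st.lists(
            st.lists(st.floats(0, 3), min_size=len(genes), max_size=len(genes)),
            min_size=n_cells,
            max_size=n_cells,
        )
    )
    nm = nm_from_dense(np.array(vals), genes)
    cat = default_catalog()
    low = classify_population(binarize(nm, genes, cutoff=lo), cat)
    high = classify_population(binarize(nm, genes, cutoff=lo + 0.7), cat)
    assert ((low == "DIN") <= (high == "DIN")).all()
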