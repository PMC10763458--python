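import numpy as np
import pandas as pd
import pytest

from uratome import summarize
from uratome.transportome import MODES, POPULATIONS


@pytest.fixture(scope="module")
def parts(classified):
    return (
        classified["calls"],
        classified["bp"],
        classified["catalog"],
        classified["nm"],
    )


class TestRegionalSummary:
    def test_fractions_sum_to_one_and_counts_conserve(self, parts):
        calls, *_ = parts
        rs = summarize.regional_summary(calls)
        pop_frac = rs[[f"frac_{p}" for p in POPULATIONS]].sum(axis=1)
        mode_frac = rs[[f"frac_{m}" for m in MODES]].sum(axis=1)
        assert np.allclose(pop_frac, 1.0, atol=1e-12)
        assert np.allclose(mode_frac, 1.0, atol=1e-12)
        assert rs["n_cells"].sum() == len(calls)

    def test_matches_per_cell_loop(self, parts):
        calls, *_ = parts
        rs = summarize.regional_summary(calls).set_index("region")
        for region in rs.index:
            sub = calls[calls["region"] == region]
            for pop in POPULATIONS:
                n = sum(1 for p in sub["population"] if p == pop)
                assert rs.loc[region, f"n_{pop}"] == n
                assert rs.loc[region, f"frac_{pop}"] == pytest.approx(n / len(sub))
            n_re = sum(1 for m in sub["mode"] if m == "reabsorption")
            n_se = sum(1 for m in sub["mode"] if m == "secretion")
            want = n_re / n_se if n_se else np.nan
            got = rs.loc[region, "reabs_secr_ratio"]
            assert got == pytest.approx(want, nan_ok=True)

    def test_hand_ratio(self):
        calls = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(26)],
                "region": "PT_S1",
                "population": "BIP",
                "ae_pos": True,
                "be_pos": False,
                "mode": ["reabsorption"] + ["secretion"] * 25,
            }
        )
        rs = summarize.regional_summary(calls)
        assert rs.loc[0, "reabs_secr_ratio"] == pytest.approx(0.04)

    def test_equal_populations_give_quarter_fractions(self):
        calls = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(8)],
                "region": "PT_S2",
                "population": list(POPULATIONS) * 2,
                "ae_pos": False,
                "be_pos": False,
                "mode": "unfunctional",
            }
        )
        rs = summarize.regional_summary(calls)
        for pop in POPULATIONS:
            assert rs.loc[0, f"frac_{pop}"] == pytest.approx(0.25)


class TestInfluxMultiplicity:
    @pytest.mark.parametrize("which", ["AI", "BI"])
    def test_matches_per_cell_loop(self, parts, which):
        calls, bp, catalog, _ = parts
        genes = catalog.ai_genes if which == "AI" else catalog.bi_genes
        tab = summarize.influx_multiplicity(bp, calls, catalog, which=which)
        mult = tab[tab["axis"] == "multiplicity"]
        for (region, pop), grp in mult.groupby(["region", "population"]):
            sub = calls[(calls["region"] == region) & (calls["population"] == pop)]
            ks = [int(bp.loc[c, genes].sum()) for c in sub["cell_id"]]
            expected = {
                "0": sum(k == 0 for k in ks),
                "1": sum(k == 1 for k in ks),
                "2+": sum(k >= 2 for k in ks),
            }
            got = grp.set_index("category")["n"].to_dict()
            assert got == expected
            assert grp["frac"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_definitional_constraints(self, parts):
        calls, bp, catalog, _ = parts
        ai = summarize.influx_multiplicity(bp, calls, catalog, which="AI")
        # an AIP or DIP cell has >= 1 positive AI gene by definition
        zero_ai = ai[
            (ai["axis"] == "multiplicity")
            & (ai["category"] == "0")
            & ai["population"].isin(["AIP", "DIP"])
        ]
        assert (zero_ai["n"] == 0).all()
        combos = ai[ai["axis"] == "ai_combination"]
        for _, grp in combos.groupby(["region", "population"]):
            if grp["n"].sum() > 0:
                assert grp["frac"].sum() == pytest.approx(1.0, abs=1e-12)


class TestBeInSecretors:
    def test_matches_per_cell_loop(self, parts):
        calls, bp, _, _ = parts
        tab = summarize.be_in_secretors(calls, bp).set_index("region")
        for region in tab.index:
            sub = calls[
                (calls["region"] == region)
                & (calls["population"] == "BIP")
                & calls["ae_pos"]
            ]
            n_pos = sum(bool(bp.loc[c, "SLC2A9"]) for c in sub["cell_id"])
            assert tab.loc[region, "n_bip_ae_pos"] == len(sub)
            assert tab.loc[region, "n_be_pos"] == n_pos
            assert tab.loc[region, "frac_be_pos"] == pytest.approx(n_pos / len(sub))

    def test_zero_denominator_is_flagged(self):
        calls = pd.DataFrame(
            {
                "cell_id": ["c1"],
                "region": "PT_S1",
                "population": "AIP",
                "ae_pos": False,
                "be_pos": True,
                "mode": "reabsorption",
            }
        )
        bp = pd.DataFrame({"SLC2A9": [True]}, index=["c1"])
        with pytest.warns(UserWarning, match="undefined"):
            tab = summarize.be_in_secretors(calls, bp)
        assert tab.loc[0, "undefined"]
        assert np.isnan(tab.loc[0, "frac_be_pos"])

    def test_direct_fraction(self):
        calls = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(10)],
                "region": "PT_S3",
                "population": "BIP",
                "ae_pos": True,
                "be_pos": [True] * 7 + [False] * 3,
                "mode": "secretion",
            }
        )
        bp = pd.DataFrame(
            {"SLC2A9": [True] * 7 + [False] * 3}, index=calls["cell_id"]
        )
        tab = summarize.be_in_secretors(calls, bp)
        assert tab.loc[0, "frac_be_pos"] == pytest.approx(0.7)


class TestScaffoldCrosstab:
    def test_matches_per_cell_loop(self, parts):
        calls, bp, catalog, _ = parts
        tabs = summarize.scaffold_crosstab(bp, calls, catalog)

        by_pop = tabs["by_population"].set_index("population")
        for pop in POPULATIONS:
            sub = calls[calls["population"] == pop]
            n_pos = sum(bool(bp.loc[c, "PDZK1"]) for c in sub["cell_id"])
            assert by_pop.loc[pop, "n_scaffold_pos"] == n_pos

        dip = calls[calls["population"] == "DIP"]
        apical = {
            c: int(bp.loc[c, catalog.apical_genes].sum()) for c in dip["cell_id"]
        }
        scaff = {c: bool(bp.loc[c, "PDZK1"]) for c in dip["cell_id"]}
        by_apical = tabs["by_apical_count"]
        for _, row in by_apical.iterrows():
            want = sum(
                1
                for c in dip["cell_id"]
                if scaff[c] == (row["scaffold"] == "positive")
                and apical[c] == int(row["category"])
            )
            assert row["n"] == want

        for key in ("by_apical_count", "by_bi_multiplicity", "by_efflux_combo"):
            for _, grp in tabs[key].groupby("scaffold"):
                assert grp["frac"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_efflux_combo_counts(self, parts):
        calls, bp, catalog, _ = parts
        tabs = summarize.scaffold_crosstab(bp, calls, catalog)
        combo_tab = tabs["by_efflux_combo"]
        dip = calls[calls["population"] == "DIP"]
        total = combo_tab["n"].sum()
        assert total == len(dip)

    def test_absent_scaffold_warns_all_negative(self, parts):
        calls, bp, catalog, _ = parts
        with pytest.warns(UserWarning, match="absent"):
            tabs = summarize.scaffold_crosstab(
                bp.drop(columns="PDZK1"), calls, catalog, scaffold_gene="PDZK1"
            )
        assert (tabs["by_population"]["n_scaffold_pos"] == 0).all()


class TestAverageModeProportions:
    def test_sums_to_one_and_matches_loop(self, parts):
        calls, *_ = parts
        avg = summarize.average_mode_proportions(calls)
        assert sum(avg.values()) == pytest.approx(1.0, abs=1e-12)
        functional = ("reabsorption", "secretion", "bidirectional")
        regions = sorted(set(calls["region"]))
        for mode in functional:
            vals = []
            for region in regions:
                sub = calls[
                    (calls["region"] == region) & calls["mode"].isin(functional)
                ]
                vals.append((sub["mode"] == mode).mean())
            assert avg[mode] == pytest.approx(np.mean(vals))

    def test_region_without_functional_cells_is_skipped(self):
        calls = pd.DataFrame(
            {
                "cell_id": ["c1", "c2"],
                "region": ["PT_S1", "PT_S2"],
                "population": ["BIP", "DIN"],
                "ae_pos": [True, False],
                "be_pos": [False, False],
                "mode": ["secretion", "unfunctional"],
            }
        )
        with pytest.warns(UserWarning, match="PT_S2"):
            avg = summarize.average_mode_proportions(calls, ("PT_S1", "PT_S2"))
        assert avg["secretion"] == pytest.approx(1.0)


class TestPopulationDotstats:
    def test_matches_group_loop(self, parts):
        calls, _, _, nm = parts
        stats = summarize.population_expression_dotstats(nm, calls, ["SLC2A9"])
        gene_idx = list(nm.gene_symbols).index("SLC2A9")
        cell_pos = {c: i for i, c in enumerate(nm.cell_ids)}
        dense = np.asarray(nm.values[:, gene_idx].todense()).ravel()
        for _, row in stats.iterrows():
            sub = calls[
                (calls["population"] == row["population"])
                & (calls["region"] == row["region"])
            ]
            vals = np.array([dense[cell_pos[c]] for c in sub["cell_id"]])
            assert row["pct_exp"] == pytest.approx((vals > 0).mean())
            assert row["avg_exp"] == pytest.approx(vals.mean())


class TestPopulationEffluxCounts:
    def test_counts_conserve_and_match_groupby(self, parts):
        calls, *_ = parts
        tab = summarize.population_efflux_counts(calls)
        assert tab["n_cells"].sum() == len(calls)
        one = tab.iloc[0]
        n = len(
            calls[
                (calls["region"] == one["region"])
                & (calls["population"] == one["population"])
                & (calls["ae_pos"] == one["ae_pos"])
                & (calls["be_pos"] == one["be_pos"])
            ]
        )
        assert one["n_cells"] == n
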