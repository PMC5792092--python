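"""Composition accounting and differential statistics on intensity tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from erstress import proteomics as pr
from erstress import synthetic as syn


@pytest.fixture(scope="module")
def proteome():
    return syn.gen_proteome_table(syn.default_truth(seed=1234))


@pytest.fixture(scope="module")
def composition(proteome):
    return pr.composition_summary(proteome, top_n=500)


class TestReadProteinGroups:
    def _write(self, path, rows):
        header = ("Majority protein IDs\tProtein names\tReverse\t"
                  "Potential contaminant\tIntensity 0\tIntensity 1")
        path.write_text("\n".join([header] + rows) + "\n")

    def test_reverse_and_contaminant_rows_dropped(self, tmp_path):
        f = tmp_path / "pg.tsv"
        self._write(f, [
            "P1\tBiP\t\t\t100\t200",
            "REV__P2\tdecoy\t+\t\t50\t60",
            "P3\tkeratin\t\t+\t10\t20",
        ])
        df = pr.read_protein_groups(f)
        assert list(df.protein_id) == ["P1"]
        assert df.loc[0, "intensity_day0"] == 100

    def test_duplicate_ids_rejected(self, tmp_path):
        f = tmp_path / "pg.tsv"
        self._write(f, ["P1\ta\t\t\t1\t2", "P1\tb\t\t\t3\t4"])
        with pytest.raises(pr.SchemaError, match="duplicate"):
            pr.read_protein_groups(f)

    def test_missing_mapped_column_named_in_error(self, tmp_path):
        f = tmp_path / "pg.tsv"
        f.write_text("id\tIntensity 0\nP1\t5\n")
        with pytest.raises(pr.SchemaError, match="Majority protein IDs"):
            pr.read_protein_groups(f)

    def test_synthetic_table_round_trip(self, tmp_path, proteome):
        f = tmp_path / "table.tsv"
        renamed = proteome.rename(columns={
            "protein_id": "Majority protein IDs",
            "name": "Protein names",
            **{f"intensity_day{d}": f"Intensity {d}" for d in (0, 1, 3, 7)},
        })
        renamed.to_csv(f, sep="\t", index=False)
        back = pr.read_protein_groups(f)
        for d in (0, 1, 3, 7):
            np.testing.assert_allclose(
                back[f"intensity_day{d}"], proteome[f"intensity_day{d}"])


class TestSelectAbundant:
    def test_identical_rankings_give_exactly_top_n(self):
        df = pd.DataFrame({
            "protein_id": [f"P{i}" for i in range(10)],
            "intensity_day0": np.arange(10, 0, -1.0),
            "intensity_day1": 2 * np.arange(10, 0, -1.0),
        })
        assert len(pr.select_abundant(df, top_n=4)) == 4

    def test_reversed_rankings_union_enumerated_by_hand(self):
        # day0 ranks A>B>C, day1 ranks C>B>A; top-2 union = {A,B,C}
        df = pd.DataFrame({
            "protein_id": ["A", "B", "C"],
            "intensity_day0": [30.0, 20.0, 10.0],
            "intensity_day1": [10.0, 20.0, 30.0],
        })
        sel = pr.select_abundant(df, top_n=2)
        assert set(sel) == {"A", "B", "C"}

    def test_monotone_in_top_n(self, proteome):
        small = set(pr.select_abundant(proteome, top_n=300))
        large = set(pr.select_abundant(proteome, top_n=500))
        assert small <= large

    def test_default_selection_covers_over_90_percent(self, composition):
        assert (composition.coverage > 0.90).all()

    def test_nonpositive_top_n_rejected(self, proteome):
        with pytest.raises(ValueError):
            pr.select_abundant(proteome, top_n=0)


class TestCompositionAccounting:
    def test_single_compartment_toy(self):
        df = pd.DataFrame({
            "protein_id": ["A", "B"],
            "name": ["a", "b"],
            "compartment": ["cytosol", "cytosol"],
            "intensity_day0": [3.0, 7.0],
        })
        frac = pr.compartment_fractions(df)
        assert frac.loc[0, "cytosol"] == pytest.approx(1.0)

    def test_day0_er_fraction_three_percent(self, composition):
        frac = composition.compartment_fractions
        er = frac.loc[0, "ER_resident"] + frac.loc[0, "client_mus"]
        assert er == pytest.approx(0.03, abs=0.005)

    def test_fractions_sum_to_one_every_day(self, composition):
        sums = composition.compartment_fractions.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, rtol=1e-12)

    def test_invariant_to_global_rescaling(self, proteome):
        scaled = proteome.copy()
        for d in (0, 1, 3, 7):
            scaled[f"intensity_day{d}"] *= 37.5
        a = pr.compartment_fractions(proteome)
        b = pr.compartment_fractions(scaled)
        pd.testing.assert_frame_equal(a, b)


class TestErInternalShares:
    def test_lone_bip_table(self):
        df = pd.DataFrame({
            "protein_id": ["A", "B"],
            "name": ["BiP", "actin"],
            "compartment": ["ER_resident", "cytosol"],
            "intensity_day0": [5.0, 95.0],
        })
        shares = pr.er_internal_shares(df)
        assert shares.loc[0, "BiP"] == pytest.approx(1.0)

    def test_day7_bip_share_30_to_40_percent(self, composition):
        assert 0.30 <= composition.er_shares.loc[7, "BiP"] <= 0.40

    def test_day7_bip_plus_client_about_half(self, composition):
        share = (composition.er_shares.loc[7, "BiP"]
                 + composition.er_shares.loc[7, "mu_s"])
        assert share == pytest.approx(0.5, abs=0.05)

    def test_bip_share_rises_from_15_percent(self, composition):
        assert composition.er_shares.loc[0, "BiP"] == pytest.approx(
            0.15, abs=0.02)


class TestFoldChange:
    def test_identical_columns_give_unity(self, proteome):
        dup = proteome.copy()
        dup["intensity_day1"] = dup["intensity_day0"]
        fc = pr.fold_change(dup, 0, 1)
        np.testing.assert_allclose(fc.ratio, 1.0)

    def test_bip_fold_matches_programmed_truth(self, proteome):
        fc = pr.fold_change(proteome, 0, 7).set_index("protein_id")
        bip_id = proteome.loc[proteome.name == "BiP", "protein_id"].iloc[0]
        # programmed: (0.35 * 0.12) / (0.15 * 0.03) = 9.33-fold
        assert fc.loc[bip_id, "ratio"] == pytest.approx(9.333, rel=1e-3)

    def test_zero_denominator_flagged_infinite(self):
        df = pd.DataFrame({
            "protein_id": ["A"], "name": ["a"], "compartment": ["cytosol"],
            "intensity_day0": [0.0], "intensity_day7": [5.0],
        })
        fc = pr.fold_change(df, 0, 7)
        assert np.isinf(fc.ratio.iloc[0]) and fc.infinite.iloc[0]


class TestSignificanceB:
    def test_constant_ratios_not_significant(self, rng):
        res = pr.significance_b(np.zeros(600), rng.uniform(1, 100, 600))
        assert not res.significant.any()
        np.testing.assert_allclose(res.p_value, 1.0)

    def test_injected_outlier_flagged(self, rng):
        ratios = rng.normal(0.0, 0.5, 601)
        ratios[300] = 4.0  # a 16-fold change in log2 units
        intensities = rng.uniform(1, 100, 601)
        res = pr.significance_b(ratios, intensities, bin_size=300)
        assert res.significant.iloc[300]
        assert res.p_value.iloc[300] < 0.05

    def test_median_protein_has_zero_z(self, rng):
        ratios = rng.normal(0.0, 1.0, 301)  # odd count: median is a datum
        res = pr.significance_b(ratios, rng.uniform(1, 10, 301), bin_size=301)
        median_idx = int(np.argsort(ratios)[150])
        assert res.z.iloc[median_idx] == 0.0

    def test_matches_direct_percentile_oracle(self, rng):
        ratios = rng.normal(0.1, 0.7, 900)
        intensities = rng.lognormal(3, 1, 900)
        res = pr.significance_b(ratios, intensities, bin_size=300)
        # oracle: rank bins and asymmetric percentile z assembled by hand
        order = np.argsort(-intensities, kind="mergesort")
        for b in range(3):
            idx = order[b * 300:(b + 1) * 300]
            vals = np.sort(ratios[idx])
            med = (vals[149] + vals[150]) / 2

            def pct(q):
                pos = q / 100 * 299
                lo = int(np.floor(pos))
                return vals[lo] + (pos - lo) * (vals[lo + 1] - vals[lo])

            up_w = pct(84.13) - med
            dn_w = med - pct(15.87)
            for i in idx:
                dev = ratios[i] - med
                want = dev / up_w if dev >= 0 else dev / dn_w
                assert res.z.iloc[i] == pytest.approx(want, abs=1e-12)

    def test_undersized_input_falls_back_to_single_bin(self, rng):
        with pytest.warns(UserWarning, match="single bin"):
            res = pr.significance_b(rng.normal(0, 1, 50),
                                    rng.uniform(1, 2, 50), bin_size=300)
        assert (res.bin == 0).all()


class TestAnovaOverDays:
    def test_er_risers_recovered_and_constants_not(self):
        truth = syn.default_truth(seed=7)
        table, day_cols = syn.gen_replicated_proteome(truth, replicates=3)
        res = pr.anova_over_days(table, day_cols).set_index("protein_id")
        bip_id = table.loc[table.name == "BiP", "protein_id"].iloc[0]
        mus_id = table.loc[table.name == "mu_s", "protein_id"].iloc[0]
        assert res.loc[bip_id, "changed"]
        assert res.loc[mus_id, "changed"]

    def test_permuted_labels_give_alpha_rate(self, rng):
        # pure-null table: same mean every day, replicate lognormal noise
        n = 1000
        mean = rng.lognormal(5, 2, n)
        cols = {}
        table = pd.DataFrame({"protein_id": [f"P{i}" for i in range(n)]})
        for d in range(4):
            names = []
            for r in range(3):
                col = f"intensity_day{d}_rep{r}"
                table[col] = mean * rng.lognormal(-0.005, 0.1, n)
                names.append(col)
            cols[d] = names
        res = pr.anova_over_days(table, cols, alpha=0.01, bh_adjust=False)
        rate = res.changed.mean()
        assert 0.002 <= rate <= 0.03  # ~alpha within binomial slack

    def test_missing_replicates_rejected(self, proteome):
        with pytest.raises(ValueError):
            pr.anova_over_days(proteome, {0: ["intensity_day0"]})
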