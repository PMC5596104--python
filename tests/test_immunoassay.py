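"""Panel validation, subset/ratio algebra and the permutation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pepscreen.immunoassay import (
    CYTOKINES,
    DEFAULT_RATIOS,
    DEFAULT_SUBSET_MAP,
    RatioDefinition,
    TestConfig,
    canonical_cytokine,
    compare_conditions,
    compute_ratios,
    load_panel,
    mwu_permutation_test,
    panel_from_dataframe,
    significance_stars,
    subset_aggregate,
)


def make_panel(donors, conditions, value_fn):
    rows = [
        {"donor_id": d, "condition": t, "cytokine": c, "concentration_pg_ml": value_fn(d, t, c)}
        for d in donors
        for t in conditions
        for c in CYTOKINES
    ]
    return panel_from_dataframe(pd.DataFrame(rows))


class TestVocabularyAndLoading:
    @pytest.mark.parametrize(
        "alias, canonical",
        [
            ("IL17", "IL-17A"), ("IL10", "IL-10"), ("TNFa", "TNFα"),
            ("IFN-gamma", "IFNγ"), ("il1b", "IL-1β"), ("IL12p70", "IL-12p70"),
            ("GM CSF", "GM-CSF"),
        ],
    )
    def test_aliases(self, alias, canonical):
        assert canonical_cytokine(alias) == canonical

    def test_unknown_cytokine_lists_vocabulary(self):
        with pytest.raises(ValueError, match="IL-12p70"):
            canonical_cytokine("IL-99")

    def test_complete_panel_loads(self, tmp_path):
        panel = make_panel(
            [f"D{i}" for i in range(1, 6)],
            ["basal", "activated", "lps", "peptide:FR16"],
            lambda d, t, c: 10.0,
        )
        path = tmp_path / "panel.tsv"
        panel.data.to_csv(path, sep="\t", index=False)
        loaded = load_panel(path)
        assert len(loaded.data) == 5 * 4 * 18
        assert loaded.missing_cells() == []

    def test_duplicate_key_rejected(self):
        df = pd.DataFrame(
            {
                "donor_id": ["D1", "D1"],
                "condition": ["basal", "basal"],
                "cytokine": ["IL-10", "IL10"],
                "concentration_pg_ml": [1.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="duplicate"):
            panel_from_dataframe(df)

    def test_empty_file_is_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("donor_id\tcondition\tcytokine\tconcentration_pg_ml\n")
        with pytest.raises(ValueError, match="no measurements"):
            load_panel(path)

    def test_invalid_condition_rejected(self):
        df = pd.DataFrame(
            {
                "donor_id": ["D1"], "condition": ["mystery"],
                "cytokine": ["IL-10"], "concentration_pg_ml": [1.0],
            }
        )
        with pytest.raises(ValueError, match="condition"):
            panel_from_dataframe(df)

    def test_missing_cells_reported(self):
        df = pd.DataFrame(
            {
                "donor_id": ["D1"] * 18 + ["D2"] * 17,
                "condition": "basal",
                "cytokine": list(CYTOKINES) + list(CYTOKINES[:-1]),
                "concentration_pg_ml": 1.0,
            }
        )
        panel = panel_from_dataframe(df)
        assert panel.missing_cells() == [("D2", "basal", "TNFα")]


class TestAggregatesAndRatios:
    def test_singleton_and_mean_aggregates(self):
        values = {"IL-4": 10.0, "IL-5": 20.0, "IL-13": 30.0, "IL-17A": 30.0}
        panel = make_panel(["D1"], ["basal"], lambda d, t, c: values.get(c, 1.0))
        assert subset_aggregate(panel, "D1", "basal", "Th22") == pytest.approx(1.0 + 0.01)
        assert subset_aggregate(panel, "D1", "basal", "Th2") == pytest.approx(20.0 + 0.01)

    def test_pseudocount_floor(self):
        panel = make_panel(["D1"], ["basal"], lambda d, t, c: 0.0)
        assert subset_aggregate(panel, "D1", "basal", "Treg") == pytest.approx(0.01)

    def test_all_equal_panel_gives_unit_pure_subset_ratios(self):
        panel = make_panel(["D1", "D2"], ["basal"], lambda d, t, c: 10.0)
        table = compute_ratios(panel)
        pure = table[table["ratio"].isin(["Th1/Th2", "Th17/Th1", "Th22/Treg", "Th22+Th17/Th1+Th2"])]
        assert np.allclose(pure["value"], 1.0)

    def test_programmed_th17_th1_ratio(self):
        th17 = set(DEFAULT_SUBSET_MAP["Th17"])
        th1 = set(DEFAULT_SUBSET_MAP["Th1"])
        panel = make_panel(
            ["D1"], ["basal"], lambda d, t, c: 30.0 if c in th17 else (10.0 if c in th1 else 5.0)
        )
        table = compute_ratios(panel, eps=0.0)
        value = table.loc[table["ratio"] == "Th17/Th1", "value"].iloc[0]
        assert value == pytest.approx(3.0)

    def test_scale_invariance(self):
        panel_a = make_panel(["D1"], ["basal"], lambda d, t, c: 3.0 + len(c))
        panel_b = make_panel(["D1"], ["basal"], lambda d, t, c: 7 * (3.0 + len(c)))
        a = compute_ratios(panel_a, eps=0.0)["value"].to_numpy()
        b = compute_ratios(panel_b, eps=0.0)["value"].to_numpy()
        assert np.allclose(a, b)

    def test_default_definitions_match_published_list(self):
        assert len(DEFAULT_RATIOS) == 17
        assert {r.name for r in DEFAULT_RATIOS} >= {
            "IL10/TNFα", "IL10/IFNγ", "IL10/IL17", "IL10/IL4", "IFNγ/IL17",
            "Th1/Th2", "Th17/Th1",
        }

    def test_unresolvable_term_is_error(self):
        panel = make_panel(["D1"], ["basal"], lambda d, t, c: 1.0)
        bad = RatioDefinition("bad", ("Th99",), ("Treg",))
        with pytest.raises(ValueError):
            compute_ratios(panel, [bad])

    def test_floored_denominator_flagged(self):
        panel = make_panel(["D1"], ["basal"], lambda d, t, c: 0.0 if c == "IL-10" else 5.0)
        table = compute_ratios(panel)
        row = table[table["ratio"] == "Th17/Treg"].iloc[0]
        assert row["denominator_floored"]


class TestPermutationMWU:
    def test_identical_groups_p_is_one(self):
        assert mwu_permutation_test([5, 5, 5], [5, 5, 5]).p_value == 1.0

    def test_fully_separated_exact_p(self):
        assert mwu_permutation_test([1, 2, 3, 4, 5], [6, 7, 8, 9, 10]).p_value == pytest.approx(2 / 252)
        assert mwu_permutation_test([1, 2, 3], [4, 5, 6]).p_value == pytest.approx(0.1)

    def test_exhaustive_matches_enumeration_oracle(self):
        from oracles import exhaustive_mwu_p

        rng = np.random.default_rng(11)
        for _ in range(10):
            a = rng.normal(size=4)
            b = rng.normal(size=5) + rng.uniform(-1, 1)
            result = mwu_permutation_test(a, b)
            assert result.exact
            assert result.p_value == pytest.approx(exhaustive_mwu_p(a, b))

    def test_exhaustive_matches_scipy_exact(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(5)
        for _ in range(10):
            a, b = rng.normal(size=6), rng.normal(size=7)  # continuous: no ties
            ours = mwu_permutation_test(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.U == pytest.approx(ref.statistic)
            assert ours.p_value == pytest.approx(ref.pvalue)

    def test_ties_use_midranks(self):
        # pooled ranks: 1->1, each 2->3 (midrank), 3->5; U = 12 - 10
        result = mwu_permutation_test([1, 2, 2, 3], [2, 4, 5, 6])
        assert result.U == 2.0

    def test_monte_carlo_is_seeded_and_reproducible(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=12), rng.normal(size=12) + 0.8
        config = TestConfig(n_permutations=2999, seed=42, exhaustive_cap=10)
        p1 = mwu_permutation_test(a, b, config).p_value
        p2 = mwu_permutation_test(a, b, config).p_value
        assert p1 == p2
        p3 = mwu_permutation_test(a, b, TestConfig(n_permutations=2999, seed=43, exhaustive_cap=10)).p_value
        assert p1 != p3

    def test_small_groups_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            mwu_permutation_test([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            mwu_permutation_test([1.0, np.nan], [2.0, 3.0])


class TestStars:
    @pytest.mark.parametrize(
        "p, label",
        [
            (0.0005, "***"), (0.001, "**"), (0.005, "**"), (0.01, "*"),
            (0.03, "*"), (0.05, ""), (0.5, ""), (1.0, ""),
        ],
    )
    def test_thresholds(self, p, label):
        assert significance_stars(p) == label

    def test_monotone_step_function(self):
        grid = np.linspace(0, 1, 201)
        levels = [len(significance_stars(p)) for p in grid]
        assert all(a >= b for a, b in zip(levels, levels[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significance_stars(1.5)


class TestCompareConditions:
    def _noisy_panel(self, elevate=None, donors=5, seed=0):
        rng = np.random.default_rng(seed)
        elevate = elevate or {}

        def value(d, t, c):
            base = 10 ** (2 + 0.2 * rng.standard_normal())
            return base * elevate.get((t, c), 1.0)

        return make_panel(
            [f"D{i}" for i in range(1, donors + 1)],
            ["activated", "peptide:X"],
            value,
        )

    def test_control_vs_itself_gives_p_one(self):
        panel = self._noisy_panel()
        out = compare_conditions(panel, "activated", ["activated"], cytokines=["IL-10", "TNFα"])
        assert (out["p_value"] == 1.0).all()
        assert (out["stars"] == "").all()

    def test_programmed_elevation_is_starred(self):
        elevate = {("peptide:X", "IL-17A"): 40.0}
        panel = self._noisy_panel(elevate=elevate, donors=5, seed=3)
        out = compare_conditions(panel, "activated", ["peptide:X"])
        starred = out[out["measure"] == "IL-17A"]["stars"].iloc[0]
        assert starred != ""

    def test_empty_measure_list_yields_empty_table(self):
        panel = self._noisy_panel()
        out = compare_conditions(panel, "activated", ["peptide:X"], cytokines=[])
        assert out.empty

    def test_missing_control_is_error(self):
        panel = self._noisy_panel()
        with pytest.raises(ValueError, match="control"):
            compare_conditions(panel, "lps", ["peptide:X"])

    def test_ratio_measures_and_bh_column(self):
        panel = self._noisy_panel(seed=9)
        ratios = [r for r in DEFAULT_RATIOS if r.name in ("Th17/Th1", "Th1/Th2")]
        out = compare_conditions(
            panel, "activated", ["peptide:X"], cytokines=[], ratios=ratios, adjust=True
        )
        assert set(out["measure"]) == {"Th17/Th1", "Th1/Th2"}
        assert (out["q_value"] >= out["p_value"] - 1e-12).all()

    def test_deterministic_given_seed(self):
        panel = self._noisy_panel(seed=1, donors=12)
        config = TestConfig(n_permutations=999, seed=7, exhaustive_cap=10)
        a = compare_conditions(panel, "activated", ["peptide:X"], cytokines=["IL-6"], config=config)
        b = compare_conditions(panel, "activated", ["peptide:X"], cytokines=["IL-6"], config=config)
        pd.testing.assert_frame_equal(a, b)
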