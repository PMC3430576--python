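"""Detection-rate combinatorics, panel search, and the chi-square test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelcover.cohort import MarkerInfo
from panelcover.panel import (
    DegenerateTableError,
    PanelSelection,
    chi_square,
    detection_rate,
    exhaustive_best_panel,
    greedy_minimal_panel,
    marginal_gain,
    sequential_curve,
    strata_from_cohort,
    stratified_rates,
)
from panelcover.scoring import EmptyStratumWarning
from panelcover.simulate import CohortConfig, generate_cohort

from conftest import random_calls


class TestDetectionRate:
    def test_empty_panel_detects_nothing(self, toy_calls):
        assert detection_rate(toy_calls, []) == 0.0

    def test_all_negative_cohort(self):
        calls = pd.DataFrame({"A": [False] * 5, "B": [False] * 5})
        assert detection_rate(calls, ["A", "B"]) == 0.0

    def test_toy_enumeration(self, toy_calls):
        # positivity sets {A}, {B}, {}, {A,B}: panel {A,B} detects 3 of 4
        assert detection_rate(toy_calls, ["A", "B"]) == 0.75
        assert detection_rate(toy_calls, ["A"]) == 0.5

    def test_empty_stratum_flagged_undefined(self, toy_calls):
        mask = pd.Series(False, index=toy_calls.index)
        with pytest.warns(EmptyStratumWarning):
            assert np.isnan(detection_rate(toy_calls, ["A"], mask=mask))

    def test_unknown_marker_raises(self, toy_calls):
        with pytest.raises(KeyError):
            detection_rate(toy_calls, ["Z"])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, derandomize=True)
    def test_coverage_monotone_under_marker_addition(self, seed):
        rng = np.random.default_rng(seed)
        markers = [f"m{i}" for i in range(rng.integers(2, 8))]
        calls = random_calls(rng, int(rng.integers(5, 40)), markers)
        k = int(rng.integers(1, len(markers)))
        panel = markers[:k]
        extra = markers[k]
        assert detection_rate(calls, panel + [extra]) >= detection_rate(calls, panel)


class TestSequentialCurve:
    def test_single_marker_equals_marginal_rate(self, toy_calls):
        res = sequential_curve(toy_calls, ["A"])
        assert res.cumulative_rates == [0.5]

    def test_toy_curve(self, toy_calls):
        res = sequential_curve(toy_calls, ["A", "B"])
        assert res.cumulative_rates == [0.5, 0.75]
        assert res.n_detected == 3 and res.n_total == 4

    def test_duplicates_rejected(self, toy_calls):
        with pytest.raises(ValueError, match="duplicate"):
            sequential_curve(toy_calls, ["A", "A"])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True)
    def test_final_rate_is_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        markers = [f"m{i}" for i in range(5)]
        calls = random_calls(rng, 30, markers)
        perm = list(rng.permutation(markers))
        assert sequential_curve(calls, markers).detection_rate == pytest.approx(
            sequential_curve(calls, perm).detection_rate
        )

    def test_curve_non_decreasing(self, toy_calls):
        res = sequential_curve(toy_calls, ["B", "A"])
        assert all(b >= a for a, b in zip(res.cumulative_rates, res.cumulative_rates[1:]))


class TestMarginalGain:
    def test_already_covered_marker_gains_nothing(self, toy_calls):
        calls = toy_calls.copy()
        calls["C"] = calls["A"]  # C positive exactly where A is
        assert marginal_gain(calls, ["A"], "C") == 0.0

    def test_gain_equals_uncovered_fraction(self, toy_calls):
        calls = toy_calls.copy()
        calls["C"] = [False, True, True, False]  # covers exactly what A misses
        assert marginal_gain(calls, ["A"], "C") == 0.5

    def test_gain_never_negative(self, toy_calls):
        for m in ("A", "B"):
            other = "B" if m == "A" else "A"
            assert marginal_gain(toy_calls, [other], m) >= 0.0


GADGET = pd.DataFrame(
    # classic set-cover gadget: C has the largest single coverage, but the
    # optimal pair is {A, B}
    {
        "A": [True, True, True, False, False, False],
        "B": [False, False, False, True, True, True],
        "C": [True, True, False, True, True, False],
    },
    index=[f"g{i}" for i in range(6)],
)


class TestGreedyAndExhaustive:
    def test_single_covering_candidate(self):
        calls = pd.DataFrame({"A": [True] * 4})
        res = greedy_minimal_panel(calls, ["A"], tn_gate=None)
        assert res.markers == ["A"] and res.detection_rate == 1.0

    def test_greedy_suboptimal_on_gadget(self):
        greedy = greedy_minimal_panel(GADGET, list(GADGET.columns), tn_gate=None, max_size=2)
        exact = exhaustive_best_panel(GADGET, list(GADGET.columns), k=2)
        assert greedy.markers[0] == "C"  # largest marginal coverage first
        assert greedy.detection_rate == pytest.approx(5 / 6)
        assert sorted(exact.markers) == ["A", "B"]
        assert exact.detection_rate == 1.0
        # the (1 - 1/e) guarantee still holds
        assert greedy.detection_rate >= (1 - 1 / np.e) * exact.detection_rate

    def test_gate_excludes_low_ratio_candidates(self, toy_calls):
        registry = {
            "A": MarkerInfo("A", "less_specific", 2.0),
            "B": MarkerInfo("B", "less_specific", 2.0),
        }
        res = greedy_minimal_panel(toy_calls, ["A", "B"], registry, tn_gate=3.0)
        assert res.markers == [] and res.reason == "no eligible candidates"

    def test_unknown_ratio_passes_gate(self, toy_calls):
        registry = {
            "A": MarkerInfo("A", "tumor_specific", None),
            "B": MarkerInfo("B", "less_specific", 2.0),
        }
        res = greedy_minimal_panel(toy_calls, ["A", "B"], registry, tn_gate=3.0)
        assert res.markers == ["A"]

    def test_tie_breaks_by_ratio_then_name(self):
        calls = pd.DataFrame({"X": [True, False], "Y": [True, False], "Z": [True, False]})
        registry = {
            "X": MarkerInfo("X", "less_specific", 4.0),
            "Y": MarkerInfo("Y", "less_specific", 8.0),
            "Z": MarkerInfo("Z", "less_specific", 8.0),
        }
        res = greedy_minimal_panel(calls, ["X", "Y", "Z"], registry, tn_gate=3.0, max_size=1)
        assert res.markers == ["Y"]  # higher ratio wins, then lexicographic

    def test_target_rate_stops_search(self, toy_calls):
        res = greedy_minimal_panel(toy_calls, ["A", "B"], tn_gate=None, target_rate=0.5)
        assert len(res.markers) == 1

    def test_exhaustive_k_equals_all(self, toy_calls):
        res = exhaustive_best_panel(toy_calls, ["A", "B"], k=2)
        assert res.detection_rate == detection_rate(toy_calls, ["A", "B"])

    def test_exhaustive_k1_tie_lexicographic(self, toy_calls):
        res = exhaustive_best_panel(toy_calls, ["A", "B"], k=1)
        assert res.markers == ["A"]

    def test_exhaustive_bound_refused(self):
        calls = pd.DataFrame({f"m{i}": [True] for i in range(16)})
        with pytest.raises(ValueError, match="enumeration bound"):
            exhaustive_best_panel(calls, list(calls.columns), k=2)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_greedy_within_1_minus_1_over_e_of_optimum(self, seed):
        rng = np.random.default_rng(seed)
        markers = [f"m{i}" for i in range(int(rng.integers(3, 9)))]
        calls = random_calls(rng, int(rng.integers(8, 40)), markers)
        for k in (1, 2, 3):
            greedy = greedy_minimal_panel(calls, markers, tn_gate=None, max_size=k)
            exact = exhaustive_best_panel(calls, markers, k=k)
            assert greedy.detection_rate >= (1 - 1 / np.e) * exact.detection_rate - 1e-12


class TestStratifiedRates:
    def test_single_stratum_equals_overall(self, toy_calls):
        strata = pd.Series("all", index=toy_calls.index)
        rates = stratified_rates(toy_calls, ["A", "B"], strata)
        assert rates == {"all": detection_rate(toy_calls, ["A", "B"])}

    def test_conservation_identity(self):
        rng = np.random.default_rng(5)
        calls = random_calls(rng, 60, ["A", "B", "C"])
        strata = pd.Series(rng.choice(["x", "y", "z"], size=60), index=calls.index)
        rates = stratified_rates(calls, ["A", "B"], strata)
        total = sum(rates[s] * (strata == s).sum() for s in rates)
        assert total == pytest.approx(calls[["A", "B"]].any(axis=1).sum())

    def test_age_group_split_puts_60_in_upper_group(self):
        cohort, _ = generate_cohort(CohortConfig(n_patients=30, seed=2))
        cohort.records[0].age = 60.0
        cohort.records[1].age = 59.9
        strata = strata_from_cohort(cohort, "age_group")
        assert strata.iloc[0] == ">=60"
        assert strata.iloc[1] == "<60"


class TestChiSquare:
    def test_no_association_gives_zero_statistic(self):
        res = chi_square([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_2x2(self):
        # n (ad - bc)^2 / (r1 r2 c1 c2)
        res = chi_square([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(60 * (20 * 20 - 10 * 10) ** 2 / (30 * 30 * 30 * 30))
        assert res.statistic == pytest.approx(6.6667, abs=1e-4)
        assert res.df == 1

    def test_df_is_rows_minus_one_times_cols_minus_one(self):
        res = chi_square([[5, 10, 15], [10, 10, 10]])
        assert res.df == 2

    def test_invariant_under_permutation(self):
        a = chi_square([[12, 7], [3, 24]])
        b = chi_square([[7, 12], [24, 3]])
        c = chi_square([[3, 24], [12, 7]])
        assert a.statistic == pytest.approx(b.statistic) == pytest.approx(c.statistic)

    def test_zero_marginal_is_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi_square([[0, 0], [5, 10]])
        with pytest.raises(DegenerateTableError):
            chi_square([[0, 5], [0, 10]])


class TestModelResults:
    def test_fit_and_summary(self):
        cohort, _ = generate_cohort(CohortConfig(n_patients=200, seed=9))
        model = PanelSelection.from_cohort(cohort)
        res = model.fit(tn_gate=3.0, max_size=5)
        assert 1 <= len(res.markers) <= 5
        text = res.summary()
        assert "detected" in text and res.markers[0] in text
        # eligible markers exclude the gated-out less-specific ones
        assert "MUC1" not in res.markers and "Mammaglobin" not in res.markers

    def test_stratified_reporting(self):
        cohort, _ = generate_cohort(CohortConfig(n_patients=300, seed=9))
        res = PanelSelection.from_cohort(cohort).fit(max_size=4)
        by_subtype = res.stratified("subtype")  # ductal-only by default
        assert set(by_subtype) <= {"luminal", "her2_driven", "basal_tn"}
        by_age = res.stratified("age_group")
        assert set(by_age) == {"<60", ">=60"}

    def test_exhaustive_method_matches_oracle(self, toy_calls):
        model = PanelSelection(toy_calls)
        res = model.fit(method="exhaustive", tn_gate=None, k=1)
        assert res.markers == ["A"]
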