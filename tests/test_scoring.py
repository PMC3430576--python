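"""Core-aggregation rules, QC filtering, and frequency tabulation."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelcover.cohort import Cohort, CoreScore, MarkerAssay, MarkerInfo, default_registry
from panelcover.scoring import (
    ConfigurationError,
    EmptyStratumWarning,
    aggregate_cores,
    calls_matrix,
    qc_filter,
    round_half_away,
    tabulate_frequencies,
)
from panelcover.simulate import CohortConfig, generate_cohort

from conftest import make_record


def dako_assay(marker, values):
    return MarkerAssay(
        marker,
        tuple(CoreScore.missing() if v is None else CoreScore(dako=v) for v in values),
    )


def pct_assay(marker, values):
    return MarkerAssay(
        marker,
        tuple(CoreScore.missing() if v is None else CoreScore(percent=v) for v in values),
    )


REG = default_registry()


class TestAggregateCores:
    @pytest.mark.parametrize(
        "marker,cores,positive,basis",
        [
            # HER2: only a rounded category of 3 is positive
            ("HER2", [3, 3, 3], True, "her2_strict"),
            ("HER2", [2, 2, 2], False, "her2_strict"),
            # mean 2.67 rounds half-away to 3 -> positive under the strict rule
            ("HER2", [3, 3, 2], True, "her2_strict"),
            # default rule: rounded mean category 2 or 3 is positive
            ("EGFR", [2, 2, 2], True, "mean_dako"),
            ("EGFR", [0, 0, 3], False, "mean_dako"),  # mean 1.0 -> category 1
            ("EGFR", [1, 2, 2], True, "mean_dako"),  # mean 1.67 -> category 2
            ("MET", [1, 1, 1], False, "mean_dako"),
            # hypoxia markers: a single positive core suffices
            ("GLUT1", [0, 0, 3], True, "any_core"),
            ("GLUT1", [0, 0, 2], True, "any_core"),
            ("CAIX", [1, 1, 1], False, "any_core"),
            # single-core missing values are dropped from the mean
            ("EGFR", [None, 2, 2], True, "mean_dako"),
            ("HER2", [None, None, 3], True, "her2_strict"),
            # fully missing scores negative
            ("CAIX", [None, None, None], False, "missing_as_negative"),
        ],
    )
    def test_dako_rules(self, marker, cores, positive, basis):
        call = aggregate_cores(dako_assay(marker, cores), REG[marker])
        assert call.positive is positive
        assert call.basis == basis

    @pytest.mark.parametrize(
        "values,positive",
        [
            ([40.0, 40.0, 40.0], True),
            ([35.0, 35.0, 35.0], False),  # strictly more than 35% required
            ([35.1, 35.1, 35.1], True),
            ([0.0, 0.0, 100.0], False),  # mean 33.3
            ([None, None, None], False),
        ],
    )
    def test_mammaglobin_percent_rule(self, values, positive):
        call = aggregate_cores(pct_assay("Mammaglobin", values), REG["Mammaglobin"])
        assert call.positive is positive

    def test_tumor_score_is_mean_of_available_cores(self):
        call = aggregate_cores(dako_assay("EGFR", [None, 1, 2]), REG["EGFR"])
        assert call.tumor_score == pytest.approx(1.5)
        call = aggregate_cores(pct_assay("Mammaglobin", [40.0, 50.0]), REG["Mammaglobin"])
        assert call.tumor_score == pytest.approx(45.0)

    def test_rule_data_mismatch_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            aggregate_cores(pct_assay("EGFR", [50.0]), REG["EGFR"])
        with pytest.raises(ConfigurationError):
            aggregate_cores(dako_assay("Mammaglobin", [2]), REG["Mammaglobin"])
        with pytest.raises(ConfigurationError):
            aggregate_cores(dako_assay("EGFR", [2]), REG["HER2"])

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(2.5) == 3
        assert round_half_away(1.5) == 2
        assert round_half_away(2.49) == 2

    @given(
        rule=st.sampled_from(["default_dako", "her2_strict", "any_core"]),
        cores=st.lists(st.integers(0, 3), min_size=1, max_size=3),
        bump=st.integers(0, 2),
    )
    @settings(max_examples=200, derandomize=True)
    def test_positivity_monotone_in_core_scores(self, rule, cores, bump):
        """Raising any single core score never flips a positive call to negative."""
        info = MarkerInfo("M", "tumor_specific", None, rule)
        before = aggregate_cores(dako_assay("M", cores), info).positive
        raised = list(cores)
        raised[bump % len(raised)] = min(3, raised[bump % len(raised)] + 1)
        after = aggregate_cores(dako_assay("M", raised), info).positive
        assert after or not before


class TestQCFilter:
    def build(self, n_missing_markers):
        markers = list(REG)
        scores = {}
        for j, m in enumerate(markers):
            if j < n_missing_markers:
                scores[m] = [None, None, None]
            elif REG[m].positivity_rule == "percent_cells":
                scores[m] = [10.0, 10.0, 10.0]
            else:
                scores[m] = [0, 0, 0]
        return make_record(f"Q{n_missing_markers}", scores)

    def test_more_than_three_missing_markers_excluded(self, registry):
        cohort = Cohort([self.build(4), self.build(3), self.build(0)], registry)
        kept, excluded = qc_filter(cohort)
        assert excluded == ["Q4"]
        assert [r.patient_id for r in kept.records] == ["Q3", "Q0"]

    def test_clean_cohort_unchanged(self):
        cohort, _ = generate_cohort(CohortConfig(n_patients=50, seed=1, missing_probs={}))
        kept, excluded = qc_filter(cohort)
        assert excluded == []
        assert len(kept) == len(cohort)

    def test_absent_assay_counts_as_missing_marker(self, registry):
        rec = make_record("P1", {"GLUT1": [1, 1, 1]})  # 10 of 11 markers absent
        kept, excluded = qc_filter(Cohort([rec], registry))
        assert excluded == ["P1"]


class TestTabulateFrequencies:
    def test_counts_partition_the_stratum(self, toy_cohort):
        for m in ("GLUT1", "HER2", "Mammaglobin"):
            ft = tabulate_frequencies(toy_cohort, m)
            assert ft.n_positive + ft.n_negative + ft.n_missing == len(toy_cohort)

    def test_missing_column_counts_fully_missing_assays(self, toy_cohort):
        ft = tabulate_frequencies(toy_cohort, "GLUT1")
        assert (ft.n_positive, ft.n_negative, ft.n_missing) == (1, 1, 1)
        # absent assays count as missing too
        ft = tabulate_frequencies(toy_cohort, "CAXII")
        assert ft.n_missing == 3

    def test_stratum_filter(self, toy_cohort):
        ft = tabulate_frequencies(toy_cohort, "HER2", lambda r: r.histology == "ductal")
        assert ft.n_total == 2

    def test_unknown_marker_raises_key_error(self, toy_cohort):
        with pytest.raises(KeyError):
            tabulate_frequencies(toy_cohort, "VEGF")

    def test_empty_stratum_flagged(self, toy_cohort):
        with pytest.warns(EmptyStratumWarning):
            ft = tabulate_frequencies(toy_cohort, "GLUT1", lambda r: r.age > 200)
        assert ft.empty and ft.pct_positive == 0.0

    def test_percentages_use_full_stratum_denominator(self, registry):
        # 2 positive, 1 negative, 1 missing of 4: 50.0 / 25.0 / 25.0
        records = [
            make_record("A", {"EGFR": [2, 2, 2]}),
            make_record("B", {"EGFR": [3, 3, 3]}),
            make_record("C", {"EGFR": [0, 0, 0]}),
            make_record("D", {"EGFR": [None, None, None]}),
        ]
        ft = tabulate_frequencies(Cohort(records, registry), "EGFR")
        assert (ft.pct_positive, ft.pct_negative, ft.pct_missing) == (50.0, 25.0, 25.0)


def test_generator_ground_truth_reproduced_call_for_call():
    """With no between-core heterogeneity and no missingness the pipeline's
    tumor-level calls equal the generator's drawn truth for every tumor and
    marker."""
    cfg = CohortConfig(n_patients=300, seed=42, heterogeneity=0.0, missing_probs={})
    cohort, truth = generate_cohort(cfg)
    cm = calls_matrix(cohort)
    assert (cm.values == truth[cm.columns].values).all()
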