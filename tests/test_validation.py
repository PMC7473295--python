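import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import linkval as lv
from linkval._rounding import format_trimmed, round_half_up
from linkval.linkage import IntegrityError
from linkval.validation import (
    ContingencyMatrix,
    build_contingency,
    cohens_kappa,
    diagnostic_metrics,
    non_response_rate,
    prevalence_per_1000,
)


# ---------------------------------------------------------------------------
# independent oracles (brute-force formula evaluation, exact arithmetic)


def oracle_metrics(tp, fp, fn, tn):
    """Exact-rational evaluation of the four defining ratios, as percents."""

    def ratio(numerator, denominator):
        return None if denominator == 0 else float(100 * Fraction(numerator, denominator))

    return (
        ratio(tp, tp + fn),
        ratio(tn, tn + fp),
        ratio(tp, tp + fp),
        ratio(tn, tn + fn),
    )


def oracle_kappa(tp, fp, fn, tn):
    """Kappa via label expansion and scikit-learn (independent route)."""
    from sklearn.metrics import cohen_kappa_score

    n = tp + fp + fn + tn
    pe = Fraction((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn), n * n)
    if pe == 1:
        return None  # chance agreement is certain; kappa undefined
    survey = [1] * tp + [1] * fp + [0] * fn + [0] * tn
    clinical = [1] * tp + [0] * fp + [1] * fn + [0] * tn
    return cohen_kappa_score(survey, clinical, labels=[0, 1])


# ---------------------------------------------------------------------------


class TestContingencyMatrix:
    def test_counts_reconcile(self):
        m = ContingencyMatrix("x", 1, 2, 3, 4, 5)
        assert m.n_valid == 10
        assert m.n_total == 15
        assert m.survey_yes == 3
        assert m.clinical_yes == 4

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ContingencyMatrix("x", -1, 0, 0, 0)


class TestBuildContingency:
    def test_planted_angina(self, planted_runs):
        _, platform, tags = planted_runs["angina"]
        m = build_contingency(platform.survey, tags, "angina")
        assert (m.tp, m.fp, m.fn, m.tn, m.no_answer) == (77, 319, 38, 10329, 560)

    def test_planted_heart_failure(self, planted_runs):
        _, platform, tags = planted_runs["heart_failure"]
        m = build_contingency(platform.survey, tags, "heart_failure")
        assert (m.tp, m.fp, m.fn, m.tn, m.no_answer) == (33, 158, 33, 10468, 631)

    def test_all_no_answer(self):
        survey = pd.DataFrame({"alf": ["A", "B"], "condition_id": "x", "answer": "no_answer"})
        tags = pd.DataFrame(
            {"alf": ["A", "B"], "condition_id": "x", "is_case": [True, False]}
        )
        m = build_contingency(survey, tags, "x")
        assert (m.tp, m.fp, m.fn, m.tn) == (0, 0, 0, 0)
        assert m.no_answer == 2

    def test_missing_survey_row_is_integrity_error(self):
        survey = pd.DataFrame({"alf": ["A"], "condition_id": "x", "answer": ["yes"]})
        tags = pd.DataFrame({"alf": ["A", "B"], "condition_id": "x", "is_case": [True, False]})
        with pytest.raises(IntegrityError, match="lack a survey row"):
            build_contingency(survey, tags, "x")

    def test_missing_tag_is_integrity_error(self):
        survey = pd.DataFrame({"alf": ["A", "B"], "condition_id": "x", "answer": "yes"})
        tags = pd.DataFrame({"alf": ["A"], "condition_id": "x", "is_case": [True]})
        with pytest.raises(IntegrityError, match="lack a case tag"):
            build_contingency(survey, tags, "x")


class TestDiagnosticMetrics:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((77, 319, 38, 10329), (66.96, 97.0, 19.44, 99.63)),
            ((82, 391, 27, 10359), (75.23, 96.36, 17.34, 99.74)),
            ((33, 158, 33, 10468), (50.0, 98.51, 17.28, 99.69)),
            ((818, 355, 370, 9220), (68.86, 96.29, 69.74, 96.14)),
        ],
    )
    def test_printed_rows(self, cells, expected):
        m = ContingencyMatrix("x", *cells)
        result = diagnostic_metrics(m)
        assert (result.sensitivity, result.specificity, result.ppv, result.npv) == expected

    def test_perfect_agreement(self):
        result = diagnostic_metrics(ContingencyMatrix("x", 7, 0, 0, 13))
        assert (result.sensitivity, result.specificity, result.ppv, result.npv) == (
            100.0,
            100.0,
            100.0,
            100.0,
        )

    def test_undefined_metrics_flagged_not_zeroed(self):
        result = diagnostic_metrics(ContingencyMatrix("x", 0, 0, 0, 5))
        assert result.sensitivity is None
        assert result.ppv is None
        assert set(result.undefined) == {"sensitivity", "ppv"}
        assert result.specificity == 100.0

    def test_formatting_trims_trailing_zeros(self):
        result = diagnostic_metrics(ContingencyMatrix("x", 33, 158, 33, 10468))
        formatted = result.formatted()
        assert formatted["sensitivity"] == "50"
        assert formatted["specificity"] == "98.51"

    def test_unrounded_values(self):
        raw = diagnostic_metrics(ContingencyMatrix("x", 77, 319, 38, 10329), rounded=False)
        assert math.isclose(raw.sensitivity, 100 * 77 / 115, rel_tol=1e-15)


class TestCohensKappa:
    def test_angina_printed_value(self):
        assert cohens_kappa(ContingencyMatrix("angina", 77, 319, 38, 10329)) == 0.290

    def test_asthma_printed_value(self):
        assert cohens_kappa(ContingencyMatrix("asthma", 818, 355, 370, 9220)) == 0.655

    def test_diagonal_only_matrix(self):
        assert cohens_kappa(ContingencyMatrix("x", 5, 0, 0, 5)) == 1.0

    def test_hand_evaluated_small_matrix(self):
        # po = 4/6, pe = (3*3 + 3*3)/36 = 1/2, kappa = (2/3 - 1/2)/(1/2) = 1/3
        assert cohens_kappa(ContingencyMatrix("x", 2, 1, 1, 2)) == 0.333

    def test_empty_matrix_domain_error(self):
        with pytest.raises(ValueError):
            cohens_kappa(ContingencyMatrix("x", 0, 0, 0, 0, no_answer=3))

    def test_degenerate_pe_one_returns_none(self):
        assert cohens_kappa(ContingencyMatrix("x", 4, 0, 0, 0)) is None

    def test_kappa_one_iff_no_disagreement(self):
        assert cohens_kappa(ContingencyMatrix("x", 3, 0, 0, 4)) == 1.0
        assert cohens_kappa(ContingencyMatrix("x", 3, 1, 0, 4)) < 1.0

    @given(
        tp=st.integers(0, 40),
        fp=st.integers(0, 40),
        fn=st.integers(0, 40),
        tn=st.integers(0, 40),
    )
    @settings(max_examples=200)
    def test_kappa_in_range_and_axis_symmetric(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        m = ContingencyMatrix("x", tp, fp, fn, tn)
        kappa = cohens_kappa(m, rounded=False)
        if kappa is None:
            return
        assert -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12
        swapped = cohens_kappa(m.transposed(), rounded=False)
        assert math.isclose(kappa, swapped, rel_tol=0, abs_tol=1e-12)

    def test_transpose_exchanges_sens_ppv_and_spec_npv(self):
        m = ContingencyMatrix("x", 12, 5, 7, 30)
        direct = diagnostic_metrics(m, rounded=False)
        swapped = diagnostic_metrics(m.transposed(), rounded=False)
        assert math.isclose(direct.sensitivity, swapped.ppv)
        assert math.isclose(direct.specificity, swapped.npv)
        assert math.isclose(direct.ppv, swapped.sensitivity)
        assert math.isclose(direct.npv, swapped.specificity)


class TestPrevalence:
    @pytest.mark.parametrize(
        "count,expected",
        [
            (396, (35, 32, 38)),
            (1173, (104, 98, 109)),
            (473, (42, 38, 45)),
            (0, (0, 0, 0)),
        ],
    )
    def test_printed_survey_prevalences(self, count, expected):
        estimate = prevalence_per_1000(count, 11323)
        assert (estimate.point, estimate.lower, estimate.upper) == expected

    def test_clinical_prevalence_both_policies_for_angina_and_asthma(self):
        # contingency-positive numerator reproduces asthma's printed pair
        asthma = prevalence_per_1000(818 + 370, 11323)
        assert (asthma.point, asthma.lower, asthma.upper) == (105, 99, 111)
        # all-identified numerator reproduces angina's printed pair
        angina = prevalence_per_1000(124, 11323)
        assert (angina.point, angina.lower, angina.upper) == (11, 9, 13)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            prevalence_per_1000(1, 0)
        with pytest.raises(ValueError):
            prevalence_per_1000(5, 4)

    def test_wilson_flag(self):
        wald = prevalence_per_1000(191, 11323, method="wald")
        wilson = prevalence_per_1000(191, 11323, method="wilson")
        assert wald.point == wilson.point == 17
        assert wilson.lower == 15  # Wilson pulls the lower bound up at small p

    @given(count=st.integers(1, 99))
    @settings(max_examples=60)
    def test_wald_symmetric_about_p(self, count):
        n = 100
        p = count / n
        z = 1.959963984540054
        half = z * math.sqrt(p * (1 - p) / n)
        estimate = prevalence_per_1000(count, n)
        # recompute the unrounded bounds: symmetric about p by construction
        assert estimate.lower == round_half_up(1000 * max(p - half, 0))
        assert estimate.upper == round_half_up(1000 * min(p + half, 1))

    def test_wald_width_shrinks_with_denominator(self):
        widths = []
        for n in (100, 1_000, 10_000, 100_000):
            count = n // 10
            p = count / n
            z = 1.959963984540054
            widths.append(2 * z * math.sqrt(p * (1 - p) / n))
        assert widths == sorted(widths, reverse=True)


class TestNonResponse:
    @pytest.mark.parametrize(
        "count,expected", [(560, 4.95), (464, 4.10), (631, 5.57), (0, 0.0)]
    )
    def test_printed_rates(self, count, expected):
        assert non_response_rate(count, 11323) == expected

    def test_domain(self):
        with pytest.raises(ValueError):
            non_response_rate(1, 0)


class TestValidateCondition:
    def test_angina_full_row(self, planted_runs):
        _, platform, tags = planted_runs["angina"]
        report = lv.validate_condition(
            platform, tags, "angina", clinical_numerator_policy="all_identified"
        )
        assert report.metrics.sensitivity == 66.96
        assert report.metrics.specificity == 97.0
        assert report.metrics.ppv == 19.44
        assert report.metrics.npv == 99.63
        assert report.kappa == 0.290
        assert (report.prevalence_clinical.point, report.prevalence_clinical.lower,
                report.prevalence_clinical.upper) == (11, 9, 13)
        assert (report.prevalence_survey.point, report.prevalence_survey.lower,
                report.prevalence_survey.upper) == (35, 32, 38)
        assert report.non_response_pct == 4.95

    def test_asthma_kappa(self, planted_runs):
        _, platform, tags = planted_runs["asthma"]
        report = lv.validate_condition(platform, tags, "asthma")
        assert report.kappa == 0.655
        assert report.prevalence_clinical.point == 105  # contingency policy

    def test_perfect_agreement_cohort(self, code_sets):
        cohort = lv.plant_contingency(20, 0, 0, 80, 0, "asthma", code_sets.get("asthma"), seed=5)
        platform = lv.build_platform(
            cohort.persons, cohort.survey, cohort.gp_events, cohort.hospital_episodes
        )
        tags = lv.ascertain(platform, code_sets.get("asthma"))
        report = lv.validate_condition(platform, tags, "asthma")
        assert report.kappa == 1.0
        assert report.metrics.sensitivity == 100.0
        assert report.metrics.specificity == 100.0
        assert report.metrics.ppv == 100.0
        assert report.metrics.npv == 100.0

    def test_valid_responses_denominator_flag(self, planted_runs):
        _, platform, tags = planted_runs["angina"]
        report = lv.validate_condition(
            platform, tags, "angina", prevalence_denominator_policy="valid_responses"
        )
        assert report.prevalence_denominator == 10763

    def test_report_records_policy(self, planted_runs):
        _, platform, tags = planted_runs["angina"]
        report = lv.validate_condition(platform, tags, "angina")
        assert report.clinical_numerator_policy == "contingency"
        assert report.to_dict()["contingency"]["tp"] == 77


class TestOracleEquivalence:
    """Implementation vs independent brute-force evaluation on small grids."""

    def test_small_grid_metrics_and_kappa(self):
        cells = range(0, 5)
        for tp in cells:
            for fp in cells:
                for fn in cells:
                    for tn in cells:
                        if tp + fp + fn + tn == 0:
                            continue
                        m = ContingencyMatrix("x", tp, fp, fn, tn)
                        got = diagnostic_metrics(m, rounded=False)
                        want = oracle_metrics(tp, fp, fn, tn)
                        for g, w in zip((got.sensitivity, got.specificity, got.ppv, got.npv), want):
                            if w is None:
                                assert g is None
                            else:
                                assert math.isclose(g, w, rel_tol=0, abs_tol=1e-12)
                        got_kappa = cohens_kappa(m, rounded=False)
                        want_kappa = oracle_kappa(tp, fp, fn, tn)
                        if want_kappa is None:
                            assert got_kappa is None
                        else:
                            assert math.isclose(got_kappa, want_kappa, rel_tol=0, abs_tol=1e-12)


class TestRounding:
    @pytest.mark.parametrize(
        "value,ndigits,expected",
        [(2.675, 2, 2.68), (0.2895, 3, 0.290), (0.5, 0, 1.0), (104.5, 0, 105.0)],
    )
    def test_half_up(self, value, ndigits, expected):
        assert round_half_up(value, ndigits) == expected

    @pytest.mark.parametrize(
        "value,expected", [(97.0, "97"), (50.004, "50"), (66.96, "66.96"), (4.10, "4.1")]
    )
    def test_trimmed_format(self, value, expected):
        assert format_trimmed(value, 2) == expected
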