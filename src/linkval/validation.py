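"""Contingency matrices and validation statistics.

The survey answer is compared against the clinical case tag (clinical data
acting as the gold standard).  Non-responders ("no answer / refused") are
excluded from the 2×2 cells but counted separately; Cohen's kappa and the
four diagnostic metrics use valid responses only, while the default
prevalence denominator includes non-responders (all matched respondents).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import pandas as pd
from scipy.stats import norm

from ._rounding import format_trimmed, round_half_up
from .linkage import IntegrityError, PlatformRecordSet

__all__ = [
    "ContingencyMatrix",
    "DiagnosticMetrics",
    "PrevalenceEstimate",
    "ValidationReport",
    "build_contingency",
    "diagnostic_metrics",
    "cohens_kappa",
    "prevalence_per_1000",
    "non_response_rate",
    "validate_condition",
    "report_frame",
    "non_response_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyMatrix:
    """Survey-vs-clinical 2×2 counts plus the excluded non-response count.

    tp: survey yes & clinical yes; fp: survey yes & clinical no;
    fn: survey no & clinical yes; tn: survey no & clinical no.
    """

    condition_id: str
    tp: int
    fp: int
    fn: int
    tn: int
    no_answer: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn", "no_answer"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_valid(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_total(self) -> int:
        return self.n_valid + self.no_answer

    @property
    def survey_yes(self) -> int:
        return self.tp + self.fp

    @property
    def clinical_yes(self) -> int:
        return self.tp + self.fn

    def transposed(self) -> "ContingencyMatrix":
        """Swap the survey and clinical axes."""
        return ContingencyMatrix(self.condition_id, self.tp, self.fn, self.fp, self.tn, self.no_answer)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "survey": ["yes", "no", "no_answer"],
                "clinical_yes": [self.tp, self.fn, None],
                "clinical_no": [self.fp, self.tn, None],
                "total": [self.survey_yes, self.fn + self.tn, self.no_answer],
            }
        )


def build_contingency(
    survey_answers: pd.DataFrame, case_tags: pd.DataFrame, condition_id: str
) -> ContingencyMatrix:
    """Cross-tabulate survey answers against clinical case tags.

    Requires exactly one survey answer and one case tag per person for the
    condition; any person present on one side only is an integrity error.
    """
    answers = survey_answers.loc[survey_answers["condition_id"] == condition_id, ["alf", "answer"]]
    tags = case_tags.loc[case_tags["condition_id"] == condition_id, ["alf", "is_case"]]
    merged = answers.merge(tags, on="alf", how="outer", indicator=True)
    missing_tag = merged["_merge"] == "left_only"
    missing_answer = merged["_merge"] == "right_only"
    if missing_answer.any():
        offenders = merged.loc[missing_answer, "alf"].tolist()
        raise IntegrityError(
            f"{condition_id}: {len(offenders)} tagged persons lack a survey row, e.g. {offenders[:5]}"
        )
    if missing_tag.any():
        offenders = merged.loc[missing_tag, "alf"].tolist()
        raise IntegrityError(
            f"{condition_id}: {len(offenders)} survey persons lack a case tag, e.g. {offenders[:5]}"
        )
    yes = merged["answer"] == "yes"
    no = merged["answer"] == "no"
    case = merged["is_case"].astype(bool)
    return ContingencyMatrix(
        condition_id=condition_id,
        tp=int((yes & case).sum()),
        fp=int((yes & ~case).sum()),
        fn=int((no & case).sum()),
        tn=int((no & ~case).sum()),
        no_answer=int((merged["answer"] == "no_answer").sum()),
    )


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV as percentages (None when undefined)."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    undefined: tuple[str, ...] = ()

    def formatted(self) -> dict[str, str]:
        return {
            name: ("undefined" if value is None else format_trimmed(value, 2))
            for name, value in (
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("ppv", self.ppv),
                ("npv", self.npv),
            )
        }


def diagnostic_metrics(m: ContingencyMatrix, rounded: bool = True) -> DiagnosticMetrics:
    """Compute the four diagnostic accuracy metrics from a 2×2.

    A metric whose denominator is zero is reported as ``None`` and named in
    ``undefined`` rather than silently zeroed.  Values are percentages,
    rounded half-up to 2 dp unless ``rounded=False``.
    """
    pairs = {
        "sensitivity": (m.tp, m.tp + m.fn),
        "specificity": (m.tn, m.tn + m.fp),
        "ppv": (m.tp, m.tp + m.fp),
        "npv": (m.tn, m.tn + m.fn),
    }
    values: dict[str, float | None] = {}
    undefined = []
    for name, (numerator, denominator) in pairs.items():
        if denominator == 0:
            values[name] = None
            undefined.append(name)
            logger.warning("%s: %s undefined (zero denominator)", m.condition_id, name)
        else:
            pct = 100.0 * numerator / denominator
            values[name] = round_half_up(pct, 2) if rounded else pct
    return DiagnosticMetrics(**values, undefined=tuple(undefined))


def cohens_kappa(m: ContingencyMatrix, rounded: bool = True) -> float | None:
    """Cohen's kappa on valid responses only.

    po = (tp+tn)/n; pe = [(tp+fp)(tp+fn) + (fn+tn)(fp+tn)] / n^2 with
    n = n_valid.  Returns None (undefined) when chance agreement pe = 1.
    """
    n = m.n_valid
    if n == 0:
        raise ValueError(f"{m.condition_id}: kappa undefined for empty matrix")
    po = (m.tp + m.tn) / n
    pe = ((m.tp + m.fp) * (m.tp + m.fn) + (m.fn + m.tn) * (m.fp + m.tn)) / (n * n)
    if pe == 1.0:
        logger.warning("%s: kappa undefined (pe = 1)", m.condition_id)
        return None
    kappa = (po - pe) / (1.0 - pe)
    return round_half_up(kappa, 3) if rounded else kappa


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Prevalence per 1,000 with a 95% confidence interval, all integers."""

    point: int
    lower: int
    upper: int

    def formatted(self) -> str:
        return f"{self.point} ({self.lower}/{self.upper})"


def prevalence_per_1000(
    case_count: int,
    denominator: int,
    alpha: float = 0.05,
    method: Literal["wald", "wilson"] = "wald",
) -> PrevalenceEstimate:
    """Binomial prevalence per 1,000 with a confidence interval.

    The default is the Wald normal approximation, p ± z·sqrt(p(1−p)/n),
    bounds clipped to [0, 1]; Wilson is available via ``method``.  Point and
    bounds are ×1000 and rounded half-up to integers.
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= case_count <= denominator:
        raise ValueError("case_count must be within [0, denominator]")
    p = case_count / denominator
    if method == "wald":
        z = norm.ppf(1 - alpha / 2)
        half = z * (p * (1 - p) / denominator) ** 0.5
        lower, upper = p - half, p + half
    elif method == "wilson":
        from statsmodels.stats.proportion import proportion_confint

        lower, upper = proportion_confint(case_count, denominator, alpha=alpha, method="wilson")
    else:
        raise ValueError(f"unknown CI method {method!r}")
    lower = max(lower, 0.0)
    upper = min(upper, 1.0)
    return PrevalenceEstimate(
        point=int(round_half_up(1000 * p, 0)),
        lower=int(round_half_up(1000 * lower, 0)),
        upper=int(round_half_up(1000 * upper, 0)),
    )


def non_response_rate(no_answer: int, n_total: int) -> float:
    """Percentage of non-responders among all matched respondents, 2 dp."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    return round_half_up(100.0 * no_answer / n_total, 2)


@dataclass(frozen=True)
class ValidationReport:
    """Full per-condition validation block (one summary-table row)."""

    condition_id: str
    matrix: ContingencyMatrix
    metrics: DiagnosticMetrics
    kappa: float | None
    prevalence_clinical: PrevalenceEstimate
    prevalence_survey: PrevalenceEstimate
    non_response_pct: float
    prevalence_denominator: int
    clinical_numerator_policy: str = "contingency"
    ci_method: str = "wald"
    notes: tuple[str, ...] = ()

    def to_row(self) -> dict:
        return {
            "condition_id": self.condition_id,
            "sensitivity": self.metrics.sensitivity,
            "specificity": self.metrics.specificity,
            "ppv": self.metrics.ppv,
            "npv": self.metrics.npv,
            "prevalence_clinical": self.prevalence_clinical.point,
            "prevalence_clinical_ci": f"({self.prevalence_clinical.lower}/{self.prevalence_clinical.upper})",
            "prevalence_survey": self.prevalence_survey.point,
            "prevalence_survey_ci": f"({self.prevalence_survey.lower}/{self.prevalence_survey.upper})",
            "kappa": self.kappa,
            "non_response_pct": self.non_response_pct,
            "clinical_numerator_policy": self.clinical_numerator_policy,
            "ci_method": self.ci_method,
        }

    def to_dict(self) -> dict:
        row = self.to_row()
        row["contingency"] = {
            "tp": self.matrix.tp,
            "fp": self.matrix.fp,
            "fn": self.matrix.fn,
            "tn": self.matrix.tn,
            "no_answer": self.matrix.no_answer,
        }
        return row


def validate_condition(
    platform: PlatformRecordSet,
    tags: pd.DataFrame,
    condition_id: str,
    *,
    prevalence_denominator_policy: Literal["all_respondents", "valid_responses"] = "all_respondents",
    clinical_numerator_policy: Literal["contingency", "all_identified"] = "contingency",
    ci_method: Literal["wald", "wilson"] = "wald",
    alpha: float = 0.05,
) -> ValidationReport:
    """Assemble the full validation block for one condition.

    Survey prevalence uses the survey-yes count.  The clinical numerator is
    either the clinical-positive count among valid responders
    (``contingency``, tp+fn) or every tagged case including non-responders
    (``all_identified``) — the two defensible readings of a partially
    ambiguous convention; the report records which was used.
    """
    matrix = build_contingency(platform.survey, tags, condition_id)
    metrics = diagnostic_metrics(matrix)
    kappa = cohens_kappa(matrix) if matrix.n_valid else None

    if prevalence_denominator_policy == "all_respondents":
        denominator = matrix.n_total
    elif prevalence_denominator_policy == "valid_responses":
        denominator = matrix.n_valid
    else:
        raise ValueError(f"unknown denominator policy {prevalence_denominator_policy!r}")

    if clinical_numerator_policy == "contingency":
        clinical_numerator = matrix.clinical_yes
    elif clinical_numerator_policy == "all_identified":
        sub = tags.loc[(tags["condition_id"] == condition_id) & tags["is_case"]]
        clinical_numerator = int(len(sub))
    else:
        raise ValueError(f"unknown clinical numerator policy {clinical_numerator_policy!r}")

    return ValidationReport(
        condition_id=condition_id,
        matrix=matrix,
        metrics=metrics,
        kappa=kappa,
        prevalence_clinical=prevalence_per_1000(clinical_numerator, denominator, alpha, ci_method),
        prevalence_survey=prevalence_per_1000(matrix.survey_yes, denominator, alpha, ci_method),
        non_response_pct=non_response_rate(matrix.no_answer, matrix.n_total),
        prevalence_denominator=denominator,
        clinical_numerator_policy=clinical_numerator_policy,
        ci_method=ci_method,
    )


def report_frame(reports: list[ValidationReport]) -> pd.DataFrame:
    """Stack per-condition reports into the summary-table layout."""
    return pd.DataFrame([r.to_row() for r in reports])


def non_response_frame(reports: list[ValidationReport]) -> pd.DataFrame:
    """Non-response counts and percentages per condition."""
    return pd.DataFrame(
        [
            {
                "condition_id": r.condition_id,
                "no_answer": r.matrix.no_answer,
                "non_response_pct": r.non_response_pct,
            }
            for r in reports
        ]
    )
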