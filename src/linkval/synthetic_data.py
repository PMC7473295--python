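"""Synthetic linked survey + GP + hospital record generation.

Two entry points:

* :func:`generate_cohort` — stochastic cohorts with controllable latent true
  status, survey misreporting, non-response, record-emission probabilities,
  event timing and partial GP-practice coverage.
* :func:`plant_contingency` — deterministic "planted" cohorts that, when run
  through linkage → phenotyping → validation, reproduce a specified 2×2
  contingency table exactly.

All tables are plain :class:`pandas.DataFrame` objects with documented
columns; dates are ``datetime64``; CSV serialization uses ISO-8601 dates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .codelists import (
    ClinicalCode,
    CodeSetCollection,
    CodeSystem,
    ConditionCodeSet,
    Window,
    code_matches,
)

__all__ = [
    "AGE_GROUPS",
    "GENDERS",
    "DEFAULT_AGE_PROBS",
    "DEFAULT_GENDER_PROBS",
    "ConditionParams",
    "CohortConfig",
    "Cohort",
    "ConfigurationError",
    "generate_cohort",
    "plant_contingency",
    "write_cohort",
    "read_cohort",
    "decoy_codes",
]

AGE_GROUPS = ("16-29", "30-44", "45-59", "60-74", "75+")
GENDERS = ("female", "male")

# age-group and gender marginals of the default cohort (sum to 1)
DEFAULT_AGE_PROBS = (1745 / 11323, 2164 / 11323, 2863 / 11323, 3108 / 11323, 1443 / 11323)
DEFAULT_GENDER_PROBS = (6079 / 11323, 5244 / 11323)

PERSON_COLUMNS = ["alf", "gender", "age_group", "interview_date", "gp_covered", "match_quality"]
SURVEY_COLUMNS = ["alf", "condition_id", "answer"]
GP_COLUMNS = ["alf", "event_date", "read_code"]
HOSPITAL_COLUMNS = ["alf", "admission_date", "icd10_codes"]
TRUTH_COLUMNS = ["alf", "condition_id", "true_status"]


class ConfigurationError(ValueError):
    """A cohort configuration is internally inconsistent."""


@dataclass
class ConditionParams:
    """Per-condition generation parameters."""

    true_prevalence: float
    survey_sensitivity: float = 1.0
    survey_specificity: float = 1.0
    non_response_rate: float = 0.0
    p_record_gp: float = 1.0
    p_record_hospital: float = 0.0
    #: probability a clinical record for a true case falls inside the
    #: 12-month pre-interview window (CURRENT_12M conditions only)
    p_in_window: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "true_prevalence",
            "survey_sensitivity",
            "survey_specificity",
            "non_response_rate",
            "p_record_gp",
            "p_record_hospital",
            "p_in_window",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} outside [0, 1]")


@dataclass
class CohortConfig:
    """Configuration for :func:`generate_cohort`."""

    n_persons: int
    seed: int = 0
    conditions: dict[str, ConditionParams] = field(default_factory=dict)
    gp_coverage: float = 0.8
    fuzzy_match_rate: float = 0.05
    survey_start: date = date(2013, 4, 1)
    survey_end: date = date(2014, 12, 31)
    gp_data_start: date = date(2010, 1, 1)
    hospital_data_start: date = date(2002, 1, 1)
    age_probs: Sequence[float] = DEFAULT_AGE_PROBS
    gender_probs: Sequence[float] = DEFAULT_GENDER_PROBS
    #: per-person probability of a non-matching decoy record per source
    p_noise_gp: float = 0.1
    p_noise_hospital: float = 0.05
    #: emit hospital codes with a random extra subdivision digit, exercising
    #: ICD-10 prefix matching
    icd_subdivisions: bool = True

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ConfigurationError("n_persons must be >= 1")
        for name in ("gp_coverage", "fuzzy_match_rate", "p_noise_gp", "p_noise_hospital"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} outside [0, 1]")
        if self.survey_end < self.survey_start:
            raise ConfigurationError("survey_end precedes survey_start")


class Cohort(NamedTuple):
    """Generated record tables plus the latent truth used to create them."""

    persons: pd.DataFrame
    survey: pd.DataFrame
    gp_events: pd.DataFrame
    hospital_episodes: pd.DataFrame
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# helpers


def _sorted_codes(codes: frozenset[ClinicalCode]) -> list[str]:
    return sorted(c.code for c in codes)


def decoy_codes(collection_or_set) -> tuple[str, str]:
    """A (read, icd10) pair guaranteed not to match any entry in the input.

    Used to generate background-noise records that phenotyping must ignore.
    """
    if isinstance(collection_or_set, ConditionCodeSet):
        sets = [collection_or_set]
    else:
        sets = list(collection_or_set)
    read_candidates = [f"ZZ{i}.." for i in range(1, 50)]
    icd_candidates = [f"Z{n:02d}" for n in range(99, 49, -1)]
    read = next(
        c
        for c in read_candidates
        if not any(s.matches_gp(c) for s in sets)
    )
    icd = next(
        c
        for c in icd_candidates
        if not any(
            code_matches(c, entry, True) or code_matches(entry.code, ClinicalCode(CodeSystem.ICD10, c), True)
            for s in sets
            for entry in s.diagnosis_codes
        )
    )
    return read, icd


def _random_dates(
    rng: np.random.Generator, start: np.ndarray, end: np.ndarray
) -> np.ndarray:
    """Uniform dates in the closed per-row interval [start, end] (day units)."""
    start_days = start.astype("datetime64[D]").astype(np.int64)
    end_days = end.astype("datetime64[D]").astype(np.int64)
    span = end_days - start_days + 1
    offsets = np.floor(rng.random(len(span)) * span).astype(np.int64)
    return (start_days + offsets).astype("datetime64[D]")


def _window_start(interview: pd.Series, window: Window, source_start: date) -> pd.Series:
    """Lower bound of the ascertainment window per person (closed)."""
    if window is Window.CURRENT_12M:
        lower = interview - pd.DateOffset(months=12)
        return lower.clip(lower=pd.Timestamp(source_start))
    return pd.Series(pd.Timestamp(source_start), index=interview.index)


def _emit_icd(rng: np.random.Generator, base_codes: list[str], subdivisions: bool) -> list[str]:
    codes = [base_codes[i] for i in rng.integers(0, len(base_codes), 1)]
    if subdivisions:
        code = codes[0].replace(".", "")
        if len(code) == 3 and rng.random() < 0.5:
            code = f"{code}.{rng.integers(0, 10)}"
        codes = [code]
    return codes


# ---------------------------------------------------------------------------
# stochastic generation


def generate_cohort(config: CohortConfig, code_sets: CodeSetCollection) -> Cohort:
    """Generate a linked cohort according to ``config``.

    For each person and configured condition a latent true status is drawn at
    ``true_prevalence``.  The survey answer is *yes* with probability
    ``survey_sensitivity`` for true cases and ``1 - survey_specificity``
    otherwise, then overwritten to *no_answer* with probability
    ``non_response_rate``.  True cases emit GP/hospital records per
    ``p_record_gp``/``p_record_hospital``; GP records are suppressed for
    persons whose practice does not contribute data (``gp_covered`` False).
    Fully reproducible from ``config.seed``.
    """
    for cid in config.conditions:
        if cid not in code_sets:
            raise ConfigurationError(f"no code set available for condition {cid!r}")
        if not code_sets.get(cid).all_codes():
            raise ConfigurationError(f"code set for condition {cid!r} is empty")

    rng = np.random.default_rng(config.seed)
    n = config.n_persons

    alf = np.array([f"A{i:07d}" for i in range(1, n + 1)])
    gender = rng.choice(GENDERS, size=n, p=list(config.gender_probs))
    age_group = rng.choice(AGE_GROUPS, size=n, p=list(config.age_probs))
    span_days = (config.survey_end - config.survey_start).days + 1
    interview = np.datetime64(config.survey_start, "D") + rng.integers(0, span_days, n)
    gp_covered = rng.random(n) < config.gp_coverage
    match_quality = np.where(rng.random(n) < config.fuzzy_match_rate, "fuzzy", "good")

    persons = pd.DataFrame(
        {
            "alf": alf,
            "gender": gender,
            "age_group": age_group,
            "interview_date": pd.to_datetime(interview),
            "gp_covered": gp_covered,
            "match_quality": match_quality,
        }
    )

    noise_read, noise_icd = decoy_codes(code_sets)
    survey_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    gp_rows: list[pd.DataFrame] = []
    hosp_rows: list[pd.DataFrame] = []
    interview_ts = pd.to_datetime(interview)

    for cid in sorted(config.conditions):
        params = config.conditions[cid]
        cset = code_sets.get(cid)
        truth = rng.random(n) < params.true_prevalence
        yes_prob = np.where(truth, params.survey_sensitivity, 1.0 - params.survey_specificity)
        answer = np.where(rng.random(n) < yes_prob, "yes", "no")
        answer = np.where(rng.random(n) < params.non_response_rate, "no_answer", answer)

        survey_frames.append(pd.DataFrame({"alf": alf, "condition_id": cid, "answer": answer}))
        truth_frames.append(pd.DataFrame({"alf": alf, "condition_id": cid, "true_status": truth}))

        in_window = rng.random(n) < params.p_in_window
        win_start = _window_start(pd.Series(interview_ts), cset.window, config.gp_data_start)

        # GP records for true cases at covered practices
        has_gp = truth & (rng.random(n) < params.p_record_gp) & gp_covered
        gp_codes = _sorted_codes(cset.gp_codes)
        if has_gp.any() and gp_codes:
            idx = np.flatnonzero(has_gp)
            dates = _gp_record_dates(
                rng, interview_ts, win_start, in_window, idx, cset.window, config.gp_data_start
            )
            keep = dates != np.datetime64("NaT")
            idx, dates = idx[keep], dates[keep]
            codes = rng.choice(gp_codes, size=len(idx))
            gp_rows.append(
                pd.DataFrame({"alf": alf[idx], "event_date": pd.to_datetime(dates), "read_code": codes})
            )

        # hospital records for true cases
        has_hosp = truth & (rng.random(n) < params.p_record_hospital)
        diag_codes = _sorted_codes(cset.diagnosis_codes)
        if has_hosp.any() and diag_codes:
            idx = np.flatnonzero(has_hosp)
            dates = _hospital_record_dates(
                rng, interview_ts, in_window, idx, cset.window, config.hospital_data_start
            )
            keep = dates != np.datetime64("NaT")
            idx, dates = idx[keep], dates[keep]
            emitted = [
                ";".join(_emit_icd(rng, diag_codes, config.icd_subdivisions)) for _ in idx
            ]
            hosp_rows.append(
                pd.DataFrame(
                    {"alf": alf[idx], "admission_date": pd.to_datetime(dates), "icd10_codes": emitted}
                )
            )

    # background noise: non-matching records anywhere in each source's range
    noise_gp = np.flatnonzero((rng.random(n) < config.p_noise_gp) & gp_covered)
    if len(noise_gp):
        start = np.full(len(noise_gp), np.datetime64(config.gp_data_start, "D"))
        dates = _random_dates(rng, start, interview[noise_gp])
        gp_rows.append(
            pd.DataFrame(
                {"alf": alf[noise_gp], "event_date": pd.to_datetime(dates), "read_code": noise_read}
            )
        )
    noise_hosp = np.flatnonzero(rng.random(n) < config.p_noise_hospital)
    if len(noise_hosp):
        start = np.full(len(noise_hosp), np.datetime64(config.hospital_data_start, "D"))
        dates = _random_dates(rng, start, interview[noise_hosp])
        hosp_rows.append(
            pd.DataFrame(
                {"alf": alf[noise_hosp], "admission_date": pd.to_datetime(dates), "icd10_codes": noise_icd}
            )
        )

    survey = pd.concat(survey_frames, ignore_index=True) if survey_frames else _empty(SURVEY_COLUMNS)
    truth_table = pd.concat(truth_frames, ignore_index=True) if truth_frames else _empty(TRUTH_COLUMNS)
    gp_events = (
        pd.concat(gp_rows, ignore_index=True).sort_values(["alf", "event_date", "read_code"]).reset_index(drop=True)
        if gp_rows
        else _empty(GP_COLUMNS)
    )
    hospital = (
        pd.concat(hosp_rows, ignore_index=True)
        .sort_values(["alf", "admission_date", "icd10_codes"])
        .reset_index(drop=True)
        if hosp_rows
        else _empty(HOSPITAL_COLUMNS)
    )
    return Cohort(persons, survey, gp_events, hospital, truth_table)


def _gp_record_dates(rng, interview_ts, win_start, in_window, idx, window, source_start):
    interview_arr = interview_ts.values[idx].astype("datetime64[D]")
    if window is Window.EVER:
        start = np.full(len(idx), np.datetime64(source_start, "D"))
        return _random_dates(rng, start, interview_arr)
    win_start_arr = win_start.values[idx].astype("datetime64[D]")
    inside = in_window[idx]
    dates = np.full(len(idx), np.datetime64("NaT"), dtype="datetime64[D]")
    if inside.any():
        dates[inside] = _random_dates(rng, win_start_arr[inside], interview_arr[inside])
    outside = ~inside
    if outside.any():
        # out-of-window record strictly before the window opens
        upper = win_start_arr[outside] - np.timedelta64(1, "D")
        lower = np.full(outside.sum(), np.datetime64(source_start, "D"))
        feasible = upper >= lower
        out_dates = np.full(outside.sum(), np.datetime64("NaT"), dtype="datetime64[D]")
        if feasible.any():
            out_dates[feasible] = _random_dates(rng, lower[feasible], upper[feasible])
        dates[outside] = out_dates
    return dates


def _hospital_record_dates(rng, interview_ts, in_window, idx, window, source_start):
    interview_arr = interview_ts.values[idx].astype("datetime64[D]")
    if window is Window.EVER:
        start = np.full(len(idx), np.datetime64(source_start, "D"))
        return _random_dates(rng, start, interview_arr)
    win_start = (pd.to_datetime(interview_arr) - pd.DateOffset(months=12)).values.astype("datetime64[D]")
    inside = in_window[idx]
    dates = np.full(len(idx), np.datetime64("NaT"), dtype="datetime64[D]")
    if inside.any():
        dates[inside] = _random_dates(rng, win_start[inside], interview_arr[inside])
    outside = ~inside
    if outside.any():
        upper = win_start[outside] - np.timedelta64(1, "D")
        lower = np.full(outside.sum(), np.datetime64(source_start, "D"))
        feasible = upper >= lower
        out_dates = np.full(outside.sum(), np.datetime64("NaT"), dtype="datetime64[D]")
        if feasible.any():
            out_dates[feasible] = _random_dates(rng, lower[feasible], upper[feasible])
        dates[outside] = out_dates
    return dates


def _empty(columns: list[str]) -> pd.DataFrame:
    frame = pd.DataFrame(columns=columns)
    for col in columns:
        if col.endswith("date"):
            frame[col] = pd.to_datetime(frame[col])
    return frame


# ---------------------------------------------------------------------------
# planted contingencies


def plant_contingency(
    tp: int,
    fp: int,
    fn: int,
    tn: int,
    no_answer: int,
    condition_id: str,
    code_set: ConditionCodeSet,
    seed: int = 0,
    *,
    window: Window | None = None,
    no_answer_cases: int = 0,
    source_counts: tuple[int, int, int] | None = None,
    p_decoy: float = 0.3,
    survey_start: date = date(2013, 4, 1),
    survey_end: date = date(2014, 12, 31),
    gp_data_start: date = date(2010, 1, 1),
    hospital_data_start: date = date(2002, 1, 1),
) -> Cohort:
    """Emit record tables that reproduce a specified 2×2 exactly.

    Exactly ``tp+fp+fn+tn+no_answer`` persons are created.  Survey answers
    are *yes* for the tp/fp groups, *no* for fn/tn, *no_answer* otherwise.
    Clinical-positive persons (tp, fn, plus ``no_answer_cases`` of the
    non-responders) receive at least one in-window matching record;
    clinical-negative persons receive none (out-of-window or non-matching
    decoy records are added with probability ``p_decoy`` and must not flip
    status downstream).

    ``source_counts`` optionally fixes the (gp_only, hospital_only, both)
    partition of the clinical positives; it must sum to
    ``tp + fn + no_answer_cases``.  Record-level details — dates, codes,
    demographics — are randomized under ``seed``.
    """
    for name, value in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn), ("no_answer", no_answer)):
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value}")
    if not 0 <= no_answer_cases <= no_answer:
        raise ValueError("no_answer_cases must be between 0 and no_answer")

    window = Window(window) if window is not None else code_set.window
    rng = np.random.default_rng(seed)
    n = tp + fp + fn + tn + no_answer
    n_pos = tp + fn + no_answer_cases

    if source_counts is not None:
        gp_only, hosp_only, both = source_counts
        if gp_only + hosp_only + both != n_pos:
            raise ValueError(
                f"source_counts sum {gp_only + hosp_only + both} != clinical positives {n_pos}"
            )
    elif n_pos:
        draws = rng.choice(["gp", "hosp", "both"], size=n_pos, p=[0.45, 0.45, 0.1])
        gp_only = int((draws == "gp").sum())
        hosp_only = int((draws == "hosp").sum())
        both = n_pos - gp_only - hosp_only
    else:
        gp_only = hosp_only = both = 0

    # group label per person, then shuffle so groups are interleaved
    labels = np.repeat(
        np.array(["tp", "fp", "fn", "tn", "na_case", "na"]),
        [tp, fp, fn, tn, no_answer_cases, no_answer - no_answer_cases],
    )
    rng.shuffle(labels)
    alf = np.array([f"P{i:07d}" for i in range(1, n + 1)])

    gender = rng.choice(GENDERS, size=n, p=list(DEFAULT_GENDER_PROBS))
    age_group = rng.choice(AGE_GROUPS, size=n, p=list(DEFAULT_AGE_PROBS))
    span_days = (survey_end - survey_start).days + 1
    interview = np.datetime64(survey_start, "D") + rng.integers(0, max(span_days, 1), n)
    match_quality = np.where(rng.random(n) < 0.05, "fuzzy", "good")

    clinical_positive = np.isin(labels, ["tp", "fn", "na_case"])
    pos_idx = np.flatnonzero(clinical_positive)
    sources = np.concatenate(
        [np.repeat("gp", gp_only), np.repeat("hosp", hosp_only), np.repeat("both", both)]
    )
    rng.shuffle(sources)

    needs_gp = np.zeros(n, dtype=bool)
    needs_hosp = np.zeros(n, dtype=bool)
    if n_pos:
        needs_gp[pos_idx] = np.isin(sources, ["gp", "both"])
        needs_hosp[pos_idx] = np.isin(sources, ["hosp", "both"])

    # coverage: anyone who must be found via GP is at a covered practice
    gp_covered = rng.random(n) < 0.8
    gp_covered[needs_gp] = True

    persons = pd.DataFrame(
        {
            "alf": alf,
            "gender": gender,
            "age_group": age_group,
            "interview_date": pd.to_datetime(interview),
            "gp_covered": gp_covered,
            "match_quality": match_quality,
        }
    )

    answer = np.where(
        np.isin(labels, ["tp", "fp"]), "yes", np.where(np.isin(labels, ["fn", "tn"]), "no", "no_answer")
    )
    survey = pd.DataFrame({"alf": alf, "condition_id": condition_id, "answer": answer})
    truth = pd.DataFrame({"alf": alf, "condition_id": condition_id, "true_status": clinical_positive})

    interview_d = interview.astype("datetime64[D]")
    if window is Window.CURRENT_12M:
        win_start = (
            (pd.to_datetime(interview_d) - pd.DateOffset(months=12)).values.astype("datetime64[D]")
        )
    gp_frames: list[pd.DataFrame] = []
    hosp_frames: list[pd.DataFrame] = []

    gp_codes = _sorted_codes(code_set.gp_codes)
    diag_codes = _sorted_codes(code_set.diagnosis_codes)
    decoy_read, decoy_icd = decoy_codes(code_set)

    idx_gp = np.flatnonzero(needs_gp)
    if len(idx_gp):
        if not gp_codes:
            raise ConfigurationError(f"{condition_id}: GP source requested but no GP codes")
        if window is Window.CURRENT_12M:
            lo = np.maximum(win_start[idx_gp], np.datetime64(gp_data_start, "D"))
        else:
            lo = np.full(len(idx_gp), np.datetime64(gp_data_start, "D"))
        dates = _random_dates(rng, lo, interview_d[idx_gp])
        gp_frames.append(
            pd.DataFrame(
                {
                    "alf": alf[idx_gp],
                    "event_date": pd.to_datetime(dates),
                    "read_code": rng.choice(gp_codes, size=len(idx_gp)),
                }
            )
        )

    idx_hosp = np.flatnonzero(needs_hosp)
    if len(idx_hosp):
        if not diag_codes:
            raise ConfigurationError(f"{condition_id}: hospital source requested but no diagnosis codes")
        if window is Window.CURRENT_12M:
            lo = np.maximum(win_start[idx_hosp], np.datetime64(hospital_data_start, "D"))
        else:
            lo = np.full(len(idx_hosp), np.datetime64(hospital_data_start, "D"))
        dates = _random_dates(rng, lo, interview_d[idx_hosp])
        emitted = [";".join(_emit_icd(rng, diag_codes, True)) for _ in idx_hosp]
        hosp_frames.append(
            pd.DataFrame(
                {"alf": alf[idx_hosp], "admission_date": pd.to_datetime(dates), "icd10_codes": emitted}
            )
        )

    # decoys for clinical negatives: out-of-window matching records where the
    # window allows it, otherwise non-matching codes; never in-window matches
    neg_idx = np.flatnonzero(~clinical_positive & (rng.random(n) < p_decoy))
    if len(neg_idx):
        half = rng.random(len(neg_idx)) < 0.5
        gp_side = neg_idx[half & persons["gp_covered"].values[neg_idx]]
        hosp_side = neg_idx[~half]
        if len(gp_side):
            if window is Window.CURRENT_12M and gp_codes:
                upper = win_start[gp_side] - np.timedelta64(1, "D")
                lower = np.full(len(gp_side), np.datetime64(gp_data_start, "D"))
                ok = upper >= lower
                if ok.any():
                    dates = _random_dates(rng, lower[ok], upper[ok])
                    gp_frames.append(
                        pd.DataFrame(
                            {
                                "alf": alf[gp_side[ok]],
                                "event_date": pd.to_datetime(dates),
                                "read_code": rng.choice(gp_codes, size=int(ok.sum())),
                            }
                        )
                    )
            else:
                lower = np.full(len(gp_side), np.datetime64(gp_data_start, "D"))
                dates = _random_dates(rng, lower, interview_d[gp_side])
                gp_frames.append(
                    pd.DataFrame(
                        {
                            "alf": alf[gp_side],
                            "event_date": pd.to_datetime(dates),
                            "read_code": decoy_read,
                        }
                    )
                )
        if len(hosp_side):
            lower = np.full(len(hosp_side), np.datetime64(hospital_data_start, "D"))
            dates = _random_dates(rng, lower, interview_d[hosp_side])
            hosp_frames.append(
                pd.DataFrame(
                    {
                        "alf": alf[hosp_side],
                        "admission_date": pd.to_datetime(dates),
                        "icd10_codes": decoy_icd,
                    }
                )
            )

    gp_events = (
        pd.concat(gp_frames, ignore_index=True)
        .sort_values(["alf", "event_date", "read_code"])
        .reset_index(drop=True)
        if gp_frames
        else _empty(GP_COLUMNS)
    )
    hospital = (
        pd.concat(hosp_frames, ignore_index=True)
        .sort_values(["alf", "admission_date", "icd10_codes"])
        .reset_index(drop=True)
        if hosp_frames
        else _empty(HOSPITAL_COLUMNS)
    )
    return Cohort(persons, survey, gp_events, hospital, truth)


# ---------------------------------------------------------------------------
# CSV I/O

_FILES = {
    "persons": "persons.csv",
    "survey": "survey.csv",
    "gp_events": "gp_events.csv",
    "hospital_episodes": "hospital_episodes.csv",
    "truth": "truth.csv",
}
_DATE_COLUMNS = {"persons": ["interview_date"], "gp_events": ["event_date"], "hospital_episodes": ["admission_date"]}


def write_cohort(cohort: Cohort, outdir: str | Path, include_truth: bool = True) -> None:
    """Write the cohort as CSV tables with ISO-8601 dates."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, filename in _FILES.items():
        if name == "truth" and not include_truth:
            continue
        frame = getattr(cohort, name).copy()
        for col in _DATE_COLUMNS.get(name, []):
            frame[col] = pd.to_datetime(frame[col]).dt.strftime("%Y-%m-%d")
        frame.to_csv(outdir / filename, index=False)


def read_cohort(indir: str | Path) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    indir = Path(indir)
    frames = {}
    for name, filename in _FILES.items():
        path = indir / filename
        if name == "truth" and not path.exists():
            frames[name] = _empty(TRUTH_COLUMNS)
            continue
        frame = pd.read_csv(path, dtype={"read_code": str, "icd10_codes": str, "alf": str})
        for col in _DATE_COLUMNS.get(name, []):
            frame[col] = pd.to_datetime(frame[col])
        frames[name] = frame
    if "gp_covered" in frames["persons"].columns and len(frames["persons"]):
        frames["persons"]["gp_covered"] = frames["persons"]["gp_covered"].astype(bool)
    return Cohort(**frames)
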