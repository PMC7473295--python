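"""Platform-file construction: one linked record set per cohort.

The platform joins survey responses to clinical event streams while
retaining every matched survey respondent, including those with no clinical
records at all.  Clinical rows whose person id does not appear in the person
table are discarded (and counted); survey rows without a usable person id
are removed when ``drop_unmatched`` is set.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .synthetic_data import (
    GP_COLUMNS,
    HOSPITAL_COLUMNS,
    PERSON_COLUMNS,
    SURVEY_COLUMNS,
    Cohort,
)

__all__ = ["PlatformRecordSet", "IntegrityError", "build_platform", "write_platform", "read_platform"]

logger = logging.getLogger(__name__)


class IntegrityError(ValueError):
    """Input tables violate a referential-integrity constraint."""


@dataclass
class PlatformRecordSet:
    """The linked per-person dataset: persons + survey + clinical streams."""

    persons: pd.DataFrame
    survey: pd.DataFrame
    gp_events: pd.DataFrame
    hospital_episodes: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    def condition_ids(self) -> list[str]:
        return sorted(self.survey["condition_id"].unique())


def build_platform(
    persons: pd.DataFrame,
    survey: pd.DataFrame,
    gp_events: pd.DataFrame,
    hospital_episodes: pd.DataFrame,
    drop_unmatched: bool = True,
    drop_fuzzy: bool = False,
) -> PlatformRecordSet:
    """Join the four input tables into a :class:`PlatformRecordSet`.

    Parameters
    ----------
    drop_unmatched
        Remove survey persons lacking a person id (null ``alf``).
    drop_fuzzy
        Exclude persons whose record linkage was a fuzzy match.  Off by
        default: both good and fuzzy matches are retained to maximise the
        sample; the flag supports sensitivity analysis.

    Raises
    ------
    IntegrityError
        If the survey table carries duplicate (alf, condition_id) rows.
    """
    persons = persons.copy()
    survey = survey.copy()
    n_input_persons = len(persons)

    dupes = survey.loc[
        survey.duplicated(["alf", "condition_id"], keep=False) & survey["alf"].notna()
    ]
    if len(dupes):
        offenders = sorted(set(map(tuple, dupes[["alf", "condition_id"]].values)))
        raise IntegrityError(f"duplicate survey rows for (alf, condition_id): {offenders[:20]}")

    unmatched_persons = 0
    if drop_unmatched:
        null_alf = persons["alf"].isna() | (persons["alf"].astype(str).str.strip() == "")
        unmatched_persons = int(null_alf.sum())
        persons = persons.loc[~null_alf]
        survey = survey.loc[survey["alf"].notna()]

    dropped_fuzzy = 0
    if drop_fuzzy and "match_quality" in persons.columns:
        fuzzy = persons["match_quality"] == "fuzzy"
        dropped_fuzzy = int(fuzzy.sum())
        persons = persons.loc[~fuzzy]

    known = set(persons["alf"])
    survey_orphans = int((~survey["alf"].isin(known)).sum())
    survey = survey.loc[survey["alf"].isin(known)]
    gp_orphans = int((~gp_events["alf"].isin(known)).sum())
    gp_events = gp_events.loc[gp_events["alf"].isin(known)].copy()
    hosp_orphans = int((~hospital_episodes["alf"].isin(known)).sum())
    hospital_episodes = hospital_episodes.loc[hospital_episodes["alf"].isin(known)].copy()

    for label, count in (
        ("unmatched survey persons", unmatched_persons),
        ("fuzzy-match persons", dropped_fuzzy),
        ("orphan survey rows", survey_orphans),
        ("orphan GP events", gp_orphans),
        ("orphan hospital episodes", hosp_orphans),
    ):
        if count:
            logger.warning("build_platform: discarded %d %s", count, label)

    manifest = {
        "n_persons_input": n_input_persons,
        "n_persons": len(persons),
        "n_survey_rows": len(survey),
        "n_gp_events": len(gp_events),
        "n_hospital_episodes": len(hospital_episodes),
        "discarded": {
            "unmatched_persons": unmatched_persons,
            "fuzzy_persons": dropped_fuzzy,
            "orphan_survey_rows": survey_orphans,
            "orphan_gp_events": gp_orphans,
            "orphan_hospital_episodes": hosp_orphans,
        },
    }
    return PlatformRecordSet(
        persons=persons.reset_index(drop=True),
        survey=survey.reset_index(drop=True),
        gp_events=gp_events.reset_index(drop=True),
        hospital_episodes=hospital_episodes.reset_index(drop=True),
        manifest=manifest,
    )


def _config_hash(manifest: dict) -> str:
    return hashlib.sha256(json.dumps(manifest, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_platform(platform: PlatformRecordSet, outdir: str | Path) -> None:
    """Serialize the platform as the four-CSV layout plus ``manifest.json``."""
    from .synthetic_data import write_cohort

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = Cohort(
        persons=platform.persons,
        survey=platform.survey,
        gp_events=platform.gp_events,
        hospital_episodes=platform.hospital_episodes,
        truth=pd.DataFrame(columns=["alf", "condition_id", "true_status"]),
    )
    write_cohort(cohort, outdir, include_truth=False)
    manifest = dict(platform.manifest)
    manifest["config_hash"] = _config_hash(manifest)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2)


def read_platform(indir: str | Path) -> PlatformRecordSet:
    from .synthetic_data import read_cohort

    indir = Path(indir)
    cohort = read_cohort(indir)
    manifest_path = indir / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        with open(manifest_path, encoding="utf-8") as handle:
            manifest = json.load(handle)
    return PlatformRecordSet(
        persons=cohort.persons,
        survey=cohort.survey,
        gp_events=cohort.gp_events,
        hospital_episodes=cohort.hospital_episodes,
        manifest=manifest,
    )
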