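from __future__ import annotations

import pytest

import linkval as lv

# printed 2x2 counts used throughout the suite:
# condition -> (tp, fp, fn, tn, no_answer, extra clinical cases among
# non-responders, (gp_only, hospital_only, both))
PLANTED = {
    "angina": (77, 319, 38, 10329, 560, 9, (32, 84, 8)),
    "heart_attack": (82, 391, 27, 10359, 464, 5, (21, 68, 25)),
    "heart_failure": (33, 158, 33, 10468, 631, 7, (28, 39, 6)),
    "asthma": (818, 355, 370, 9220, 560, 68, (1079, 80, 97)),
}

N_RESPONDENTS = 11_323


@pytest.fixture(scope="session")
def code_sets() -> lv.CodeSetCollection:
    return lv.default_code_sets()


def plant_pipeline(condition_id: str, code_sets: lv.CodeSetCollection, seed: int = 1):
    """Plant the printed 2x2 for one condition and run the full pipeline."""
    tp, fp, fn, tn, na, extra, sources = PLANTED[condition_id]
    cohort = lv.plant_contingency(
        tp,
        fp,
        fn,
        tn,
        na,
        condition_id,
        code_sets.get(condition_id),
        seed=seed,
        no_answer_cases=extra,
        source_counts=sources,
    )
    platform = lv.build_platform(
        cohort.persons, cohort.survey, cohort.gp_events, cohort.hospital_episodes
    )
    tags = lv.ascertain(platform, code_sets.get(condition_id))
    return cohort, platform, tags


@pytest.fixture(scope="session")
def planted_runs(code_sets):
    """Planted cohort + platform + case tags for all four conditions."""
    return {cid: plant_pipeline(cid, code_sets) for cid in PLANTED}
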