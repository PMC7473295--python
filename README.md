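# linkval

Validate survey-reported chronic-condition prevalence against linked
primary- and secondary-care records.

Given (a) per-condition clinical code lists (ICD-10 hospital diagnosis
codes, Read GP event codes, optionally Read medication codes), (b) a linked
per-person record set joining survey answers to GP events and hospital
episodes, `linkval` tags each person as a clinical case using
condition-specific ascertainment windows ("ever" vs "in the 12 months prior
to interview"), attributes cases to their identifying source (GP / hospital
/ both), and reports the survey-vs-clinical validation block per condition:
2×2 contingency matrix, sensitivity/specificity/PPV/NPV, Cohen's kappa on
valid responses, prevalence per 1,000 with 95% confidence intervals, the
non-response rate, and a partial-GP-coverage undercount estimate.

A first-class synthetic-data module generates linked cohorts with
controllable true status, misreporting, recording and timing probabilities —
including a *planted contingency* mode that emits record tables which, when
run through the whole pipeline, reproduce any specified 2×2 exactly.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria; the rest are unit
and property tests per module.

## Library quick start

```python
import linkval as lv

code_sets = lv.default_code_sets()          # illustrative fixture code lists
cohort = lv.plant_contingency(77, 319, 38, 10329, 560, "angina",
                              code_sets.get("angina"), seed=1)
platform = lv.build_platform(cohort.persons, cohort.survey,
                             cohort.gp_events, cohort.hospital_episodes)
tags = lv.ascertain(platform, code_sets.get("angina"))
report = lv.validate_condition(platform, tags, "angina")
print(report.metrics, report.kappa, report.prevalence_survey)
```

## CLI

One YAML config drives a run; exactly one input mode (`files`, `generate`
or `plant`) must be configured:

```yaml
mode: plant
seed: 1
output_dir: out/
code_sets: builtin          # or a path to a CSV/JSON code-list file
flags:
  icd_prefix_matching: true
  min_gp_events: 1
  ci_method: wald           # or wilson
  prevalence_denominator: all_respondents   # or valid_responses
  clinical_numerator: contingency           # or all_identified
  drop_fuzzy: false
plant:
  angina:
    tp: 77
    fp: 319
    fn: 38
    tn: 10329
    no_answer: 560
    no_answer_cases: 9      # clinical positives among non-responders
    sources: [32, 84, 8]    # gp_only / hospital_only / both
```

```sh
linkval all --config run.yaml        # full pipeline
linkval generate --config gen.yaml   # write a synthetic cohort only
linkval plant --config run.yaml      # write planted cohorts only
linkval phenotype --data out/cohort --out out/tags
linkval report --run out/
```

Pipeline outputs (all CSV/JSON): platform manifests, `case_tags.csv`,
`source_attribution.csv`, per-condition `contingency_<id>.csv`,
`validation_report.csv`/`.json`, `non_response.csv` and a run log.

## Notes

- The bundled code lists (`default_code_sets`) are small illustrative
  fixtures; all pipeline statistics are independent of the specific codes
  chosen. Supply your own lists via the documented CSV/JSON schema
  (`condition_id,system,code,role,description[,window,question_text]`).
- ICD-10 matching defaults to dot-insensitive prefix matching (category
  entries match subdivisions); Read codes match exactly after trailing-dot
  normalization.
- The 12-month window is a calendar-month subtraction, closed at both ends;
  "ever" windows are bounded below by each source's data start (hospital
  2002-01-01, GP 2010-01-01 by default).
- The clinical-prevalence numerator is policy-configurable (`contingency`:
  clinical positives among valid responders; `all_identified`: every tagged
  case including non-responders); the report records which was used.
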