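"""Condition code sets: loading, validation, and code matching.

A condition is ascertained from clinical records via three code lists:
hospital diagnosis codes (ICD-10), GP event codes (Read v2) and, optionally,
GP medication codes (Read v2).  Each condition also carries an ascertainment
window rule: ``EVER`` (any record since the source's data start) or
``CURRENT_12M`` (a record in the 12 months up to and including the interview
date).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CodeSystem",
    "Window",
    "ClinicalCode",
    "ConditionCodeSet",
    "CodeSetCollection",
    "ExclusivityConflict",
    "CodeListParseError",
    "CodeListSchemaError",
    "code_matches",
    "load_code_sets",
    "save_code_sets",
    "validate_exclusivity",
    "default_code_sets",
    "normalize_icd10",
    "normalize_read",
]


class CodeSystem(str, Enum):
    ICD10 = "ICD10"
    READ = "READ"


class Window(str, Enum):
    EVER = "EVER"
    CURRENT_12M = "CURRENT_12M"


class CodeListParseError(ValueError):
    """A row of a code-list file could not be parsed."""


class CodeListSchemaError(ValueError):
    """A code-list file violates the documented schema."""


# letter + two digits + optional subdivision characters, dots removed
_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]*$")


def normalize_icd10(code: str) -> str:
    """Uppercase and strip the decimal point from an ICD-10 code."""
    return code.strip().upper().replace(".", "")


def normalize_read(code: str) -> str:
    """Trim a Read code and drop trailing-dot padding (5-byte Read v2)."""
    return code.strip().rstrip(".")


@dataclass(frozen=True, order=True)
class ClinicalCode:
    """A single code in a clinical coding system.

    ICD-10 codes are stored uppercase; Read codes are case-preserved with
    trailing-dot padding removed.
    """

    system: CodeSystem
    code: str
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        system = CodeSystem(self.system)
        raw = self.code.strip()
        if system is CodeSystem.ICD10:
            code = raw.upper()
            if not _ICD10_RE.match(code.replace(".", "")):
                raise ValueError(f"not a valid ICD-10 code: {self.code!r}")
        else:
            code = raw.rstrip(".")
        if not code or any(ch.isspace() for ch in code):
            raise ValueError(f"empty or whitespace-containing code: {self.code!r}")
        object.__setattr__(self, "system", system)
        object.__setattr__(self, "code", code)

    @property
    def normalized(self) -> str:
        if self.system is CodeSystem.ICD10:
            return normalize_icd10(self.code)
        return normalize_read(self.code)


def code_matches(
    record_code: str, code_set_entry: ClinicalCode, icd_prefix_matching: bool = True
) -> bool:
    """Does a record-level code match a code-list entry?

    Read codes match by exact string equality after trimming and
    trailing-dot normalization.  ICD-10 codes compare dot-insensitively;
    with ``icd_prefix_matching`` a category-level entry (e.g. ``I21``)
    matches all of its subdivisions (``I21.9``, ``I219`` ...).
    """
    if not record_code or not record_code.strip():
        raise ValueError("record_code must be non-empty")
    if code_set_entry.system is CodeSystem.READ:
        return normalize_read(record_code) == code_set_entry.normalized
    rec = normalize_icd10(record_code)
    entry = code_set_entry.normalized
    if icd_prefix_matching:
        return rec.startswith(entry)
    return rec == entry


@dataclass(frozen=True)
class ConditionCodeSet:
    """Code lists plus ascertainment rule for one condition."""

    condition_id: str
    diagnosis_codes: frozenset[ClinicalCode]
    event_codes: frozenset[ClinicalCode]
    medication_codes: frozenset[ClinicalCode] = frozenset()
    window: Window = Window.CURRENT_12M
    question_text: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "diagnosis_codes", frozenset(self.diagnosis_codes))
        object.__setattr__(self, "event_codes", frozenset(self.event_codes))
        object.__setattr__(self, "medication_codes", frozenset(self.medication_codes))
        object.__setattr__(self, "window", Window(self.window))
        if not self.condition_id:
            raise ValueError("condition_id must be non-empty")
        if not (self.diagnosis_codes or self.event_codes):
            raise ValueError(
                f"{self.condition_id}: diagnosis_codes and event_codes are both empty"
            )
        for code in self.diagnosis_codes:
            if code.system is not CodeSystem.ICD10:
                raise ValueError(f"{self.condition_id}: diagnosis code {code.code} is not ICD10")
        for code in self.event_codes | self.medication_codes:
            if code.system is not CodeSystem.READ:
                raise ValueError(f"{self.condition_id}: GP code {code.code} is not READ")

    @property
    def gp_codes(self) -> frozenset[ClinicalCode]:
        """Read codes eligible for GP-record matching (events + medications)."""
        return self.event_codes | self.medication_codes

    def all_codes(self) -> frozenset[ClinicalCode]:
        return self.diagnosis_codes | self.event_codes | self.medication_codes

    def matches_gp(self, read_code: str) -> bool:
        return normalize_read(read_code) in {c.normalized for c in self.gp_codes}

    def matches_hospital(self, icd_code: str, icd_prefix_matching: bool = True) -> bool:
        return any(
            code_matches(icd_code, entry, icd_prefix_matching)
            for entry in self.diagnosis_codes
        )

    def without_medications(self) -> "ConditionCodeSet":
        """Copy of this set with medication codes removed (sensitivity analysis)."""
        return ConditionCodeSet(
            condition_id=self.condition_id,
            diagnosis_codes=self.diagnosis_codes,
            event_codes=self.event_codes,
            medication_codes=frozenset(),
            window=self.window,
            question_text=self.question_text,
        )


@dataclass(frozen=True)
class ExclusivityConflict:
    condition_a: str
    condition_b: str
    code: ClinicalCode

    def __post_init__(self) -> None:
        # canonical ordering so conflicts are comparable regardless of scan order
        if self.condition_b < self.condition_a:
            a, b = self.condition_b, self.condition_a
            object.__setattr__(self, "condition_a", a)
            object.__setattr__(self, "condition_b", b)


@dataclass
class CodeSetCollection:
    """All condition code sets for a run, plus exclusivity constraints.

    ``exclusivity_groups`` lists groups of condition ids whose code lists
    must be pairwise disjoint (e.g. the cardiovascular conditions, whose
    ambiguous codes were deliberately left untagged).
    """

    sets: list[ConditionCodeSet]
    exclusivity_groups: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.condition_id for s in self.sets]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate condition ids: {dupes}")
        known = set(ids)
        for group in self.exclusivity_groups:
            unknown = set(group) - known
            if unknown:
                raise ValueError(f"exclusivity group names unknown conditions: {sorted(unknown)}")

    def condition_ids(self) -> list[str]:
        return [s.condition_id for s in self.sets]

    def get(self, condition_id: str) -> ConditionCodeSet:
        for s in self.sets:
            if s.condition_id == condition_id:
                return s
        raise KeyError(condition_id)

    def __contains__(self, condition_id: str) -> bool:
        return condition_id in self.condition_ids()

    def __iter__(self):
        return iter(self.sets)


def validate_exclusivity(collection: CodeSetCollection) -> list[ExclusivityConflict]:
    """Report codes shared between conditions of the same exclusivity group.

    Returns an empty list when every declared group is pairwise disjoint
    across all three code roles.  Overlaps between conditions that do not
    share a group are ignored.
    """
    conflicts: set[ExclusivityConflict] = set()
    for group in collection.exclusivity_groups:
        members = [collection.get(cid) for cid in group]
        for i, first in enumerate(members):
            for second in members[i + 1 :]:
                shared = first.all_codes() & second.all_codes()
                for code in shared:
                    conflicts.add(
                        ExclusivityConflict(first.condition_id, second.condition_id, code)
                    )
    return sorted(conflicts, key=lambda c: (c.condition_a, c.condition_b, c.code))


# ---------------------------------------------------------------------------
# serialization

_ROLES = ("diagnosis", "event", "medication")
_CSV_HEADER = ["condition_id", "system", "code", "role", "description"]
_OPTIONAL_COLUMNS = ["window", "question_text"]

#: window defaults for the bundled fixture conditions, applied when a file
#: does not carry a window column
DEFAULT_WINDOWS = {
    "angina": Window.CURRENT_12M,
    "heart_attack": Window.EVER,
    "heart_failure": Window.CURRENT_12M,
    "asthma": Window.CURRENT_12M,
}


def _rows_to_collection(
    rows: Iterable[dict],
    exclusivity_groups: Sequence[Sequence[str]] | None,
    source: str,
) -> CodeSetCollection:
    by_condition: dict[str, dict[str, set[ClinicalCode]]] = {}
    windows: dict[str, Window] = {}
    questions: dict[str, str] = {}
    for lineno, row in enumerate(rows, start=2):  # row 1 is the header
        missing = [c for c in _CSV_HEADER[:4] if not (row.get(c) or "").strip()]
        if missing:
            raise CodeListParseError(f"{source}, line {lineno}: missing field(s) {missing}")
        cid = row["condition_id"].strip()
        system_raw = row["system"].strip().upper()
        role = row["role"].strip().lower()
        if system_raw not in CodeSystem.__members__:
            raise CodeListSchemaError(
                f"{source}, line {lineno}: unknown system {row['system']!r}"
            )
        if role not in _ROLES:
            raise CodeListSchemaError(f"{source}, line {lineno}: unknown role {row['role']!r}")
        system = CodeSystem(system_raw)
        if role == "diagnosis" and system is not CodeSystem.ICD10:
            raise CodeListSchemaError(
                f"{source}, line {lineno}: diagnosis codes must be ICD10"
            )
        if role in ("event", "medication") and system is not CodeSystem.READ:
            raise CodeListSchemaError(
                f"{source}, line {lineno}: {role} codes must be READ"
            )
        try:
            code = ClinicalCode(system, row["code"], (row.get("description") or "").strip())
        except ValueError as exc:
            raise CodeListParseError(f"{source}, line {lineno}: {exc}") from exc
        bucket = by_condition.setdefault(
            cid, {"diagnosis": set(), "event": set(), "medication": set()}
        )
        bucket[role].add(code)  # duplicate rows collapse into the set
        window_raw = (row.get("window") or "").strip()
        if window_raw:
            if window_raw.upper() not in Window.__members__:
                raise CodeListSchemaError(
                    f"{source}, line {lineno}: unknown window {window_raw!r}"
                )
            window = Window(window_raw.upper())
            if cid in windows and windows[cid] is not window:
                raise CodeListSchemaError(
                    f"{source}, line {lineno}: conflicting windows for {cid}"
                )
            windows[cid] = window
        question = (row.get("question_text") or "").strip()
        if question and cid not in questions:
            questions[cid] = question

    sets = []
    for cid, bucket in by_condition.items():
        window = windows.get(cid, DEFAULT_WINDOWS.get(cid, Window.EVER))
        try:
            sets.append(
                ConditionCodeSet(
                    condition_id=cid,
                    diagnosis_codes=frozenset(bucket["diagnosis"]),
                    event_codes=frozenset(bucket["event"]),
                    medication_codes=frozenset(bucket["medication"]),
                    window=window,
                    question_text=questions.get(cid, ""),
                )
            )
        except ValueError as exc:
            raise CodeListSchemaError(f"{source}: {exc}") from exc
    groups = [list(g) for g in exclusivity_groups] if exclusivity_groups else []
    return CodeSetCollection(sets=sets, exclusivity_groups=groups)


def load_code_sets(
    path: str | Path,
    format: str | None = None,
    exclusivity_groups: Sequence[Sequence[str]] | None = None,
) -> CodeSetCollection:
    """Load a code-set collection from CSV or JSON.

    CSV schema: header ``condition_id,system,code,role,description`` with
    optional ``window`` and ``question_text`` columns; role is one of
    ``diagnosis``/``event``/``medication``.  The JSON format mirrors the CSV:
    a list of row objects with the same fields, optionally wrapped in
    ``{"codes": [...], "exclusivity_groups": [...]}``.
    """
    path = Path(path)
    if format is None:
        format = "JSON" if path.suffix.lower() == ".json" else "CSV"
    format = format.upper()
    if format == "CSV":
        with open(path, newline="", encoding="utf-8") as handle:
            reader = csv.DictReader(handle)
            if reader.fieldnames is None or not set(_CSV_HEADER[:4]) <= set(reader.fieldnames):
                raise CodeListSchemaError(
                    f"{path}: header must contain {_CSV_HEADER[:4]}, got {reader.fieldnames}"
                )
            return _rows_to_collection(list(reader), exclusivity_groups, str(path))
    if format == "JSON":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        if isinstance(payload, dict):
            rows = payload.get("codes", [])
            groups = exclusivity_groups or payload.get("exclusivity_groups", [])
        else:
            rows, groups = payload, exclusivity_groups
        return _rows_to_collection(rows, groups, str(path))
    raise ValueError(f"unknown format {format!r}")


def save_code_sets(collection: CodeSetCollection, path: str | Path, format: str | None = None) -> None:
    """Serialize a collection to the CSV/JSON schema read by :func:`load_code_sets`."""
    path = Path(path)
    if format is None:
        format = "JSON" if path.suffix.lower() == ".json" else "CSV"
    format = format.upper()
    rows = []
    for cset in sorted(collection.sets, key=lambda s: s.condition_id):
        for role, codes in (
            ("diagnosis", cset.diagnosis_codes),
            ("event", cset.event_codes),
            ("medication", cset.medication_codes),
        ):
            for code in sorted(codes):
                rows.append(
                    {
                        "condition_id": cset.condition_id,
                        "system": code.system.value,
                        "code": code.code,
                        "role": role,
                        "description": code.description,
                        "window": cset.window.value,
                        "question_text": cset.question_text,
                    }
                )
    if format == "CSV":
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.DictWriter(handle, fieldnames=_CSV_HEADER + _OPTIONAL_COLUMNS)
            writer.writeheader()
            writer.writerows(rows)
    elif format == "JSON":
        payload = {"codes": rows, "exclusivity_groups": collection.exclusivity_groups}
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=2)
    else:
        raise ValueError(f"unknown format {format!r}")


def default_code_sets() -> CodeSetCollection:
    """Illustrative fixture code sets for the four bundled conditions.

    These are small, plausible stand-ins — not authoritative clinical code
    lists.  The three cardiovascular conditions form an exclusivity group
    and carry no medication codes; asthma carries medication codes.
    """

    def icd(*codes: str) -> frozenset[ClinicalCode]:
        return frozenset(ClinicalCode(CodeSystem.ICD10, c) for c in codes)

    def read(*codes: str) -> frozenset[ClinicalCode]:
        return frozenset(ClinicalCode(CodeSystem.READ, c) for c in codes)

    sets = [
        ConditionCodeSet(
            condition_id="angina",
            diagnosis_codes=icd("I20"),
            event_codes=read("G33..", "G33z."),
            window=Window.CURRENT_12M,
            question_text="currently being treated for angina",
        ),
        ConditionCodeSet(
            condition_id="heart_attack",
            diagnosis_codes=icd("I21", "I22"),
            event_codes=read("G30..", "G35..", "G30X."),
            window=Window.EVER,
            question_text="ever been treated for heart attack",
        ),
        ConditionCodeSet(
            condition_id="heart_failure",
            diagnosis_codes=icd("I50"),
            event_codes=read("G58..", "G580.", "G581."),
            window=Window.CURRENT_12M,
            question_text="currently being treated for heart failure",
        ),
        ConditionCodeSet(
            condition_id="asthma",
            diagnosis_codes=icd("J45", "J46"),
            event_codes=read("H33..", "H330.", "H331."),
            medication_codes=read("c11..", "c12..", "c14y.", "c15.."),
            window=Window.CURRENT_12M,
            question_text="currently being treated for asthma",
        ),
    ]
    return CodeSetCollection(
        sets=sets,
        exclusivity_groups=[["angina", "heart_attack", "heart_failure"]],
    )
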