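"""Encounter-level predictor construction.

An inpatient encounter carries a principal diagnosis and any number of
secondary diagnoses, each with a present-on-admission (POA) flag.  Two
feature families are built per encounter and per *phase*:

* 18 ordinal body-system indicators with three severity levels —
  0: no diagnosis in that body system; 1: at least one diagnosis but none
  designated CC/MCC; 2: at least one CC or MCC diagnosis in the system;
* 30 binary Elixhauser comorbidity flags, set from *secondary* diagnoses
  only (the conventional Elixhauser definition excludes the principal
  diagnosis).

The *discharge* phase uses every coded diagnosis; the *admission* phase
uses only diagnoses present on admission (POA flag Y or W) plus
POA-reporting-exempt codes, so admission features are always an
elementwise lower bound of discharge features.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from jscore.codes import CCMCC, N_BODY_SYSTEMS, ReferenceMaps, normalize_code

__all__ = [
    "Phase",
    "CodedDiagnosis",
    "Encounter",
    "SeverityFeatures",
    "select_codes",
    "body_system_levels",
    "elixhauser_flags",
    "build_features",
    "binarize_outcome",
    "read_encounters",
    "write_encounters",
    "POA_PRESENT_DEFAULT",
]

Phase = Literal["admission", "discharge"]

#: POA flag values counted as present on admission.  CMS treats both Y
#: (yes) and W (clinically undetermined) as POA for payment purposes;
#: N (no), U (insufficient documentation), "1"/blank (exempt reporting)
#: are not.  Exempt codes are included by table lookup, not by flag.
POA_PRESENT_DEFAULT: frozenset[str] = frozenset({"Y", "W"})

_VALID_POA = frozenset({"Y", "N", "U", "W", "1", ""})


@dataclass(frozen=True)
class CodedDiagnosis:
    """One ICD-10-CM diagnosis on an encounter."""

    code: str
    poa: str = "Y"
    position: Literal["principal", "secondary"] = "secondary"

    def __post_init__(self) -> None:
        object.__setattr__(self, "code", normalize_code(self.code))
        poa = str(self.poa).strip().upper()
        if poa not in _VALID_POA:
            raise ValueError(f"invalid POA flag {self.poa!r} (expected Y/N/U/W/1/blank)")
        object.__setattr__(self, "poa", poa)
        if self.position not in ("principal", "secondary"):
            raise ValueError(f"invalid diagnosis position {self.position!r}")


@dataclass(frozen=True)
class Encounter:
    """One adult inpatient encounter with its coded diagnoses."""

    encounter_id: str
    age: float
    sex: str
    race: str
    discharge_month: str  # "YYYY-MM"
    admit_soi: int
    discharge_soi: int
    diagnoses: tuple[CodedDiagnosis, ...] = ()
    facility: str | None = None
    cds_reviewed: bool | None = None
    cds_queried: bool | None = None

    def __post_init__(self) -> None:
        if self.age < 18:
            raise ValueError(f"encounter {self.encounter_id}: age {self.age} < 18")
        for name in ("admit_soi", "discharge_soi"):
            soi = getattr(self, name)
            if soi not in (1, 2, 3, 4):
                raise ValueError(
                    f"encounter {self.encounter_id}: {name}={soi} outside 1..4"
                )
        object.__setattr__(self, "diagnoses", tuple(self.diagnoses))
        n_principal = sum(1 for d in self.diagnoses if d.position == "principal")
        if self.diagnoses and n_principal != 1:
            raise ValueError(
                f"encounter {self.encounter_id}: {n_principal} principal diagnoses, "
                "expected exactly 1"
            )


@dataclass(frozen=True)
class SeverityFeatures:
    """Model-ready predictors for one encounter and phase."""

    phase: Phase
    body_system_levels: np.ndarray  # shape (18,), values in {0,1,2}
    elix_flags: np.ndarray  # shape (30,), values in {0,1}

    def __post_init__(self) -> None:
        bsl = np.asarray(self.body_system_levels, dtype=np.int8)
        ef = np.asarray(self.elix_flags, dtype=np.int8)
        if bsl.shape != (N_BODY_SYSTEMS,) or not np.isin(bsl, (0, 1, 2)).all():
            raise ValueError("body_system_levels must be 18 values in {0,1,2}")
        if ef.shape != (30,) or not np.isin(ef, (0, 1)).all():
            raise ValueError("elix_flags must be 30 values in {0,1}")
        bsl.setflags(write=False)
        ef.setflags(write=False)
        object.__setattr__(self, "body_system_levels", bsl)
        object.__setattr__(self, "elix_flags", ef)


def select_codes(
    encounter: Encounter,
    phase: Phase,
    maps: ReferenceMaps,
    *,
    poa_present: frozenset[str] = POA_PRESENT_DEFAULT,
) -> list[CodedDiagnosis]:
    """Pick the diagnoses that inform the given phase.

    Discharge uses every diagnosis.  Admission keeps diagnoses whose POA
    flag marks them present on admission, plus any POA-exempt code
    regardless of its flag; the result is always a subset of the
    discharge list.
    """
    if phase == "discharge":
        return list(encounter.diagnoses)
    if phase != "admission":
        raise ValueError(f"unknown phase {phase!r}")
    return [
        d
        for d in encounter.diagnoses
        if d.poa in poa_present or maps.poa_exempt(d.code)
    ]


def body_system_levels(
    codes: Sequence[CodedDiagnosis],
    maps: ReferenceMaps,
    *,
    include_principal: bool = True,
) -> np.ndarray:
    """Per-system maximum severity level over the given diagnoses.

    A system scores 2 if any of its codes is CC or MCC, 1 if it has codes
    but none CC/MCC, 0 if no code falls in it.  Codes without a
    body-system mapping contribute nothing (warned, never fatal).
    """
    levels = np.zeros(N_BODY_SYSTEMS, dtype=np.int8)
    for d in codes:
        if not include_principal and d.position == "principal":
            continue
        system = maps.body_system_of(d.code)
        if system is None:
            warnings.warn(
                f"diagnosis code {d.code} has no body-system mapping", stacklevel=2
            )
            continue
        severity = 2 if maps.ccmcc_of(d.code) is not CCMCC.NONE else 1
        idx = system - 1
        if severity > levels[idx]:
            levels[idx] = severity
    return levels


def elixhauser_flags(
    codes: Sequence[CodedDiagnosis], maps: ReferenceMaps
) -> np.ndarray:
    """Binary comorbidity flags from secondary diagnoses only."""
    flags = np.zeros(len(maps.categories), dtype=np.int8)
    index = {name: i for i, name in enumerate(maps.categories)}
    for d in codes:
        if d.position == "principal":
            continue
        for cat in maps.elix_of(d.code):
            flags[index[cat]] = 1
    return flags


def build_features(
    encounter: Encounter,
    maps: ReferenceMaps,
    phase: Phase,
    *,
    poa_present: frozenset[str] = POA_PRESENT_DEFAULT,
    include_principal_in_body_systems: bool = True,
) -> SeverityFeatures:
    """Compose code selection with both indicator builders."""
    codes = select_codes(encounter, phase, maps, poa_present=poa_present)
    return SeverityFeatures(
        phase=phase,
        body_system_levels=body_system_levels(
            codes, maps, include_principal=include_principal_in_body_systems
        ),
        elix_flags=elixhauser_flags(codes, maps),
    )


def binarize_outcome(soi: int) -> int:
    """Collapse the 4-level severity of illness to the binary outcome.

    Minor/moderate (1, 2) -> 0 (low severity); major/extreme (3, 4) -> 1
    (high severity).
    """
    if soi not in (1, 2, 3, 4):
        raise ValueError(f"SOI level {soi!r} outside 1..4")
    return 1 if soi >= 3 else 0


# ---------------------------------------------------------------------------
# Encounter file I/O
# ---------------------------------------------------------------------------

_CSV_FIELDS = [
    "encounter_id",
    "age",
    "sex",
    "race",
    "discharge_month",
    "admit_soi",
    "discharge_soi",
    "facility",
    "cds_reviewed",
    "cds_queried",
    "diagnoses",
]


def _diag_to_str(d: CodedDiagnosis) -> str:
    return f"{d.code};{d.poa};{d.position}"


def _diag_from_str(s: str) -> CodedDiagnosis:
    code, poa, position = s.split(";")
    return CodedDiagnosis(code=code, poa=poa, position=position)  # type: ignore[arg-type]


def _opt_bool(value) -> bool | None:
    if value is None or value == "":
        return None
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("1", "true", "yes", "y")


def encounter_to_dict(e: Encounter) -> dict:
    return {
        "encounter_id": e.encounter_id,
        "age": e.age,
        "sex": e.sex,
        "race": e.race,
        "discharge_month": e.discharge_month,
        "admit_soi": e.admit_soi,
        "discharge_soi": e.discharge_soi,
        "facility": e.facility,
        "cds_reviewed": e.cds_reviewed,
        "cds_queried": e.cds_queried,
        "diagnoses": [
            {"code": d.code, "poa": d.poa, "position": d.position} for d in e.diagnoses
        ],
    }


def encounter_from_dict(row: dict) -> Encounter:
    return Encounter(
        encounter_id=str(row["encounter_id"]),
        age=float(row["age"]),
        sex=str(row["sex"]),
        race=str(row["race"]),
        discharge_month=str(row["discharge_month"]),
        admit_soi=int(row["admit_soi"]),
        discharge_soi=int(row["discharge_soi"]),
        facility=row.get("facility") or None,
        cds_reviewed=_opt_bool(row.get("cds_reviewed")),
        cds_queried=_opt_bool(row.get("cds_queried")),
        diagnoses=tuple(
            CodedDiagnosis(code=d["code"], poa=d.get("poa", "Y"), position=d.get("position", "secondary"))
            for d in row.get("diagnoses", [])
        ),
    )


def write_encounters(encounters: Iterable[Encounter], path: str | Path) -> Path:
    """Write encounters as line-JSON (``.jsonl``) or CSV by extension.

    The CSV layout packs the diagnosis list into a space-separated list of
    ``code;poa;position`` triples in the ``diagnoses`` column.
    """
    path = Path(path)
    if path.suffix == ".jsonl":
        with path.open("w") as fh:
            for e in encounters:
                fh.write(json.dumps(encounter_to_dict(e)) + "\n")
    elif path.suffix == ".csv":
        with path.open("w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
            w.writeheader()
            for e in encounters:
                row = encounter_to_dict(e)
                row["diagnoses"] = " ".join(_diag_to_str(d) for d in e.diagnoses)
                row["cds_reviewed"] = "" if e.cds_reviewed is None else str(e.cds_reviewed)
                row["cds_queried"] = "" if e.cds_queried is None else str(e.cds_queried)
                row["facility"] = e.facility or ""
                w.writerow(row)
    else:
        raise ValueError(f"unsupported encounter file extension: {path.suffix!r}")
    return path


def read_encounters(path: str | Path) -> list[Encounter]:
    """Read encounters from ``.jsonl`` or ``.csv`` written by this module."""
    path = Path(path)
    out: list[Encounter] = []
    if path.suffix == ".jsonl":
        with path.open() as fh:
            for line in fh:
                if line.strip():
                    out.append(encounter_from_dict(json.loads(line)))
    elif path.suffix == ".csv":
        with path.open(newline="") as fh:
            for row in csv.DictReader(fh):
                diags = [
                    _diag_from_str(s) for s in (row.get("diagnoses") or "").split() if s
                ]
                row = dict(row)
                row["diagnoses"] = [
                    {"code": d.code, "poa": d.poa, "position": d.position} for d in diags
                ]
                out.append(encounter_from_dict(row))
    else:
        raise ValueError(f"unsupported encounter file extension: {path.suffix!r}")
    return out
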