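"""Reference mapping tables for ICD-10-CM diagnosis codes.

Four pluggable lookup tables drive feature construction:

* **body system** — each diagnosis code belongs to one of 18 body systems
  (the HCUP-style grouping of ICD-10-CM chapters into organ systems);
* **CC/MCC** — whether CMS designates the code a Complication/Comorbidity
  (CC) or a Major CC (MCC) for payment-tier escalation;
* **Elixhauser** — membership of the code in one or more of the 30
  Elixhauser comorbidity categories;
* **POA exempt** — codes exempt from present-on-admission reporting.

The licensed HCUP/CMS contents are not shipped; only the file shapes are
fixed (simple comma-delimited tables, documented per loader) so that any
release of the real tables — or a synthetic universe — can be plugged in.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "ELIX_CATEGORIES",
    "N_BODY_SYSTEMS",
    "CCMCC",
    "ReferenceMaps",
    "ReferenceMapError",
    "normalize_code",
    "is_valid_code",
    "load_reference_maps",
]

#: Number of body systems in the diagnosis grouping.
N_BODY_SYSTEMS = 18

#: The 30 Elixhauser comorbidity categories, in fixed registry order.
#: Order is load-bearing: feature vectors and model coefficients are
#: positionally indexed by it.  Short names follow the classic comorbidity
#: software conventions (HTN = hypertension, LYTES = fluid and electrolyte
#: disorders, ANEMDEF = deficiency anemia, CHRNLUNG = chronic pulmonary
#: disease, ...).
ELIX_CATEGORIES: tuple[str, ...] = (
    "CHF",        # congestive heart failure
    "ARRHY",      # cardiac arrhythmias
    "VALVE",      # valvular disease
    "PULMCIRC",   # pulmonary circulation disorders
    "PERIVASC",   # peripheral vascular disorders
    "HTN",        # hypertension
    "PARA",       # paralysis
    "NEURO",      # other neurological disorders
    "CHRNLUNG",   # chronic pulmonary disease
    "DM",         # diabetes, uncomplicated
    "DMCX",       # diabetes, complicated
    "HYPOTHY",    # hypothyroidism
    "RENLFAIL",   # renal failure
    "LIVER",      # liver disease
    "ULCER",      # peptic ulcer disease
    "AIDS",       # AIDS / HIV
    "LYMPH",      # lymphoma
    "METS",       # metastatic cancer
    "TUMOR",      # solid tumor without metastasis
    "ARTH",       # rheumatoid arthritis / collagen vascular
    "COAG",       # coagulopathy
    "OBESE",      # obesity
    "WGHTLOSS",   # weight loss
    "LYTES",      # fluid and electrolyte disorders
    "BLDLOSS",    # blood loss anemia
    "ANEMDEF",    # deficiency anemia
    "ALCOHOL",    # alcohol abuse
    "DRUG",       # drug abuse
    "PSYCH",      # psychoses
    "DEPRESS",    # depression
)

ELIX_INDEX: dict[str, int] = {name: i for i, name in enumerate(ELIX_CATEGORIES)}

# ICD-10-CM diagnosis code, dotless form: letter, two digits, then up to
# four alphanumerics (the part after the dot in the dotted display form).
_CODE_RE = re.compile(r"^[A-Z][0-9][0-9A-Z][0-9A-Z]{0,4}$")


class CCMCC(enum.IntEnum):
    """CMS complication/comorbidity designation of a diagnosis code."""

    NONE = 0
    CC = 1
    MCC = 2


class ReferenceMapError(ValueError):
    """Raised for unrecoverable problems in a reference mapping table."""


def normalize_code(raw: str) -> str:
    """Normalize an ICD-10-CM code to canonical dotless uppercase form.

    Strips surrounding whitespace, removes the dot and uppercases, e.g.
    ``"e87.70" -> "E8770"``.  Idempotent.  Raises :class:`ValueError` if
    the result does not look like an ICD-10-CM diagnosis code.
    """
    if raw is None or not str(raw).strip():
        raise ValueError("empty diagnosis code")
    code = str(raw).strip().upper()
    if "." in code:
        head, dot, tail = code.partition(".")
        # the dotted display form has exactly one dot after the category
        if len(head) != 3 or "." in tail or not tail:
            raise ValueError(f"not a valid ICD-10-CM diagnosis code: {raw!r}")
        code = head + tail
    if not _CODE_RE.match(code):
        raise ValueError(f"not a valid ICD-10-CM diagnosis code: {raw!r}")
    return code


def is_valid_code(raw: str) -> bool:
    """True if ``raw`` normalizes to a syntactically valid code."""
    try:
        normalize_code(raw)
    except ValueError:
        return False
    return True


@dataclass(frozen=True)
class ReferenceMaps:
    """Immutable bundle of the four diagnosis-code lookup tables.

    Lookups are total: a code absent from every table resolves to
    (no body system, ``CCMCC.NONE``, empty category set, not exempt)
    and never raises.
    """

    body_system: Mapping[str, int]
    ccmcc: Mapping[str, CCMCC]
    elixhauser: Mapping[str, frozenset[str]]
    poa_exempt_codes: frozenset[str]
    version_label: str = "unversioned"
    categories: tuple[str, ...] = ELIX_CATEGORIES

    def __post_init__(self) -> None:
        if len(self.categories) != 30 or len(set(self.categories)) != 30:
            raise ReferenceMapError(
                "Elixhauser registry must hold exactly 30 unique category names"
            )
        for code, sys in self.body_system.items():
            if not _CODE_RE.match(code):
                raise ReferenceMapError(f"invalid code key in body-system map: {code!r}")
            if not 1 <= int(sys) <= N_BODY_SYSTEMS:
                raise ReferenceMapError(
                    f"body system for {code} is {sys}, outside 1..{N_BODY_SYSTEMS}"
                )
        for code in self.ccmcc:
            if not _CODE_RE.match(code):
                raise ReferenceMapError(f"invalid code key in CC/MCC map: {code!r}")
        registry = set(self.categories)
        for code, cats in self.elixhauser.items():
            if not _CODE_RE.match(code):
                raise ReferenceMapError(f"invalid code key in Elixhauser map: {code!r}")
            unknown = set(cats) - registry
            if unknown:
                raise ReferenceMapError(
                    f"code {code} maps to unknown Elixhauser categories {sorted(unknown)}"
                )
        for code in self.poa_exempt_codes:
            if not _CODE_RE.match(code):
                raise ReferenceMapError(f"invalid code in POA-exempt list: {code!r}")

    # -- total lookups -------------------------------------------------
    def body_system_of(self, code: str) -> int | None:
        return self.body_system.get(code)

    def ccmcc_of(self, code: str) -> CCMCC:
        return self.ccmcc.get(code, CCMCC.NONE)

    def elix_of(self, code: str) -> frozenset[str]:
        return self.elixhauser.get(code, frozenset())

    def poa_exempt(self, code: str) -> bool:
        return code in self.poa_exempt_codes

    @property
    def all_codes(self) -> frozenset[str]:
        """Every code mentioned in at least one table."""
        return frozenset(self.body_system) | frozenset(self.ccmcc) | frozenset(
            self.elixhauser
        ) | self.poa_exempt_codes

    # -- persistence ---------------------------------------------------
    def save(self, directory: str | Path) -> dict[str, Path]:
        """Write the four canonical delimited files into ``directory``.

        Round-trips: reloading the written files reproduces identical
        lookup behaviour for every code.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "body_systems": directory / "body_systems.csv",
            "ccmcc": directory / "ccmcc.csv",
            "elixhauser": directory / "elixhauser.csv",
            "poa_exempt": directory / "poa_exempt.csv",
        }
        with paths["body_systems"].open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["code", "body_system"])
            for code in sorted(self.body_system):
                w.writerow([code, self.body_system[code]])
        with paths["ccmcc"].open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["code", "level"])
            for code in sorted(self.ccmcc):
                if self.ccmcc[code] is not CCMCC.NONE:
                    w.writerow([code, self.ccmcc[code].name])
        with paths["elixhauser"].open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["code", "category"])
            for code in sorted(self.elixhauser):
                for cat in sorted(self.elixhauser[code]):
                    w.writerow([code, cat])
        with paths["poa_exempt"].open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["code"])
            for code in sorted(self.poa_exempt_codes):
                w.writerow([code])
        return paths


def _read_rows(path: Path, n_cols: int) -> Iterable[tuple[int, list[str]]]:
    """Yield (line_number, fields) skipping blank lines and a header row."""
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            fields = [f.strip() for f in row]
            if not any(fields):
                continue
            # tolerate an optional header: first row whose code column is
            # not a plausible code
            if lineno == 1 and not is_valid_code(fields[0]):
                continue
            if len(fields) < n_cols:
                raise ReferenceMapError(
                    f"{path.name}:{lineno}: expected {n_cols} columns, got {len(fields)}"
                )
            yield lineno, fields[:n_cols]


def _load_single_valued(
    path: Path, parse_value, errors: list[str]
) -> dict[str, object]:
    """Load a (code, value) table; dedupe identical rows, reject conflicts."""
    out: dict[str, object] = {}
    conflicts: list[str] = []
    for lineno, (raw_code, raw_value) in _read_rows(path, 2):
        try:
            code = normalize_code(raw_code)
        except ValueError as exc:
            errors.append(f"{path.name}:{lineno}: {exc}")
            continue
        value = parse_value(raw_value, f"{path.name}:{lineno}")
        if code in out and out[code] != value:
            conflicts.append(code)
        out[code] = value
    if conflicts:
        raise ReferenceMapError(
            f"{path.name}: conflicting duplicate rows for codes "
            f"{sorted(set(conflicts))}"
        )
    return out


def load_reference_maps(
    body_systems_path: str | Path,
    ccmcc_path: str | Path,
    elixhauser_path: str | Path,
    poa_exempt_path: str | Path,
    *,
    version_label: str = "unversioned",
    categories: tuple[str, ...] = ELIX_CATEGORIES,
    strict: bool = True,
) -> ReferenceMaps:
    """Load the four canonical mapping files into a :class:`ReferenceMaps`.

    File layouts (comma-delimited, UTF-8, optional header row; codes may be
    dotted or dotless):

    * ``body_systems.csv`` — columns ``code,body_system`` with body_system
      an integer in 1..18;
    * ``ccmcc.csv`` — columns ``code,level`` with level ``CC`` or ``MCC``;
    * ``elixhauser.csv`` — columns ``code,category``; a code may appear on
      several rows for different categories;
    * ``poa_exempt.csv`` — single column ``code``.

    Duplicate identical rows are deduplicated; duplicates that conflict
    (same code, different value) abort the load.  Rows with malformed codes
    are collected with their line numbers and, under ``strict`` (default),
    abort the load; otherwise they are skipped.
    """
    for p in (body_systems_path, ccmcc_path, elixhauser_path, poa_exempt_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"reference mapping file not found: {p}")
    row_errors: list[str] = []

    def parse_system(raw: str, where: str) -> int:
        try:
            value = int(raw)
        except ValueError:
            raise ReferenceMapError(f"{where}: body system {raw!r} is not an integer")
        if not 1 <= value <= N_BODY_SYSTEMS:
            raise ReferenceMapError(
                f"{where}: body system {value} outside 1..{N_BODY_SYSTEMS}"
            )
        return value

    def parse_level(raw: str, where: str) -> CCMCC:
        name = raw.strip().upper()
        if name not in ("CC", "MCC"):
            raise ReferenceMapError(f"{where}: CC/MCC level must be CC or MCC, got {raw!r}")
        return CCMCC[name]

    body_system = _load_single_valued(Path(body_systems_path), parse_system, row_errors)
    ccmcc = _load_single_valued(Path(ccmcc_path), parse_level, row_errors)

    registry = set(categories)
    elix: dict[str, set[str]] = {}
    for lineno, (raw_code, raw_cat) in _read_rows(Path(elixhauser_path), 2):
        try:
            code = normalize_code(raw_code)
        except ValueError as exc:
            row_errors.append(f"{Path(elixhauser_path).name}:{lineno}: {exc}")
            continue
        cat = raw_cat.strip().upper()
        if cat not in registry:
            raise ReferenceMapError(
                f"{Path(elixhauser_path).name}:{lineno}: unknown Elixhauser "
                f"category {raw_cat!r}"
            )
        elix.setdefault(code, set()).add(cat)

    exempt: set[str] = set()
    for lineno, (raw_code,) in _read_rows(Path(poa_exempt_path), 1):
        try:
            exempt.add(normalize_code(raw_code))
        except ValueError as exc:
            row_errors.append(f"{Path(poa_exempt_path).name}:{lineno}: {exc}")

    if row_errors and strict:
        raise ReferenceMapError(
            "malformed rows in reference maps:\n  " + "\n  ".join(row_errors)
        )

    return ReferenceMaps(
        body_system=body_system,
        ccmcc=ccmcc,
        elixhauser={c: frozenset(v) for c, v in elix.items()},
        poa_exempt_codes=frozenset(exempt),
        version_label=version_label,
        categories=tuple(categories),
    )
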