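"""Per-encounter severity scores and benchmarking / CDI analytics.

``score_encounters`` applies a fitted admission-phase model and a fitted
discharge-phase model (same variant) to every encounter, yielding one
:class:`JScoreRecord` with

* ``j_score_poa`` — probability of high severity from present-on-admission
  and POA-exempt diagnoses only (admission severity), and
* ``j_score`` — probability from all coded diagnoses (discharge severity),

plus the predicted high/low classes at the stored cutoffs.  The analytic
reports (score distribution, monthly trend, CDI group comparison,
per-facility high-severity proportions) consume only the scored records,
so every statistic is reproducible from the scored file alone.

The per-encounter gap ``j_score - j_score_poa`` measures severity acquired
or documented after admission; averaged within clinical-documentation
review groups it quantifies how much comorbidity capture the CDI process
adds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from jscore.codes import ReferenceMaps
from jscore.features import (
    POA_PRESENT_DEFAULT,
    Encounter,
    binarize_outcome,
    build_features,
)
from jscore.model import SeverityResults

__all__ = [
    "JScoreRecord",
    "score_encounters",
    "write_records",
    "read_records",
    "score_distribution",
    "bimodality_coefficient",
    "trend_report",
    "group_comparison",
    "high_severity_proportion",
]

#: A displayed "score of 1": any probability rounding to 1.00 at two
#: decimals, i.e. >= 0.995.  (A logistic probability never equals 1.)
SATURATION_THRESHOLD = 0.995


@dataclass(frozen=True)
class JScoreRecord:
    """Scored encounter: admission and discharge severity probabilities."""

    encounter_id: str
    j_score_poa: float
    j_score: float
    predicted_class_poa: Literal["low", "high"]
    predicted_class: Literal["low", "high"]
    facility: str | None = None
    discharge_month: str | None = None
    cds_reviewed: bool | None = None
    cds_queried: bool | None = None
    admit_soi: int | None = None
    discharge_soi: int | None = None

    def __post_init__(self) -> None:
        for name in ("j_score_poa", "j_score"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside the open interval (0, 1)")


def score_encounters(
    results_poa: SeverityResults,
    results_discharge: SeverityResults,
    maps: ReferenceMaps,
    encounters: Sequence[Encounter],
    *,
    cutoff_poa: float = 0.5,
    cutoff: float = 0.5,
    poa_present: frozenset[str] = POA_PRESENT_DEFAULT,
) -> list[JScoreRecord]:
    """Score every encounter with both phase models.

    Both models must share a variant.  An encounter whose codes are all
    POA gets identical features for both phases and (if the two models
    were fitted on the same data-generating process) typically similar
    scores; an encounter with no diagnoses scores at each model's
    intercept-only probability.
    """
    if results_poa.variant != results_discharge.variant:
        raise ValueError(
            f"phase models disagree on variant: {results_poa.variant!r} vs "
            f"{results_discharge.variant!r}"
        )
    for name, c in (("cutoff_poa", cutoff_poa), ("cutoff", cutoff)):
        if not np.isfinite(c):
            raise ValueError(f"{name} must be finite")
    records: list[JScoreRecord] = []
    for e in encounters:
        f_adm = build_features(e, maps, "admission", poa_present=poa_present)
        f_dis = build_features(e, maps, "discharge", poa_present=poa_present)
        p_adm = results_poa.predict(f_adm)
        p_dis = results_discharge.predict(f_dis)
        records.append(
            JScoreRecord(
                encounter_id=e.encounter_id,
                j_score_poa=p_adm,
                j_score=p_dis,
                predicted_class_poa="high" if p_adm >= cutoff_poa else "low",
                predicted_class="high" if p_dis >= cutoff else "low",
                facility=e.facility,
                discharge_month=e.discharge_month,
                cds_reviewed=e.cds_reviewed,
                cds_queried=e.cds_queried,
                admit_soi=e.admit_soi,
                discharge_soi=e.discharge_soi,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Record file I/O (delimited text, one row per encounter)
# ---------------------------------------------------------------------------

_RECORD_FIELDS = [
    "encounter_id",
    "j_score_poa",
    "j_score",
    "predicted_class_poa",
    "predicted_class",
    "facility",
    "discharge_month",
    "cds_reviewed",
    "cds_queried",
    "admit_soi",
    "discharge_soi",
]


def write_records(records: Iterable[JScoreRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_RECORD_FIELDS)
        for r in records:
            w.writerow(
                [
                    r.encounter_id,
                    repr(r.j_score_poa),
                    repr(r.j_score),
                    r.predicted_class_poa,
                    r.predicted_class,
                    r.facility or "",
                    r.discharge_month or "",
                    "" if r.cds_reviewed is None else str(r.cds_reviewed),
                    "" if r.cds_queried is None else str(r.cds_queried),
                    "" if r.admit_soi is None else r.admit_soi,
                    "" if r.discharge_soi is None else r.discharge_soi,
                ]
            )
    return path


def read_records(path: str | Path) -> list[JScoreRecord]:
    def opt_bool(s: str):
        return None if s == "" else s == "True"

    out: list[JScoreRecord] = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                JScoreRecord(
                    encounter_id=row["encounter_id"],
                    j_score_poa=float(row["j_score_poa"]),
                    j_score=float(row["j_score"]),
                    predicted_class_poa=row["predicted_class_poa"],  # type: ignore[arg-type]
                    predicted_class=row["predicted_class"],  # type: ignore[arg-type]
                    facility=row["facility"] or None,
                    discharge_month=row["discharge_month"] or None,
                    cds_reviewed=opt_bool(row["cds_reviewed"]),
                    cds_queried=opt_bool(row["cds_queried"]),
                    admit_soi=int(row["admit_soi"]) if row["admit_soi"] else None,
                    discharge_soi=int(row["discharge_soi"]) if row["discharge_soi"] else None,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Analytics
# ---------------------------------------------------------------------------


def score_distribution(
    records: Sequence[JScoreRecord],
    *,
    bin_width: float = 0.01,
    saturation_threshold: float = SATURATION_THRESHOLD,
) -> dict:
    """Histogram summary of both scores plus saturation proportions.

    Scores at or above ``saturation_threshold`` display as 1.00 at
    two-decimal rounding and are reported as the proportion "at 1".
    Bin counts conserve the record count.
    """
    if not records:
        raise ValueError("need at least one scored record")
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    edges[-1] = 1.0
    out: dict = {"bin_edges": edges.tolist(), "n": len(records)}
    for key in ("j_score_poa", "j_score"):
        values = np.array([getattr(r, key) for r in records])
        counts, _ = np.histogram(values, bins=edges)
        out[key] = {
            "counts": counts.tolist(),
            "proportion_at_one": float((values >= saturation_threshold).mean()),
            "mean": float(values.mean()),
        }
    return out


def bimodality_coefficient(values) -> float:
    """Sarle's bimodality coefficient b = (g1^2 + 1) / (g2 + 3(n-1)^2/((n-2)(n-3))).

    Values above ~0.555 (the uniform distribution's coefficient) suggest
    bimodality; a two-point mass at the interval ends approaches 1.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("bimodality coefficient needs at least 4 values")
    from scipy.stats import kurtosis, skew

    g1 = skew(x, bias=False)
    g2 = kurtosis(x, fisher=True, bias=False)
    return float((g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def trend_report(records: Sequence[JScoreRecord]) -> dict[str, dict[str, float]]:
    """Per-discharge-month means of both scores and their gap.

    The gap (mean j_score - mean j_score_poa) tracks severity identified
    after admission ("non-POA capture").  Records without a discharge
    month are skipped with a warning.
    """
    import warnings

    groups: dict[str, list[JScoreRecord]] = {}
    skipped = 0
    for r in records:
        if r.discharge_month is None:
            skipped += 1
            continue
        groups.setdefault(r.discharge_month, []).append(r)
    if skipped:
        warnings.warn(f"{skipped} records without discharge_month skipped", stacklevel=2)
    report: dict[str, dict[str, float]] = {}
    for month in sorted(groups):
        rs = groups[month]
        mean_poa = float(np.mean([r.j_score_poa for r in rs]))
        mean_dis = float(np.mean([r.j_score for r in rs]))
        report[month] = {
            "n": len(rs),
            "mean_j_score_poa": mean_poa,
            "mean_j_score": mean_dis,
            "gap": mean_dis - mean_poa,
        }
    return report


def group_comparison(
    records: Sequence[JScoreRecord],
    group_field: Literal["cds_reviewed", "cds_queried"],
) -> dict[str, dict[str, float]]:
    """Mean scores and within-group gap by CDI review/query status.

    Groups with zero members are reported as absent.  A CDI process that
    targets high-admission-severity cases and documents additional
    non-POA complications shows a larger gap in the reviewed group.
    """
    if group_field not in ("cds_reviewed", "cds_queried"):
        raise ValueError(f"unsupported group field {group_field!r}")
    groups: dict[str, list[JScoreRecord]] = {}
    for r in records:
        flag = getattr(r, group_field)
        if flag is None:
            continue
        groups.setdefault("yes" if flag else "no", []).append(r)
    report: dict[str, dict[str, float]] = {}
    for name in sorted(groups):
        rs = groups[name]
        mean_poa = float(np.mean([r.j_score_poa for r in rs]))
        mean_dis = float(np.mean([r.j_score for r in rs]))
        report[name] = {
            "n": len(rs),
            "mean_j_score_poa": mean_poa,
            "mean_j_score": mean_dis,
            "gap": mean_dis - mean_poa,
        }
    return report


def high_severity_proportion(
    records: Sequence[JScoreRecord],
    *,
    phase: Literal["admission", "discharge"] = "admission",
) -> dict[str, dict[str, float]]:
    """Per-facility proportion of predicted-high cases, for benchmarking.

    When the records carry observed SOI levels, the observed proportion
    of SOI >= 3 is reported alongside for a side-by-side comparison of
    model-based and grouper-based severity rates.
    """
    pred_field = "predicted_class_poa" if phase == "admission" else "predicted_class"
    soi_field = "admit_soi" if phase == "admission" else "discharge_soi"
    groups: dict[str, list[JScoreRecord]] = {}
    for r in records:
        groups.setdefault(r.facility or "(none)", []).append(r)
    report: dict[str, dict[str, float]] = {}
    for facility in sorted(groups):
        rs = groups[facility]
        entry: dict[str, float] = {
            "n": len(rs),
            "predicted_high": float(
                np.mean([getattr(r, pred_field) == "high" for r in rs])
            ),
        }
        sois = [getattr(r, soi_field) for r in rs if getattr(r, soi_field) is not None]
        if sois:
            entry["observed_high"] = float(
                np.mean([binarize_outcome(s) for s in sois])
            )
        report[facility] = entry
    return report
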