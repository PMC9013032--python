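"""Synthetic code universe, encounters, and CDI process with known truth.

Real severity-score development uses licensed reference tables and a
proprietary clinical database; this module stands in for both with a
fully synthetic study whose ground truth is known, so that every other
module can be exercised and checked end-to-end:

* a code universe in which each code carries one body system (1-18), a
  CC/MCC designation with configurable fractions, zero or more Elixhauser
  categories, and possibly POA-reporting exemption;
* encounters whose binary high-severity labels are drawn from a known
  logistic model on the constructed discharge features, with POA flags
  making admission features a stochastic subset of discharge features;
* an optional clinical-documentation-improvement (CDI) process that
  selects high-admission-severity cases for review and documents extra
  non-POA CC/MCC codes on them.

Everything is deterministic under the configured seed.  The synthetic
codes satisfy ICD-10-CM syntax but carry no clinical meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from jscore.codes import CCMCC, ELIX_CATEGORIES, N_BODY_SYSTEMS, ReferenceMaps
from jscore.contrasts import ContrastDesign, Variant, design_matrix
from jscore.features import CodedDiagnosis, Encounter, build_features

__all__ = [
    "SimulationConfig",
    "generate_reference_maps",
    "generate_encounters",
    "generate_cdi_process",
    "write_truth",
    "read_truth",
]


def _default_elix_attach() -> tuple[float, ...]:
    # per-code attachment probability per category, declining geometrically
    # from 3% to 0.3%; with ~9 codes per encounter this yields encounter
    # prevalences of roughly 20-25% for the leading categories down to ~3%,
    # the order of magnitude seen in adult inpatient cohorts
    return tuple(0.03 * (0.1 ** (i / 29)) for i in range(30))


def _default_coefficients(variant: Variant) -> tuple[float, ...]:
    """True coefficients on the contrast basis.

    Body-system linear terms rise from 0.5 to 1.5 across systems with a
    small positive quadratic component; Elixhauser terms (when the
    variant uses them) decline from 0.5 to 0.05, so comorbidity carries a
    real but weaker signal than the body-system CC/MCC indicators.
    """
    design = ContrastDesign(variant)
    parts: list[float] = []
    if design.uses_body_systems:
        for s in range(N_BODY_SYSTEMS):
            parts.append(0.5 + 1.0 * s / (N_BODY_SYSTEMS - 1))  # linear
            parts.append(0.15)  # quadratic
    if design.uses_elixhauser:
        parts.extend(0.5 - 0.45 * i / 29 for i in range(30))
    return tuple(parts)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    ``true_intercept=None`` calibrates the intercept on the generated
    cohort so the mean true probability of high severity equals
    ``target_high_fraction`` (default 40%, a typical adult inpatient
    high-severity rate at large academic centers).
    """

    seed: int = 0
    n_encounters: int = 10_000
    codes_per_system: int = 40
    cc_fraction: float = 0.20
    mcc_fraction: float = 0.10
    elix_attach_prob: tuple[float, ...] = field(default_factory=_default_elix_attach)
    poa_exempt_fraction: float = 0.05
    mean_diagnoses: float = 9.0
    poa_probability: float = 0.90
    # severe complications acquired during the stay are mostly surfaced by
    # the CDI process below, so spontaneously coded CC/MCC diagnoses are
    # present on admission more often than routine ones
    poa_probability_ccmcc: float = 0.97
    variant: Variant = "body_system"
    true_intercept: float | None = None
    target_high_fraction: float = 0.40
    true_coefficients: tuple[float, ...] | None = None
    n_facilities: int = 6
    months: tuple[str, ...] = tuple(
        f"{y}-{m:02d}" for y in (2018, 2019) for m in range(1, 13)
    )
    # CDI process
    cdi_review_threshold: float = 0.50
    cdi_augment_intensity: float = 3.0
    cdi_query_fraction: float = 0.5

    def __post_init__(self) -> None:
        probs = (
            self.cc_fraction,
            self.mcc_fraction,
            self.poa_exempt_fraction,
            self.poa_probability,
            self.poa_probability_ccmcc,
            self.target_high_fraction,
            self.cdi_query_fraction,
            *self.elix_attach_prob,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.cc_fraction + self.mcc_fraction > 1.0:
            raise ValueError("cc_fraction + mcc_fraction must not exceed 1")
        if len(self.elix_attach_prob) != 30:
            raise ValueError("elix_attach_prob must have length 30")
        coefs = self.coefficients
        width = ContrastDesign(self.variant).n_columns
        if len(coefs) != width:
            raise ValueError(
                f"true_coefficients has length {len(coefs)}, variant "
                f"{self.variant!r} needs {width}"
            )

    @property
    def coefficients(self) -> tuple[float, ...]:
        if self.true_coefficients is not None:
            return tuple(self.true_coefficients)
        return _default_coefficients(self.variant)

    def _seeds(self) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return [np.random.default_rng(c) for c in children]


def _code_name(system: int, j: int) -> str:
    # letter encodes the body system (A..R for 1..18); digits keep ICD
    # syntax: letter + two digits + up to four more characters
    return f"{chr(ord('A') + system - 1)}{system - 1:02d}{j:04d}"


def generate_reference_maps(config: SimulationConfig) -> ReferenceMaps:
    """Build the synthetic code universe and its four lookup tables."""
    rng = config._seeds()[0]
    body_system: dict[str, int] = {}
    ccmcc: dict[str, CCMCC] = {}
    elix: dict[str, frozenset[str]] = {}
    exempt: set[str] = set()
    attach = np.asarray(config.elix_attach_prob)
    for system in range(1, N_BODY_SYSTEMS + 1):
        for j in range(config.codes_per_system):
            code = _code_name(system, j)
            body_system[code] = system
            u = rng.random()
            if u < config.mcc_fraction:
                ccmcc[code] = CCMCC.MCC
            elif u < config.mcc_fraction + config.cc_fraction:
                ccmcc[code] = CCMCC.CC
            cats = frozenset(
                cat for cat, p in zip(ELIX_CATEGORIES, attach) if rng.random() < p
            )
            if cats:
                elix[code] = cats
            if rng.random() < config.poa_exempt_fraction:
                exempt.add(code)
    return ReferenceMaps(
        body_system=body_system,
        ccmcc=ccmcc,
        elixhauser=elix,
        poa_exempt_codes=frozenset(exempt),
        version_label=f"synthetic-seed{config.seed}",
    )


_RACES = ("White", "Black", "Hispanic", "Asian", "Other")
_RACE_P = (0.60, 0.15, 0.12, 0.06, 0.07)


def _draw_poa(rng: np.random.Generator, present: bool) -> str:
    # present-on-admission codes are mostly flagged Y with a few W
    # (clinically undetermined); absent ones mostly N with a few U
    if present:
        return "Y" if rng.random() < 0.95 else "W"
    return "N" if rng.random() < 0.90 else "U"


def generate_encounters(
    config: SimulationConfig, maps: ReferenceMaps
) -> tuple[list[Encounter], "pandas.DataFrame"]:
    """Draw the synthetic cohort and its latent truth.

    Per encounter: a diagnosis set is drawn, POA flags assigned, the TRUE
    discharge features built, the true probability of high severity
    computed from the configured logistic model, the binary label drawn,
    and the label cosmetically refined to a 4-level SOI (high -> 3 or 4,
    low -> 1 or 2, uniformly).  The admission SOI follows the same model
    applied to the admission features.  Returns the encounters plus a
    truth table (true probabilities, labels, linear predictors) for
    recovery tests.
    """
    import pandas as pd

    rng = config._seeds()[1]
    universe = sorted(maps.body_system)
    n_codes = len(universe)
    design = ContrastDesign(config.variant)
    coefs = np.asarray(config.coefficients)

    raw: list[dict] = []
    feats_dis = []
    feats_adm = []
    for i in range(config.n_encounters):
        n_dx = min(1 + rng.poisson(max(config.mean_diagnoses - 1.0, 0.0)), n_codes)
        idx = rng.choice(n_codes, size=n_dx, replace=False)
        diagnoses = []
        for k, ci in enumerate(idx):
            code = universe[ci]
            p_present = (
                config.poa_probability_ccmcc
                if maps.ccmcc_of(code) is not CCMCC.NONE
                else config.poa_probability
            )
            present = bool(rng.random() < p_present)
            poa = "1" if maps.poa_exempt(code) else _draw_poa(rng, present)
            diagnoses.append(
                CodedDiagnosis(
                    code=code,
                    poa=poa,
                    position="principal" if k == 0 else "secondary",
                )
            )
        raw.append(
            {
                "encounter_id": f"E{i:07d}",
                "age": int(rng.integers(18, 95)),
                "sex": "F" if rng.random() < 0.55 else "M",
                "race": _RACES[rng.choice(len(_RACES), p=_RACE_P)],
                "discharge_month": config.months[rng.integers(len(config.months))],
                "facility": f"F{rng.integers(config.n_facilities) + 1:02d}",
                "diagnoses": tuple(diagnoses),
            }
        )

    # true features and linear predictors (vectorized over the cohort)
    shell = [
        Encounter(
            encounter_id=r["encounter_id"],
            age=r["age"],
            sex=r["sex"],
            race=r["race"],
            discharge_month=r["discharge_month"],
            admit_soi=1,
            discharge_soi=1,
            facility=r["facility"],
            diagnoses=r["diagnoses"],
        )
        for r in raw
    ]
    feats_dis = [build_features(e, maps, "discharge") for e in shell]
    feats_adm = [build_features(e, maps, "admission") for e in shell]
    lp_dis = design_matrix(feats_dis, config.variant) @ coefs
    lp_adm = design_matrix(feats_adm, config.variant) @ coefs

    if config.true_intercept is None:
        intercept = _calibrate_intercept(lp_dis, config.target_high_fraction)
    else:
        intercept = float(config.true_intercept)
    p_dis = expit(intercept + lp_dis)
    p_adm = expit(intercept + lp_adm)
    label_dis = (rng.random(config.n_encounters) < p_dis).astype(int)
    label_adm = (rng.random(config.n_encounters) < p_adm).astype(int)
    soi_detail = rng.integers(0, 2, size=(config.n_encounters, 2))
    soi_dis = np.where(label_dis == 1, 3 + soi_detail[:, 0], 1 + soi_detail[:, 0])
    soi_adm = np.where(label_adm == 1, 3 + soi_detail[:, 1], 1 + soi_detail[:, 1])

    encounters = [
        replace(e, admit_soi=int(sa), discharge_soi=int(sd))
        for e, sa, sd in zip(shell, soi_adm, soi_dis)
    ]
    truth = pd.DataFrame(
        {
            "encounter_id": [e.encounter_id for e in encounters],
            "true_intercept": intercept,
            "lp_discharge": lp_dis,
            "lp_admission": lp_adm,
            "p_discharge": p_dis,
            "p_admission": p_adm,
            "label_discharge": label_dis,
            "label_admission": label_adm,
        }
    )
    return encounters, truth


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept making the cohort mean true probability equal ``target``."""

    def deficit(c: float) -> float:
        return float(expit(c + lp).mean() - target)

    return float(brentq(deficit, -40.0, 40.0, xtol=1e-10))


def generate_cdi_process(
    encounters: Sequence[Encounter],
    truth,
    config: SimulationConfig,
    maps: ReferenceMaps,
) -> list[Encounter]:
    """Apply the synthetic CDI review/query process.

    Encounters whose latent admission probability exceeds the review
    threshold are marked reviewed (a fraction of those also queried); for
    reviewed encounters a Poisson number of extra CC/MCC codes are
    documented with POA flag N (found during the stay).  With
    ``cdi_augment_intensity=0`` the process is a pure labelling with no
    augmentation.

    Because the discharge severity level is assigned from the *final*
    coded record, augmented encounters get their discharge SOI redrawn
    from the post-augmentation true probability; the truth table is
    updated in place (``lp_discharge``, ``p_discharge``,
    ``label_discharge``) to stay consistent with the returned encounters.
    """
    rng = config._seeds()[2]
    p_adm = np.asarray(truth["p_admission"], dtype=float)
    if len(p_adm) != len(encounters):
        raise ValueError("truth table and encounter list lengths differ")
    # injected codes must act only on discharge features, so the pool
    # excludes POA-exempt codes (those count toward admission regardless
    # of their flag)
    cc_pool = sorted(
        c
        for c in maps.ccmcc
        if maps.ccmcc_of(c) is not CCMCC.NONE and not maps.poa_exempt(c)
    )
    out: list[Encounter] = []
    for e, p in zip(encounters, p_adm):
        reviewed = bool(p > config.cdi_review_threshold)
        queried = reviewed and bool(rng.random() < config.cdi_query_fraction)
        diagnoses = e.diagnoses
        if reviewed and config.cdi_augment_intensity > 0 and cc_pool:
            n_extra = int(rng.poisson(config.cdi_augment_intensity))
            have = {d.code for d in diagnoses}
            candidates = [c for c in cc_pool if c not in have]
            if n_extra and candidates:
                picks = rng.choice(
                    len(candidates), size=min(n_extra, len(candidates)), replace=False
                )
                extra = tuple(
                    CodedDiagnosis(code=candidates[i], poa="N", position="secondary")
                    for i in picks
                )
                diagnoses = diagnoses + extra
        out.append(
            replace(e, diagnoses=diagnoses, cds_reviewed=reviewed, cds_queried=queried)
        )

    augmented = [
        i for i, (a, b) in enumerate(zip(encounters, out)) if len(b.diagnoses) > len(a.diagnoses)
    ]
    if augmented:
        intercept = float(truth["true_intercept"].iloc[0])
        coefs = np.asarray(config.coefficients)
        feats = [build_features(out[i], maps, "discharge") for i in augmented]
        lp_new = design_matrix(feats, config.variant) @ coefs
        p_new = expit(intercept + lp_new)
        label_new = (rng.random(len(augmented)) < p_new).astype(int)
        detail = rng.integers(0, 2, size=len(augmented))
        for j, i in enumerate(augmented):
            soi = int((3 if label_new[j] else 1) + detail[j])
            out[i] = replace(out[i], discharge_soi=soi)
            truth.loc[i, "lp_discharge"] = lp_new[j]
            truth.loc[i, "p_discharge"] = p_new[j]
            truth.loc[i, "label_discharge"] = label_new[j]
    return out


def write_truth(truth, path: str | Path) -> Path:
    """Write the latent truth table as CSV (documented delimited format)."""
    path = Path(path)
    truth.to_csv(path, index=False)
    return path


def read_truth(path: str | Path):
    import pandas as pd

    return pd.read_csv(path)
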