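import numpy as np
import pytest

from jscore.codes import CCMCC, ReferenceMaps
from jscore.features import CodedDiagnosis, Encounter
from jscore.synthetic import (
    SimulationConfig,
    generate_encounters,
    generate_reference_maps,
)


@pytest.fixture(scope="session")
def tiny_maps() -> ReferenceMaps:
    """Hand-written code universe: a handful of codes across a few systems.

    I10 -> system 7 (HTN, no CC); E8770 -> system 3 (LYTES, CC);
    J9601 -> system 10 (MCC); K2900 -> system 5; Z3800 POA-exempt.
    """
    return ReferenceMaps(
        body_system={
            "I10": 7,
            "E8770": 3,
            "J9601": 10,
            "K2900": 5,
            "N179": 12,
            "Z3800": 16,
        },
        ccmcc={"E8770": CCMCC.CC, "J9601": CCMCC.MCC, "N179": CCMCC.CC},
        elixhauser={
            "I10": frozenset({"HTN"}),
            "E8770": frozenset({"LYTES"}),
            "N179": frozenset({"RENLFAIL"}),
        },
        poa_exempt_codes=frozenset({"Z3800"}),
        version_label="tiny-fixture",
    )


def make_encounter(diagnoses, *, encounter_id="E1", admit_soi=1, discharge_soi=3, **kw):
    """Build a valid encounter around a diagnosis list.

    ``diagnoses`` is a list of (code, poa) or (code, poa, position)
    tuples; the first diagnosis is principal unless positions are given.
    """
    built = []
    for i, d in enumerate(diagnoses):
        if len(d) == 2:
            code, poa = d
            position = "principal" if i == 0 else "secondary"
        else:
            code, poa, position = d
        built.append(CodedDiagnosis(code=code, poa=poa, position=position))
    defaults = dict(
        age=60,
        sex="F",
        race="White",
        discharge_month="2019-03",
        admit_soi=admit_soi,
        discharge_soi=discharge_soi,
    )
    defaults.update(kw)
    return Encounter(encounter_id=encounter_id, diagnoses=tuple(built), **defaults)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=2024, n_encounters=2000)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(maps, encounters, truth) for a 2000-encounter synthetic cohort."""
    maps = generate_reference_maps(small_config)
    encounters, truth = generate_encounters(small_config, maps)
    return maps, encounters, truth


def random_encounter(rng: np.random.Generator, codes: list[str], i: int = 0) -> Encounter:
    """Random encounter over a given code universe (for property tests)."""
    n_dx = int(rng.integers(0, 8))
    diagnoses = []
    picks = rng.choice(len(codes), size=min(n_dx, len(codes)), replace=False)
    for k, ci in enumerate(picks):
        poa = rng.choice(["Y", "N", "U", "W", "1"], p=[0.6, 0.2, 0.05, 0.05, 0.1])
        diagnoses.append(
            CodedDiagnosis(
                code=codes[ci],
                poa=str(poa),
                position="principal" if k == 0 else "secondary",
            )
        )
    return Encounter(
        encounter_id=f"R{i}",
        age=int(rng.integers(18, 95)),
        sex="M",
        race="Other",
        discharge_month="2018-07",
        admit_soi=int(rng.integers(1, 5)),
        discharge_soi=int(rng.integers(1, 5)),
        diagnoses=tuple(diagnoses),
    )
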