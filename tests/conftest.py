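"""Shared fixtures: all cohorts are generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from embryosig.schema import (
    CONVENTIONAL,
    FEATURE_NAMES,
    ICSI,
    CohortTable,
)
from embryosig.simulate import (
    SimulationConfig,
    default_planted_rules,
    generate_cohort,
)

#: a fully consistent ICSI record; tests override single fields to probe
#: individual invariants
BASE_RECORD = {
    "embryo_id": "E0001",
    "patient_id": "P001",
    "label": "BL",
    "age": 34.0,
    "bmi": 23.5,
    "day3_fsh": 6.8,
    "amh": 3.1,
    "afc": 14,
    "infertility_years": 2.5,
    "total_fsh": 2000.0,
    "peak_e2": 2100.0,
    "osi": 5.0,
    "n_cocs": 10,
    "n_mature": 8,
    "n_fertilized": 6,
    "n_cleaved": 5,
    "maturation_rate": 0.8,
    "fertilization_rate": 0.75,
    "cleavage_rate": 5 / 6,
    "insemination": ICSI,
    "imcs": 7.5,
    "tPNa": 7.0,
    "tPNf": 24.0,
    "t2": 26.5,
    "t3": 36.5,
    "t4": 38.5,
    "t8": 56.0,
    "tPNf_tPNa": 17.0,
    "t2_tPNf": 2.5,
    "t3_t2": 10.0,
    "t4_t3": 2.0,
    "t4_t2": 12.0,
    "t8_t4": 17.5,
}


def make_record(**overrides) -> dict:
    rec = dict(BASE_RECORD)
    rec.update(overrides)
    return rec


def make_conventional(**overrides) -> dict:
    base = {"insemination": CONVENTIONAL, "tPNa": np.nan, "tPNf_tPNa": np.nan}
    base.update(overrides)
    return make_record(**base)


def make_cohort(records: list[dict]) -> CohortTable:
    return CohortTable(pd.DataFrame(records))


@pytest.fixture
def tiny_cohort() -> CohortTable:
    """Three well-formed embryos, two patients, both insemination routes."""
    return make_cohort(
        [
            make_record(embryo_id="E1", patient_id="P1", label="BL"),
            make_record(embryo_id="E2", patient_id="P1", label="nBL", imcs=5.0,
                        t4=40.0, t4_t3=3.5, t4_t2=13.5, t8_t4=16.0),
            make_conventional(embryo_id="E3", patient_id="P2", label="nBL"),
        ]
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """A small planted cohort shared by the recovery-style unit tests."""
    cfg = SimulationConfig(
        n_patients=60,
        n_embryos=400,
        planted_rules=default_planted_rules(),
        label_noise=0.05,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_single_rule_cohort():
    """Labels exactly equal to one rule's firing indicator."""
    rules = (default_planted_rules()[0][0], float("inf"))
    cfg = SimulationConfig(
        n_patients=40, n_embryos=300, planted_rules=(rules,), label_noise=0.0, seed=5
    )
    return generate_cohort(cfg)
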