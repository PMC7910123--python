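import logging
import warnings

import numpy as np
import pytest

from rnnlr.impute import ImputerConfig
from rnnlr.model import ModelConfig
from rnnlr.schema import ClinicalRecord, Cohort, PatientHistory, default_panel
from rnnlr.simulate import SimConfig, generate_cohort

logging.disable(logging.INFO)
warnings.filterwarnings("ignore", category=UserWarning)

#: Study conditions for the stochastic property checks: a prevalence with
#: enough minority cases that one-vs-all AUC estimates are stable at the
#: cohort sizes used (see docs/methods.md).
PROPERTY_PREVALENCE = (0.70, 0.12, 0.18)


@pytest.fixture(scope="session")
def small_cohort():
    cohort, truth = generate_cohort(SimConfig(
        n_patients=120, prevalence=PROPERTY_PREVALENCE, missing_rate=0.10,
        seed=11))
    return cohort, truth


@pytest.fixture(scope="session")
def medium_cohort():
    cohort, truth = generate_cohort(SimConfig(
        n_patients=800, prevalence=PROPERTY_PREVALENCE, missing_rate=0.10,
        seed=5))
    return cohort, truth


@pytest.fixture()
def panel():
    return default_panel()


def make_patient(pid="P0", n_records=2, outcome="neither", age=60, labs=None,
                 days=None, panel=None):
    """Hand-built minimal patient for schema-level tests."""
    panel = panel or default_panel()
    days = days if days is not None else list(range(n_records))
    records = []
    for d in days:
        rl = dict(labs) if labs else {"albumin": 3.0, "creatinine": 1.0}
        records.append(ClinicalRecord(d, rl))
    return PatientHistory(
        patient_id=pid, inpatient_id=f"I{pid}", sex=0, age=age, dgtm=2,
        comorbidities=frozenset({"diabetes"}), operation_category=1,
        pneumonia=False, uti=False, ssi=False, records=records,
        outcome=outcome)


@pytest.fixture()
def tiny_cohort(panel):
    patients = [make_patient("P0", 1, "neither"),
                make_patient("P1", 2, "AHE"),
                make_patient("P2", 3, "HRS")]
    return Cohort(patients, panel)


def quick_model_config(**kw):
    defaults = dict(epochs=10, batch_size=64, seed=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


def quick_imputer_config(**kw):
    defaults = dict(epochs=60, seed=0)
    defaults.update(kw)
    return ImputerConfig(**defaults)
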