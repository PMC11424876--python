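import dataclasses

import numpy as np
import pytest

from pbpkfih import pbpk, reference
from pbpkfih.pk_dataset import ConcentrationProfile, blq_policy


def make_profile(times, concs, blq=None, dose=10.0, subject="S001"):
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if blq is None:
        blq = np.zeros(times.size, dtype=bool)
    return ConcentrationProfile(subject, dose, times, concs, np.asarray(blq, bool))


def prepared(times, concs, **kw):
    return blq_policy(make_profile(times, concs, **kw))


@pytest.fixture(scope="session")
def drug_config():
    return reference.load_drug_config()


@pytest.fixture(scope="session")
def base_model(drug_config):
    return pbpk.build_model(
        reference.drug_parameters(drug_config),
        reference.load_physiology(),
        reference.absorption_model(drug_config),
        reference.elimination_model(drug_config),
    )


@pytest.fixture(scope="session")
def calibrated_model(base_model, drug_config):
    ref_dose, targets = reference.calibration_reference(drug_config)
    return pbpk.calibrate(base_model, ref_dose, targets)


@pytest.fixture(scope="session")
def unit_kp_drug(drug_config):
    drug = reference.drug_parameters(drug_config)
    return dataclasses.replace(drug, kp={k: 1.0 for k in drug.kp})
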