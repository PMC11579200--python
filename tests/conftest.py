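import numpy as np
import pytest

from qspvct import model_core as mc
from qspvct import vp_generation as vg


@pytest.fixture(scope="session")
def default_params():
    return mc.PatientParameters()


@pytest.fixture(scope="session")
def immune_off_params():
    """Parameters with the APC->priming chain disabled: starting from a
    cancer-only state, every immune population stays at zero and the tumor
    follows the pure logistic law."""
    return mc.PatientParameters({"k_apc_mat": 0.0})


@pytest.fixture(scope="session")
def small_cohort():
    """A small plausible cohort shared across tests (40 proposed)."""
    dists = vg.default_distribution_set()
    plausible, n_proposed = vg.build_plausible_cohort(dists, 40, seed=123)
    assert len(plausible) >= 20
    return plausible, n_proposed


@pytest.fixture(scope="session")
def one_patient(small_cohort):
    return small_cohort[0][0]


@pytest.fixture(scope="session")
def one_params(one_patient):
    return one_patient.params
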