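import copy

import numpy as np
import pytest

from dmer.params import default_parameters
from dmer.tis import default_tis_table


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture()
def params_copy(params):
    return copy.deepcopy(params)


@pytest.fixture(scope="session")
def tis_table():
    return default_tis_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def deterministic_params(params, e_plac=1.0):
    """Typical-value-only parameter set: no IIV, optional no placebo drift."""
    p = copy.deepcopy(params)
    p.iiv_emax_norm = 0.0
    p.iiv_e_plac = 0.0
    p.block_correlation = 0.0
    p.shared.e_plac = e_plac
    for spec in p.endpoints.values():
        spec.iiv_baseline = 0.0
        if spec.eta_own_var is not None:
            spec.eta_own_var = 0.0
    return p


@pytest.fixture()
def typical_only(params):
    return deterministic_params(params)
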