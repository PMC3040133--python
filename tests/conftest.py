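import numpy as np
import pytest

from rnaifit import SharedRates, make_params, standard_dose_grid


@pytest.fixture
def shared():
    """Default shared rates: km = 1 a.u./min, dm = ln(2)/40 min^-1."""
    return SharedRates()


@pytest.fixture
def egfp_mrna_fits():
    """Reference fitted parameters from an EGFP-mRNA knockdown titration."""
    return {
        "model1": make_params("model1", k1=1.38e-4),
        "model2": make_params("model2", k2=5.00e-3, h2=0.126),
        "model3": make_params("model3", k3h3=1.40e-4, c3_over_km=1.33e3),
        "model4": make_params("model4", d4=8.1e-3, theta4=0.105, h4=4.47),
    }


@pytest.fixture
def egfp_protein_model4():
    """Reference Hill-model parameters from the EGFP protein-level fit."""
    return make_params("model4", d4=8.6e-3, theta4=12.9, h4=4.49)


@pytest.fixture
def dose_grid():
    return standard_dose_grid()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
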