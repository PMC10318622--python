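import numpy as np
import pytest

from jab.core import PlotForcing, SpeciesParams, StageState
from jab.datasets import posterior_mean_params, reference_stage_state, reference_states


@pytest.fixture(scope="session")
def fitted_params():
    params, consts = posterior_mean_params()
    return params, consts


@pytest.fixture(scope="session")
def reference_forcing(fitted_params):
    params, _ = fitted_params
    B_p = np.asarray(reference_states()["initial_data"]["BA"])
    return PlotForcing.from_l(params.l, B_p)


@pytest.fixture(scope="session")
def initial_state(fitted_params):
    return reference_stage_state("initial_model")


@pytest.fixture
def single_species():
    """A hand-computable one-species setup (state, params, forcing, consts)."""
    from jab.core import Constants

    consts = Constants(beta_uA=0.025, beta_mA=np.array([0.02]))
    params = SpeciesParams.from_natural(["sp"], {
        "r": [0.1], "l": [1.0], "c_J": [1e-4], "s": [1e-3], "g": [0.05],
        "c_A": [1e-3], "h": [0.2], "b": [0.05], "c_B": [1e-3]})
    state = StageState.from_stages([100.0], [50.0], [10.0], consts)
    forcing = PlotForcing(B_p=np.array([2.0]), L_p=np.array([2.0]))
    return state, params, forcing, consts
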