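import numpy as np
import pytest
from hypothesis import settings

from entrodyn.dynamics import SET3_PARAMS, CoupledTraitParams, InitialCondition
from entrodyn.synthetic import dental_observed

# reproducible property tests regardless of the invoking environment
settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def dental_norm():
    """Dental fixture on the normalized scale (supp -> N, time -> P)."""
    return dental_observed(scale="norm")


@pytest.fixture(scope="session")
def set3_params():
    return SET3_PARAMS


@pytest.fixture(scope="session")
def set3_init():
    return InitialCondition(t0=0.0, N0=0.9, P0=0.93, E0=0.01)


@pytest.fixture(scope="session")
def free_abg_spec():
    """Factory for a spec freeing (alpha, beta, gamma) with every other
    coefficient fixed at the supplied truth."""
    from entrodyn.estimation import ParamEntry, ParameterSpec

    def make(params, init, coupled=True):
        entries = {
            "mu": ParamEntry(False, params.mu, 0.0, 1.0),
            "alpha": ParamEntry(True, 0.5, 0.0, 5.0),
            "beta": ParamEntry(True, 0.2, -2.0, 2.0),
            "gamma": ParamEntry(True, 0.1, 0.0, 1.0),
            "c1": ParamEntry(False, params.c1, 0.0, 20.0),
            "c2": ParamEntry(False, params.c2, 0.0, 20.0),
            "c3": ParamEntry(False, params.c3, 0.0, 20.0),
            "K": ParamEntry(False, params.K, 1e-3, 10.0),
            "G": ParamEntry(False, params.G, 1e-3, 10.0),
            "N0": ParamEntry(False, init.N0, 0.0, 1.0),
            "P0": ParamEntry(False, init.P0, 1e-4, 1.0),
            "E0": ParamEntry(False, init.E0, 1e-4, 1.0),
        }
        return ParameterSpec(entries, coupled=coupled)

    return make


@pytest.fixture(scope="session")
def recovery_truth():
    """Ground truth for parameter-recovery experiments.

    The stress pathway is live (c3 > 0) so gamma is identifiable, and
    the coupling is strong enough that alpha/beta/gamma all leave a
    visible imprint on six waves.
    """
    params = CoupledTraitParams(
        mu=0.05, alpha=0.3, beta=0.4, gamma=0.15,
        c1=1.0, c2=0.2, c3=1.0, K=0.5, G=1.0,
    )
    init = InitialCondition(t0=0.0, N0=0.8, P0=0.85, E0=0.05)
    wave_times = np.array([0.0, 3.0, 9.0, 13.0, 19.0, 23.0])
    return params, init, wave_times
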