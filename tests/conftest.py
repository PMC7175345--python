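import numpy as np
import pytest

from nucrheo import BurgersParams, average_curves, mpa_to_creep
from nucrheo.synthetic import NoiseModel, make_preset, simulate_aspiration, true_curve


@pytest.fixture(scope="session")
def wt_params() -> BurgersParams:
    """Wild-type-like Burgers ground truth (kPa, kPa*s)."""
    return BurgersParams(k_M=0.5, k_KV=0.5, mu_M=9.5, mu_KV=0.9)


@pytest.fixture(scope="session")
def wt_preset():
    return make_preset("WT")


@pytest.fixture(scope="session")
def tko_preset():
    return make_preset("TKO")


@pytest.fixture(scope="session")
def noiseless_wt_curve(wt_preset):
    """Exact Burgers compliance on a 10 Hz, 12 s grid."""
    return true_curve(wt_preset)


@pytest.fixture(scope="session")
def averaged_noisy_wt_curve(wt_preset):
    """15-replicate average of 5%-noise aspiration simulations (fixed seed)."""
    traces = simulate_aspiration(
        wt_preset, noise=NoiseModel(cv=0.05, seed=42), n_replicates=15
    )
    curves = [mpa_to_creep(tr) for tr in traces]
    return average_curves(curves, curves[0].t)


@pytest.fixture(scope="session")
def dense_grid():
    return np.linspace(0.0, 12.0, 241)
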