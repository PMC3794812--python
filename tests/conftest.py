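import numpy as np
import pytest

import trabs
from trabs.pipeline import run_pipeline


def _run_scenario(kind, seed=0, snr=None, n_exp=None, single_wavelength=None):
    """Run the bundled scenario end to end and return the report dict."""
    cfg = trabs.example_config(kind, seed)
    if snr is not None:
        cfg["noise"] = {"enabled": True, "snr": float(snr)}
    if n_exp is not None:
        cfg["analysis"]["n_exp"] = int(n_exp)
    cfg["analysis"]["single_wavelength_nm"] = single_wavelength
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def run_scenario():
    return _run_scenario


@pytest.fixture(scope="session")
def solution_noise_free_report():
    """Noise-free PYP-solution pipeline report (shared across tests)."""
    return _run_scenario("pyp_solution", seed=1, single_wavelength=485.0)


@pytest.fixture(scope="session")
def crystal_noise_free_report():
    return _run_scenario("pyp_crystal", seed=1)


@pytest.fixture(scope="session")
def solution_sim_noise_free():
    """Noise-free simulated solution campaign with its truth record."""
    from trabs import simulate as sim
    from trabs.core import make_logtime_grid

    model = sim.pyp_solution_model()
    times = make_logtime_grid(3e-5, 2.0, 10)
    return sim.simulate_series(
        model, sim.InstrumentModel(), times, seed=1, noise=False
    )


def random_rate_matrix(rng, n_species):
    """Random valid first-order rate matrix: columns sum to zero."""
    K = rng.uniform(0.0, 10.0, size=(n_species, n_species))
    np.fill_diagonal(K, 0.0)
    K -= np.diag(K.sum(axis=0))
    return K
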