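import numpy as np
import pytest

from thermperf import MCMCConfig, SimConfig
from thermperf.preprocess import preprocess
from thermperf.synthetic_data import simulate_experiment
from thermperf.tpc_model import fit_tpc


def recovery_config(seed: int = 3) -> SimConfig:
    """12 populations, 3 genotypes, 6 regimes, low noise: the standard
    parameter-recovery scenario."""
    return SimConfig(
        n_native_pops=6,
        n_invasive_pops=6,
        truth_mode="cline",
        noise_sd=0.01,
        p_establish_fail=0.0,
        p_damage=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_fit():
    """One fitted recovery dataset shared across model-level tests."""
    cfg = recovery_config(seed=3)
    climate, truths, records = simulate_experiment(cfg)
    _clean, _report, _means, scaled = preprocess(records)
    draws, diag = fit_tpc(
        scaled, MCMCConfig(chains=2, iterations_per_chain=2000, seed=103)
    )
    return {
        "config": cfg,
        "climate": climate,
        "truths": truths,
        "scaled": scaled,
        "draws": draws,
        "diagnostics": diag,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
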