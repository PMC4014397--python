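import numpy as np
import pytest

from superpose.pipeline import PipelineConfig, run_pipeline
from superpose.simulate import SimulationConfig


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at study-default settings (20 promoters,
    15 condition sets, 4 days, σ=0.14 day noise, 1 violator)."""
    return run_pipeline(PipelineConfig(), seed=1)


@pytest.fixture(scope="session")
def noiseless_run():
    """Noise-free small experiment at window 5 for exact-recovery checks."""
    sim = SimulationConfig(
        n_promoters=8,
        n_violators=0,
        single_shape_fraction=0.0,
        day_noise_sigma=0.0,
        od_noise_cv=0.0,
        fluo_noise_frac=0.0,
        n_days=1,
    )
    cfg = PipelineConfig(window=5, simulation=sim)
    return run_pipeline(cfg, seed=2, steps=("simulate", "activity", "fit"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
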