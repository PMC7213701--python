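import numpy as np
import pytest
from hypothesis import settings

from fetalqt import synthetic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_sim():
    """150 clean beats at the default fetal rate (140 bpm), exact truth."""
    cfg = synthetic.SimulationConfig(n_beats=150, hr_bpm=140, hr_sd_bpm=5, seed=7)
    return synthetic.simulate_record(cfg)


@pytest.fixture(scope="session")
def slow_sim():
    """100 beats at 120 bpm (RR ~ 500 ms), where the default band-constant
    reading yields an estimate for every beat."""
    cfg = synthetic.SimulationConfig(n_beats=100, hr_bpm=120, hr_sd_bpm=3, seed=11)
    return synthetic.simulate_record(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
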