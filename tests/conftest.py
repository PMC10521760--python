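import numpy as np
import pytest

from phasorquant import raman as rq
from phasorquant import synthetic as syn


@pytest.fixture(scope="session")
def delays():
    return syn.default_delays()


@pytest.fixture(scope="session")
def noise_free_scene():
    cfg = syn.SceneConfig(noise_sigma=0.0)
    return syn.make_scene(cfg, seed=11)


@pytest.fixture(scope="session")
def noise_free_stack(noise_free_scene):
    return syn.render_delay_stack(noise_free_scene)


@pytest.fixture(scope="session")
def unsat_model():
    standards = syn.make_calibration_standards("unsaturation")
    pairs = [(x, rq.band_ratio(s, rq.BAND_CC_STRETCH, rq.BAND_CH2_BEND)) for x, s in standards]
    return rq.fit_calibration(pairs, "unsaturation")


@pytest.fixture(scope="session")
def ce_model():
    standards = syn.make_calibration_standards("ce_percent")
    pairs = [(x, rq.band_ratio(s, rq.BAND_CHOLESTEROL, rq.BAND_CH2_BEND)) for x, s in standards]
    return rq.fit_calibration(pairs, "ce_percent")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
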