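import numpy as np
import pytest

import meltcycle as mc

GRID = np.arange(25.0, 95.0 + 0.2, 0.4)


def make_curve(tm=64.0, dh=80.0, bn=(1000.0, 5.0), bu=(20000.0, 20.0),
               probe="DSF", noise_sd=0.0, seed=0, grid=GRID, **labels):
    """Synthetic two-state melt curve with optional Gaussian noise."""
    y = mc.two_state_signal(grid, tm, dh, bn, bu)
    if noise_sd:
        rng = np.random.default_rng(seed)
        amp = abs((bu[0] + bu[1] * grid.mean()) - (bn[0] + bn[1] * grid.mean()))
        y = y + rng.normal(0.0, noise_sd * amp, size=grid.size)
    kw = dict(well_id="w1", variant_index=0, replicate_id=1, batch_id="b1",
              probe=probe)
    kw.update(labels)
    return mc.MeltCurve(temperatures=grid.copy(), signals=y, **kw)


@pytest.fixture
def clean_curve():
    return make_curve()


@pytest.fixture(scope="session")
def noisefree_config():
    return mc.GeneratorConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def noisefree_truth(noisefree_config):
    return mc.make_truth(noisefree_config)


@pytest.fixture(scope="session")
def noisefree_plate(noisefree_truth, noisefree_config):
    return mc.generate_plate(noisefree_truth, noisefree_config, probe="DSF")
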