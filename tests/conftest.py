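"""Shared fixtures: synthetic recordings built once per session."""

import warnings

import numpy as np
import pytest

from wakeosc.core import Recording
from wakeosc.montage import make_geodesic_montage
from wakeosc.synthetic import BurstSpec, generate_aperiodic, insert_bursts

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", module="statsmodels")

FS = 250.0


@pytest.fixture(scope="session")
def single_channel_montage():
    return make_geodesic_montage().subset(["E1"])


@pytest.fixture(scope="session")
def full_montage():
    return make_geodesic_montage()


def make_burst_scenario(seed: int, duration_s: float, montage, min_cycles=12,
                        max_cycles=26, gap=(1.0, 3.0), amp=(20.0, 45.0)):
    """Well-separated planted bursts on one channel; returns the spec list."""
    rng = np.random.default_rng(seed)
    specs, t0 = [], 2.0
    while True:
        f = float(rng.uniform(5, 14))
        nc = int(rng.integers(min_cycles, max_cycles))
        if t0 + nc / f > duration_s - 2:
            break
        specs.append(
            BurstSpec((0,), t0, f, nc, float(rng.uniform(*amp)))
        )
        t0 += nc / f + float(rng.uniform(*gap))
    return specs


@pytest.fixture(scope="session")
def burst_scenario_zero(single_channel_montage):
    """Planted bursts on a silent background, with ground truth."""
    specs = make_burst_scenario(7, 120.0, single_channel_montage)
    base = Recording(np.zeros((1, int(120 * FS))), FS, single_channel_montage)
    rec, manifest = insert_bursts(base, specs)
    return rec, manifest


@pytest.fixture(scope="session")
def burst_scenario_pink(single_channel_montage):
    """Same bursts superposed on a 1/f^1.5 background."""
    specs = make_burst_scenario(7, 120.0, single_channel_montage)
    base = generate_aperiodic(
        1, 120.0, FS, exponent=1.5, offset=0.5, seed=4,
        montage=single_channel_montage,
    )
    rec, manifest = insert_bursts(base, specs)
    return rec, manifest


@pytest.fixture(scope="session")
def clean_128ch_recording(full_montage):
    """Spatially correlated 1/f background on the full sensor net, raw rate."""
    return generate_aperiodic(
        128, 90.0, 500.0, exponent=1.5, offset=1.0, seed=2, montage=full_montage
    )
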