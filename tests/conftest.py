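import numpy as np
import pytest

from simpull import GFPPhotophysics
from simpull.synthetic import CellSpec, SyntheticImageSpec, simulate_cell_image


@pytest.fixture(scope="session")
def phys():
    """Default photophysics: SNR 20, 30% self-dimer background."""
    return GFPPhotophysics()


@pytest.fixture(scope="session")
def noiseless_phys():
    return GFPPhotophysics(noise_sd=0.0)


@pytest.fixture(scope="session")
def single_cell_image():
    """One noiseless cell, nuclear fraction 0.5, with ground truth."""
    cell = CellSpec(center=(64, 64), nuclear_signal_fraction=0.5)
    spec = SyntheticImageSpec(shape=(128, 128), cells=(cell,), noise_sd=0.0, seed=0)
    return simulate_cell_image(spec)


def distinct_bleach_frames(rng: np.random.Generator, k: int, n_frames: int):
    """k distinct, well-interior bleach frames for constructing staircases."""
    lo, hi = max(2, n_frames // 20), n_frames - 2
    frames = rng.choice(np.arange(lo, hi), size=k, replace=False)
    return sorted(int(f) for f in frames)
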