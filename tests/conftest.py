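import numpy as np
import pytest

from hostguest import phase_thermo as pt
from hostguest import synth

# Published stability constants (M^-1) of aurisin A with three cyclodextrins
# at 20/30/40/50 C; the reference input for the Van't Hoff reproduction.
KC_TABLE = {
    "AA/bCD": [42.0, 60.0, 73.0, 80.0],
    "AA/DMbCD": [209.0, 219.0, 232.0, 237.0],
    "AA/HPbCD": [88.0, 112.0, 135.0, 148.0],
}
KC_TEMPS_K = [293.15, 303.15, 313.15, 323.15]

# Published MM/PBSA component means (kcal/mol) of the AA/DMbCD complex.
ENERGY_MEANS = {
    "e_vdw": -35.12,
    "e_ele": -17.05,
    "g_solv_polar": 29.69,
    "g_solv_nonpolar": -5.51,
}
T_DELTA_S = -24.12
G_EXP = -3.24


@pytest.fixture
def kc_series():
    def make(label):
        return [
            pt.StabilityConstant(kc=k, temperature=t, label=label)
            for k, t in zip(KC_TABLE[label], KC_TEMPS_K)
        ]
    return make


@pytest.fixture
def ring_rigid():
    """Seven-unit ring, no jitter: every descriptor has a closed-form value."""
    return synth.simulate_ring_trajectory(synth.RingConfig(seed=0, n_frames=5))


@pytest.fixture
def ring_jittered():
    return synth.simulate_ring_trajectory(
        synth.RingConfig(seed=11, n_frames=8, jitter_sd=0.15, n_guest=6)
    )


@pytest.fixture
def solvated_ring():
    """Uniform single-site solvent in a periodic cube around the ring."""
    return synth.simulate_ring_trajectory(
        synth.RingConfig(seed=3, n_frames=20, n_waters=2000, box=40.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
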