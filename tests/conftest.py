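import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from woundrepair import simkit

settings.register_profile(
    "default",
    settings(derandomize=True, max_examples=25,
             suppress_health_check=[HealthCheck.too_slow]),
)
settings.load_profile("default")


def small_frame_times(t_end=900.0, late_end=None):
    """Pre-wound frame at -30 s then the 30 s cadence (optionally extended
    at 60 s cadence) — a truncated version of the acquisition grid."""
    parts = [[-30.0], np.arange(0.0, t_end + 1, 30.0)]
    if late_end is not None:
        parts.append(np.arange(t_end + 60.0, late_end + 1, 60.0))
    return np.concatenate(parts)


def make_params(**kwargs) -> simkit.WoundSimParams:
    """Small test stack: 192x192 px, initial area 100 μm², 30 s cadence."""
    defaults = dict(
        image_shape=(192, 192),
        pixel_size=0.22,
        frame_times=small_frame_times(),
        r0=np.sqrt(100.0 / np.pi),  # initial area exactly 100 μm²
        expansion_fold_true=1.5,
        t_max_true=60.0,
        closure_rate_true=0.2,
        rng_seed=0,
    )
    defaults.update(kwargs)
    return simkit.WoundSimParams(**defaults)


@pytest.fixture(scope="session")
def noiseless_params():
    return make_params(noise_model="none")


@pytest.fixture(scope="session")
def noiseless_stack(noiseless_params):
    return simkit.simulate_wound_stack(noiseless_params)


@pytest.fixture(scope="session")
def noisy_stack():
    return simkit.simulate_wound_stack(make_params())


def random_connected_mask(rng: np.random.Generator, shape=(40, 40),
                          n_steps=80) -> np.ndarray:
    """Random connected blob: self-avoiding-ish random walk, dilated once."""
    from scipy import ndimage
    mask = np.zeros(shape, dtype=bool)
    r, c = shape[0] // 2, shape[1] // 2
    mask[r, c] = True
    for _ in range(n_steps):
        dr, dc = rng.choice([(0, 1), (0, -1), (1, 0), (-1, 0)])
        r = int(np.clip(r + dr, 1, shape[0] - 2))
        c = int(np.clip(c + dc, 1, shape[1] - 2))
        mask[r, c] = True
    return ndimage.binary_dilation(mask)


def brute_force_feret(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """O(n²) oracle: max pairwise distance between boundary-pixel centers."""
    from scipy import ndimage
    from scipy.spatial.distance import pdist
    boundary = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(boundary).astype(float)
    if len(pts) < 2:
        return 0.0
    return float(pdist(pts).max()) * pixel_size
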