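import numpy as np
import pytest

from msnakit import SyntheticConfig, simulate_recording
from msnakit.synthetic import burst_template


@pytest.fixture(scope="session")
def default_recording():
    """60 s noise-free-ish default simulation shared across read-only tests."""
    return simulate_recording(SyntheticConfig(duration_s=60.0, seed=1))


@pytest.fixture(scope="session")
def noisy_recording():
    """240 s recording with an electrode-search epoch in the middle."""
    cfg = SyntheticConfig(duration_s=240.0, noise_epochs=[(60.0, 180.0)], seed=11)
    return simulate_recording(cfg)


def make_bump_signal(
    n: int = 5000, centers=(2000,), height: float = 0.3, width_scale: float = 1.0
) -> np.ndarray:
    """Quiet signal with burst-shaped bumps at given sample indices."""
    x = np.zeros(n)
    for c in centers:
        bump, apex = burst_template(height, 100.0 * width_scale, 180.0 * width_scale)
        lo = c - apex
        hi = lo + bump.size
        lo_c, hi_c = max(lo, 0), min(hi, n)
        x[lo_c:hi_c] += bump[lo_c - lo : hi_c - lo]
    return x


def random_test_signal(rng: np.random.Generator, n: int = 10000) -> np.ndarray:
    """Smooth random signal with occasional bumps, plateau-free."""
    from scipy.ndimage import gaussian_filter1d

    x = gaussian_filter1d(rng.normal(0.0, 1.0, n), 60.0)
    x *= 0.15 / max(x.std(), 1e-12)
    for _ in range(rng.integers(2, 8)):
        c = int(rng.integers(300, n - 300))
        h = rng.uniform(0.05, 0.9)
        bump, apex = burst_template(h, rng.uniform(40, 150), rng.uniform(80, 250))
        lo = c - apex
        hi = lo + bump.size
        lo_c, hi_c = max(lo, 0), min(hi, n)
        x[lo_c:hi_c] += bump[lo_c - lo : hi_c - lo]
    # break any accidental plateaus
    x += rng.normal(0.0, 1e-9, n)
    return x
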