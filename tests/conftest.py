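import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from phenogrow import compute_gi, estimate_background, power_law_plate

#: Printed K562 calibration the idealised fixtures are built from.
K562_M = 0.99
K562_Q = -14.6
SEEDING_DENSITY = 1e5  # cells/ml


@pytest.fixture(scope="session")
def powerlaw_plate():
    """Idealised plate following ln(GI) = 0.99 ln(C) - 14.6 exactly."""
    well, blank, counts = power_law_plate(m=K562_M, q=K562_Q, c0=SEEDING_DENSITY)
    gi = compute_gi(well, background=estimate_background([blank]))
    return well, blank, counts, gi


def random_window_instance(rng: np.random.Generator):
    """A random log-growth-like series for window-detector oracle tests."""
    n = int(rng.integers(8, 61))
    t = np.sort(rng.uniform(0, 200, size=n)) if rng.random() < 0.3 else np.arange(n) * 6.0
    t = np.unique(t)
    n = t.size
    kind = rng.integers(0, 3)
    if kind == 0:  # noisy line
        y = rng.uniform(-0.05, 0.08) * t + rng.normal(0, 0.1, n)
    elif kind == 1:  # lag - exponential - plateau
        t1, t2 = np.sort(rng.uniform(t[0], t[-1], 2))
        mu = rng.uniform(0.01, 0.08)
        y = mu * np.clip(t, t1, t2) + rng.normal(0, 0.02, n)
    else:  # random walk
        y = np.cumsum(rng.normal(0, 0.3, n))
    return t, y
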