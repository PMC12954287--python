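import numpy as np
import pytest

from mpkb.phantoms import PhantomSpec, make_cohort

# compact, coarse phantoms for fast unit tests (the full-scale defaults are
# exercised in the acceptance suite)
TINY_BASE = PhantomSpec(fine_spacing=1.0, margin_mm=4.0)
TINY_VAR = {"semi_axis_mm": (8.0, 12.0), "in_plane_mm": (0.9, 1.1),
            "slice_mm": (2.5, 3.5)}

TINY_NET = dict(encoder_depth=3, base_channels=4, latent_dim=16,
                in_plane_size=32)


@pytest.fixture(scope="session")
def tiny_cohort():
    """10 small full-protocol phantom exams with ground truth."""
    return make_cohort(10, base_spec=TINY_BASE, variability=TINY_VAR, seed=7)


@pytest.fixture(scope="session")
def tiny_exam(tiny_cohort):
    return tiny_cohort[0][0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
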