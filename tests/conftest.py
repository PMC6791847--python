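import numpy as np
import pytest

from lincquant import (
    SyntheticConfig,
    TABLE1_FILAMENT_COUNTS,
    TABLE1_HAS_MICROTUBULE,
    generate_cohort,
    quantify_sites,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def table1_cohort():
    """Synthetic 11-site cohort with the observed per-site filament counts
    and microtubule pattern (6 without, 5 with)."""
    cfg = SyntheticConfig(
        n_sites=11, filament_counts=TABLE1_FILAMENT_COUNTS, seed=42
    )
    return generate_cohort(cfg, mt_pattern=TABLE1_HAS_MICROTUBULE)


@pytest.fixture(scope="session")
def table1_quantified(table1_cohort):
    return quantify_sites(table1_cohort.models)


def random_polyline(rng, n_points=20, scale=50.0):
    """Random open polyline used across oracle tests."""
    steps = rng.normal(size=(n_points, 3)) * scale / np.sqrt(n_points)
    return np.cumsum(steps, axis=0)


def random_rotation(rng):
    """Uniform-ish random rotation matrix via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
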