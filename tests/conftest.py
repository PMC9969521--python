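import numpy as np
import pytest

import revmre as rv


@pytest.fixture(scope="session")
def reverberant_field():
    """Fully reverberant field at the default study conditions (48^3)."""
    cfg = rv.SimulationConfig(grid_shape=(48, 48, 48), rng_seed=0)
    return cfg, rv.simulate_reverberant_field(cfg)


@pytest.fixture(scope="session")
def plane_wave_field():
    """Single-plane-wave field: analytic oracle for the inversion chain."""
    cfg = rv.SimulationConfig(grid_shape=(24, 24, 24), n_sources=1, rng_seed=5)
    return cfg, rv.simulate_reverberant_field(cfg)


def oblique_plane_wave(shape, k_rad_per_m, spacing_mm=1.6, direction=(1.0, 1.0, 1.0)):
    """Complex plane wave with wavenumber k along an oblique direction."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    axes = [np.arange(n) * spacing_mm * 1e-3 for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return np.exp(1j * k_rad_per_m * (d[0] * X + d[1] * Y + d[2] * Z))
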