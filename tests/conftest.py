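import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scene():
    """A 96x96 default-statistics scene shared by read-only tests."""
    from lodgemap.scene import SimulationConfig, generate_scene

    cfg = SimulationConfig(
        grid_height=96,
        grid_width=96,
        n_train_pixels=600,
        n_validation_pixels=300,
        plot_radius=3.0,
        seed=11,
    )
    return generate_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_psd_c2(rng, n):
    """n random 2x2 Hermitian PSD matrices as (c11, c22, c12) arrays."""
    a = rng.normal(size=(n, 2)) + 1j * rng.normal(size=(n, 2))
    b = rng.normal(size=(n, 2)) + 1j * rng.normal(size=(n, 2))
    # C = x x^H + y y^H is PSD with probability 1
    c11 = (np.abs(a[:, 0]) ** 2 + np.abs(b[:, 0]) ** 2).real
    c22 = (np.abs(a[:, 1]) ** 2 + np.abs(b[:, 1]) ** 2).real
    c12 = a[:, 0] * np.conj(a[:, 1]) + b[:, 0] * np.conj(b[:, 1])
    return c11, c22, c12
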