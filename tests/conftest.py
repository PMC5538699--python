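import numpy as np
import pytest

from ventprofile.forward import CEMSystem, skip4_scheme
from ventprofile.geometry import (
    Contour,
    ThoraxGeometry,
    build_mesh,
    place_electrodes,
    rasterize,
)
from ventprofile.synthetic import (
    BreathingConfig,
    PhantomConfig,
    make_phantom,
    simulate_recording,
)


def circle_contour(n: int = 128, radius: float = 1.0, center=(0.0, 0.0)) -> Contour:
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return Contour(
        np.column_stack([center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]),
        "thorax",
    )


@pytest.fixture(scope="session")
def circle_geometry() -> ThoraxGeometry:
    return ThoraxGeometry(thorax=circle_contour(), kind="circular")


@pytest.fixture(scope="session")
def circle_layout(circle_geometry):
    return place_electrodes(circle_geometry.thorax, 32)


@pytest.fixture(scope="session")
def circle_mesh(circle_geometry, circle_layout):
    return build_mesh(circle_geometry, circle_layout, target_elements=3000)


@pytest.fixture(scope="session")
def circle_grid(circle_geometry):
    return rasterize(circle_geometry)


@pytest.fixture(scope="session")
def scheme32():
    return skip4_scheme()


@pytest.fixture(scope="session")
def circle_system(circle_mesh, scheme32):
    return CEMSystem(circle_mesh, scheme32)


@pytest.fixture(scope="session")
def circle_jacobian(circle_system, circle_mesh):
    return circle_system.jacobian(np.ones(circle_mesh.n_elements))


@pytest.fixture(scope="session")
def pig_geometry():
    return make_phantom(PhantomConfig(kind="averaged"))


@pytest.fixture(scope="session")
def individual_geometry():
    return make_phantom(PhantomConfig(kind="individual", seed=0))


@pytest.fixture(scope="session")
def small_recording(individual_geometry):
    """One clean (noise-free) desk-scale breathing recording."""
    series, truth = simulate_recording(
        individual_geometry,
        BreathingConfig(sim_target_elements=8000, noise_snr=None),
    )
    return series, truth
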