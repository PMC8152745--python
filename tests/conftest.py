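import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ringpucker import Frame, RingSpec, Trajectory, build_reference_ring

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def furan_ring() -> RingSpec:
    return RingSpec.furan()


@pytest.fixture(scope="session")
def furan_classes(furan_ring):
    from ringpucker import build_wheel, reduce_by_symmetry

    return reduce_by_symmetry(build_wheel(), furan_ring)


@pytest.fixture(scope="session")
def reference_frame() -> Frame:
    """Planar furan-like reference ring in the xy-plane."""
    return build_reference_ring()


@pytest.fixture
def make_trajectory():
    """Build a Trajectory from an (n_frames, n_atoms, 3) coordinate array."""

    def _make(coords: np.ndarray, elements=None) -> Trajectory:
        coords = np.asarray(coords, dtype=float)
        if elements is None:
            elements = ("O",) + ("C",) * (coords.shape[1] - 1)
        frames = [
            Frame(index=i, elements=tuple(elements), coords=coords[i])
            for i in range(coords.shape[0])
        ]
        return Trajectory(frames=frames)

    return _make


def regular_pentagon(radius: float = 1.2) -> np.ndarray:
    """Counterclockwise regular pentagon in the xy-plane, centred on origin."""
    theta = 2.0 * np.pi * np.arange(5) / 5.0
    return np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(5)], axis=-1
    )
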