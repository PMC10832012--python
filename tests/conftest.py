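import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kbpdose import (
    DoseGrid,
    GridGeometry,
    PhantomSpec,
    StructureMask,
    make_dose,
    make_phantom,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_geometry() -> GridGeometry:
    return GridGeometry(origin=(0.0, 0.0, 0.0), spacing=(0.2, 0.2, 0.2), shape=(20, 20, 20))


@pytest.fixture
def random_mask_factory(small_geometry):
    """Seeded random masks on the shared small grid."""

    def make(seed: int, p: float = 0.3, name: str = "blob", role: str = "oar") -> StructureMask:
        rng = np.random.default_rng(seed)
        occ = rng.random(small_geometry.shape) < p
        if not occ.any():  # ensure non-empty
            occ[tuple(rng.integers(0, s) for s in small_geometry.shape)] = True
        return StructureMask(name=name, role=role, occupancy=occ, geometry=small_geometry)

    return make


@pytest.fixture
def random_dose_factory(small_geometry):
    def make(seed: int, scale: float = 80.0, prescription: float = 76.0) -> DoseGrid:
        rng = np.random.default_rng(seed)
        return DoseGrid(
            small_geometry,
            rng.random(small_geometry.shape) * scale,
            prescription_dose=prescription,
        )

    return make


@pytest.fixture(scope="session")
def default_phantom():
    spec = PhantomSpec()
    structures = make_phantom(spec)
    dose = make_dose(structures, spec)
    return spec, structures, dose
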