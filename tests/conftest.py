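import numpy as np
import pytest

from dosemimic import (
    DoseGrid,
    Prescription,
    PhantomSpec,
    StructureMask,
    make_phantom,
    make_reference_dose,
)

#: desk-scale phantom: same physical anatomy as the default, coarser grid
SMALL_SPEC = PhantomSpec(shape=(64, 64, 64), spacing=(4.0, 4.0, 4.0), seed=7)


@pytest.fixture(scope="session")
def rx() -> Prescription:
    return Prescription()


@pytest.fixture(scope="session")
def small_case(rx):
    """(geometry, structures, reference dose) on a 64³ / 4 mm grid."""
    geometry, structures = make_phantom(SMALL_SPEC)
    dose = make_reference_dose(geometry, structures, rx, side=SMALL_SPEC.side)
    return geometry, structures, dose


def random_grid(rng, shape, spacing=(2.0, 2.0, 2.0), max_gy=70.0) -> DoseGrid:
    return DoseGrid(
        origin=(0.0, 0.0, 0.0),
        spacing=spacing,
        values=rng.random(shape) * max_gy,
    )


def random_mask(rng, grid: DoseGrid, name="S", p=0.5, nonempty=True) -> StructureMask:
    occ = rng.random(grid.shape) < p
    if nonempty and not occ.any():
        occ.flat[rng.integers(occ.size)] = True
    return StructureMask(name, occ, grid.frame_id)
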