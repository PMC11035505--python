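import numpy as np
import pytest

from nmdose.nuclides import EmissionLine, Radionuclide
from nmdose.phantoms import VoxelPhantom, generate_phantom


@pytest.fixture(scope="session")
def mono140():
    """Single-line 140.511 keV emitter with unit yield."""
    return Radionuclide("mono140", 1000.0, (EmissionLine(140.511, 1.0),))


@pytest.fixture(scope="session")
def vacuum_point_phantom():
    """A single labelled source voxel in vacuum (analytic-limit geometry)."""
    labels = np.full((3, 3, 3), 2, dtype=np.int16)
    labels[1, 1, 1] = 1
    return VoxelPhantom(
        labels=labels, voxel_size_mm=10.0,
        label_map={1: ("Src", "vacuum"), 2: ("Pad", "vacuum")},
        origin_cm=(-1.5, -1.5, -1.5),
    )


@pytest.fixture(scope="session")
def coarse_body():
    """A 10-mm-voxel adult body reused by the slower geometry/dose tests."""
    return generate_phantom(164.0, 60.2, seed=1, voxel_mm=10.0)
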