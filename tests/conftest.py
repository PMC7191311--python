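import numpy as np
import pytest

from skinoptics.optics_core import OpticalProperties, load_paper_tables
from skinoptics.skin_voxel import VoxelGrid


@pytest.fixture(scope="session")
def tables():
    """Packaged (tissue, blood, vessel) tables, loaded once."""
    return load_paper_tables()


@pytest.fixture(scope="session")
def dermis_632():
    """Dermis optical properties at 632 nm (the workhorse test medium)."""
    return OpticalProperties.from_reduced(0.07, 3.06, 0.9, 1.39)


def homogeneous_grid(
    props: OpticalProperties,
    shape=(120, 120, 160),
    pitch_mm: float = 0.025,
) -> VoxelGrid:
    labels = np.zeros(shape, dtype=np.uint8)
    return VoxelGrid(labels=labels, pitch_mm=pitch_mm, properties={0: props})
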