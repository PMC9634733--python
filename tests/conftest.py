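import numpy as np
import pytest

from arterylabel.grid import VolumeGrid
from arterylabel.phantom import DESK_GRID, sample_subject
from arterylabel.taxonomy import build_aggregated_taxonomy, build_detailed_taxonomy


@pytest.fixture(scope="session")
def detailed():
    return build_detailed_taxonomy()


@pytest.fixture(scope="session")
def aggregated():
    return build_aggregated_taxonomy()


@pytest.fixture(scope="session")
def subject_complete():
    """One phantom subject with every artery segment present."""
    return sample_subject(seed=7, missing_prob=0.0, grid=DESK_GRID)


@pytest.fixture(scope="session")
def subject_missing():
    """One phantom subject guaranteed to have missing droppable segments."""
    return sample_subject(seed=11, missing_prob=1.0, grid=DESK_GRID)


def cylinder_mask(shape=(25, 25, 30), radius=3.0, axis=2, spacing=(1.0, 1.0, 1.0)):
    """Solid axis-aligned cylinder centered on an integer voxel (thinning
    tie-breaks erase perfectly symmetric even-centered tubes)."""
    idx = np.indices(shape).astype(float)
    center = [(s - 1) // 2 for s in shape]
    trans = [a for a in range(3) if a != axis]
    r2 = sum((idx[a] - center[a]) ** 2 for a in trans)
    return VolumeGrid((r2 <= radius ** 2).astype(np.uint8), spacing)


@pytest.fixture
def cylinder():
    return cylinder_mask()
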