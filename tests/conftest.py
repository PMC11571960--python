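"""Shared phantom fixtures; everything is generated at test time."""

import numpy as np
import pytest

from microvasc import phantom as ph
from microvasc.volume import BinaryMask


@pytest.fixture(scope="session")
def straight_tube_truth():
    """One axis-aligned tube: radius 4 µm, length 80 µm, in a 100³ µm ROI."""
    return ph.PhantomTruth(
        segments=[ph.TubeSegment.straight((50, 50, 10), (50, 50, 90), 4.0)],
        roi_extent_um=(100.0, 100.0, 100.0),
    )


@pytest.fixture(scope="session")
def y_tree_truth():
    """A parent tube bifurcating into two children: one degree-3 junction."""
    j = np.array([50.0, 50.0, 50.0])
    c1 = j + 40 * np.array([0.0, 0.5, 0.8])
    c2 = j + 40 * np.array([0.0, -0.5, 0.8])
    return ph.PhantomTruth(
        segments=[
            ph.TubeSegment.straight((50, 50, 10), j, 2.5),
            ph.TubeSegment.straight(j, c1, 2.0),
            ph.TubeSegment.straight(j, c2, 2.0),
        ],
        roi_extent_um=(100.0, 100.0, 100.0),
    )


@pytest.fixture(scope="session")
def semicircle_truth():
    """A semicircular arc of bend radius 20 µm (tube radius 2.5 µm)."""
    return ph.PhantomTruth(
        segments=[ph.TubeSegment.arc(center=(40, 40, 40), axis=(1, 0, 0),
                                     p0=(40, 20, 40), span=np.pi, radius_um=2.5)],
        roi_extent_um=(80.0, 80.0, 80.0),
    )


@pytest.fixture(scope="session")
def network_truth():
    """A seeded random branching network at moderate scale."""
    return ph.sample_network(20, roi_extent_um=(200.0, 200.0, 200.0),
                             seed=11, min_junctions=5)


@pytest.fixture(scope="session")
def network_mask(network_truth):
    """Noiseless solid mask of the random network at (2,1,1) µm spacing."""
    vol = ph.render(network_truth, spacing_um=(2.0, 1.0, 1.0))
    return BinaryMask(vol.voxels > 0, (2.0, 1.0, 1.0))
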