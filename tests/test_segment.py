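"""Segmentation: background subtraction, vesselness, thresholding, and the
hollow-vessel filling route."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
import hypothesis.extra.numpy as hnp

from microvasc import phantom as ph
from microvasc.segment import (
    SegmentationParams,
    subtract_background,
    vesselness,
    binarize,
    fill_hollow,
    segment_volume,
)
from microvasc.volume import Volume3D, BinaryMask
from microvasc.spots import Spot


def _dice(a, b):
    return 2.0 * (a & b).sum() / max(a.sum() + b.sum(), 1)


class TestSubtractBackground:
    def test_constant_image_maps_to_zero(self):
        vol = Volume3D(np.full((20, 30, 30), 37.0), (2, 1, 1))
        out = subtract_background(vol, radius_um=10.0)
        assert float(np.abs(out.voxels).max()) == pytest.approx(0.0, abs=1e-4)

    def test_tube_contrast_preserved_on_offset_background(self):
        truth = ph.PhantomTruth(
            segments=[ph.TubeSegment.straight((30, 30, 5), (30, 30, 55), 3.0)],
            roi_extent_um=(60, 60, 60))
        tube = ph.render(truth, spacing_um=(1, 1, 1), peak=100.0)
        before = tube.voxels[30, 30, 30] - tube.voxels[30, 50, 30]
        withbg = Volume3D(tube.voxels + 40.0, (1, 1, 1))
        out = subtract_background(withbg, radius_um=20.0)
        after = out.voxels[30, 30, 30] - out.voxels[30, 50, 30]
        assert after == pytest.approx(before, rel=0.10)

    def test_radius_below_voxel_size_raises(self):
        vol = Volume3D(np.zeros((10, 10, 10)), (2, 1, 1))
        with pytest.raises(ValueError):
            subtract_background(vol, radius_um=1.5)

    @settings(max_examples=20, deadline=None)
    @given(hnp.arrays(np.float32, (8, 12, 12),
                      elements=st.floats(0, 100, width=32)))
    def test_output_never_negative(self, arr):
        out = subtract_background(Volume3D(arr, (1, 1, 1)), radius_um=4.0)
        assert float(out.voxels.min()) >= 0.0


class TestVesselness:
    def test_uniform_image_gives_zero_response(self):
        vol = Volume3D(np.full((20, 20, 20), 7.0), (1, 1, 1))
        out = vesselness(vol, (1.0,), (3.0,))
        assert float(out.voxels.max()) == 0.0

    def test_centerline_dominates_off_axis(self):
        truth = ph.PhantomTruth(
            segments=[ph.TubeSegment.straight((30, 30, 5), (30, 30, 55), 2.0)],
            roi_extent_um=(60, 60, 60))
        vol = ph.render(truth, spacing_um=(1, 1, 1), blur_sigma_um=0.7)
        ves = vesselness(vol).voxels
        center = float(ves[30, 30, 30])
        away = float(ves[30, 36, 30])  # 3 radii off-axis
        assert center >= 5.0 * max(away, 1e-12)

    def test_blob_center_suppressed_relative_to_tube(self):
        # equal radius: tube r=4 and sphere d=8 in one volume; the Frangi
        # blobness term suppresses the isotropic center response
        tube = ph.TubeSegment.straight((20, 20, 5), (20, 20, 55), 4.0)
        truth = ph.PhantomTruth(
            segments=[tube], roi_extent_um=(60, 60, 60),
            spots=[Spot(id=0, center_um=(45, 45, 30), diameter_um=8.0)])
        v = np.maximum(ph.render(truth, spacing_um=(1, 1, 1), blur_sigma_um=1.5).voxels,
                       ph.render_spots(truth, spacing_um=(1, 1, 1), blur_sigma_um=1.5).voxels)
        ves = vesselness(Volume3D(v, (1, 1, 1))).voxels
        assert ves[45, 45, 30] < 0.5 * ves[20, 20, 30]

    def test_subvoxel_scale_warns(self):
        vol = Volume3D(np.zeros((10, 10, 10)) + np.eye(10)[None], (2, 1, 1))
        with pytest.warns(UserWarning, match="below voxel size"):
            vesselness(vol, (0.5,), (3.0,))


class TestBinarize:
    def test_zero_vesselness_gives_empty_mask(self):
        vol = Volume3D(np.zeros((15, 15, 15)), (1, 1, 1))
        with pytest.warns(UserWarning):
            mask = binarize(vol, SegmentationParams())
        assert not mask.voxels.any()

    def test_min_component_filter_is_monotone(self):
        rng = np.random.default_rng(0)
        vol = Volume3D((rng.random((20, 20, 20)) > 0.7).astype(float), (1, 1, 1))
        big = binarize(vol, SegmentationParams(threshold_method="fixed",
                                               threshold_value=0.5,
                                               min_component_voxels=20))
        small = binarize(vol, SegmentationParams(threshold_method="fixed",
                                                 threshold_value=0.5,
                                                 min_component_voxels=5))
        assert not (big.voxels & ~small.voxels).any()

    def test_noiseless_tube_dice_with_vesselness_route(self):
        truth = ph.PhantomTruth(
            segments=[ph.TubeSegment.straight((30, 30, 5), (30, 30, 55), 2.0)],
            roi_extent_um=(60, 60, 60))
        vol = ph.render(truth, spacing_um=(1, 1, 1))
        true_mask = vol.voxels > 0
        mask = segment_volume(vol, SegmentationParams(min_component_voxels=30),
                              subtract_bg=False)
        assert _dice(mask.voxels, true_mask) >= 0.9


@pytest.fixture(scope="module")
def hollow_pair():
    truth = ph.sample_network(10, roi_extent_um=(120, 120, 120),
                              radius_range_um=(3.0, 5.0), seed=4,
                              min_junctions=2)
    solid = ph.render(truth, spacing_um=(1, 1, 1)).voxels > 0
    hollow = ph.render(truth, spacing_um=(1, 1, 1), mode="hollow",
                       wall_um=1.0).voxels > 0
    return BinaryMask(hollow, (1, 1, 1)), solid


class TestFillHollow:
    def test_filled_hollow_matches_solid_render(self, hollow_pair):
        hollow, solid = hollow_pair
        filled = fill_hollow(hollow, SegmentationParams(min_component_voxels=30))
        assert _dice(filled.voxels, solid) >= 0.95

    def test_monotone_and_idempotent(self, hollow_pair):
        hollow, _ = hollow_pair
        params = SegmentationParams(min_component_voxels=30)
        once = fill_hollow(hollow, params)
        assert not (hollow.voxels & ~once.voxels).any()
        twice = fill_hollow(once, params)
        assert np.array_equal(once.voxels, twice.voxels)

    def test_solid_input_grows_at_most_by_closing(self, straight_tube_truth):
        solid = ph.render(straight_tube_truth, spacing_um=(1, 1, 1)).voxels > 0
        mask = BinaryMask(solid, (1, 1, 1))
        params = SegmentationParams(min_component_voxels=30, closing_radius_um=2.0)
        out = fill_hollow(mask, params)
        assert not (solid & ~out.voxels).any()
        # any growth stays within the closing radius of the input surface
        import scipy.ndimage as ndi
        dist_out = ndi.distance_transform_edt(~solid, sampling=(1, 1, 1))
        assert float(dist_out[out.voxels & ~solid].max(initial=0.0)) <= 2.0 + 1.8

    def test_border_open_halfpipe_not_filled(self):
        # a U-channel open along the top and touching the border: its cavity
        # is connected to the outside, so it must not be filled
        m = np.zeros((20, 20, 20), bool)
        m[5:15, 5, 5:15] = True          # bottom
        m[5:15, 5:15, 5] = True          # one side
        m[5:15, 5:15, 14] = True         # other side (top open)
        mask = BinaryMask(m, (1, 1, 1))
        params = SegmentationParams(min_component_voxels=1,
                                    closing_radius_um=1.0)
        out = fill_hollow(mask, params)
        assert not out.voxels[10, 12, 10]  # channel interior stays open

    def test_undersized_closing_radius_warns(self):
        truth = ph.PhantomTruth(
            segments=[ph.TubeSegment.straight((30, 30, 5), (30, 30, 55), 4.0)],
            roi_extent_um=(60, 60, 60))
        hollow = ph.render(truth, spacing_um=(1, 1, 1), mode="hollow",
                           wall_um=1.0).voxels > 0
        hollow[33:36, 29:32, 28:31] = False  # 3 µm hole through the wall
        mask = BinaryMask(hollow, (1, 1, 1))
        # a 1 µm closing cannot seal the 3 µm hole: lumen leaks to outside
        params = SegmentationParams(min_component_voxels=10,
                                    closing_radius_um=1.0)
        with pytest.warns(UserWarning, match="hollow"):
            fill_hollow(mask, params)
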