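"""Phantom generator: determinism, rasterization accuracy, analytic metrics,
and spot placement."""

import json
import math

import numpy as np
import pytest

from microvasc import phantom as ph
from microvasc.metrics import CALIBER_CLASSES


class TestSampleNetwork:
    def test_single_segment_has_no_junctions(self):
        truth = ph.sample_network(1, roi_extent_um=(100, 100, 100), seed=7)
        assert len(truth.segments) == 1
        assert truth.n_junctions == 0

    def test_y_tree_has_one_degree3_junction(self, y_tree_truth):
        assert y_tree_truth.n_junctions == 1
        assert y_tree_truth.junctions[0].degree == 3

    def test_determinism_and_seed_sensitivity(self):
        kw = dict(roi_extent_um=(200, 200, 200), min_junctions=4)
        a = ph.sample_network(20, seed=11, **kw)
        b = ph.sample_network(20, seed=11, **kw)
        c = ph.sample_network(20, seed=12, **kw)
        assert json.dumps(a.to_dict()) == json.dumps(b.to_dict())
        assert json.dumps(a.to_dict()) != json.dumps(c.to_dict())

    def test_requested_junction_minimum_is_met(self, network_truth):
        assert network_truth.n_junctions >= 5

    def test_centerlines_stay_inside_roi(self, network_truth):
        ext = np.asarray(network_truth.roi_extent_um)
        for seg in network_truth.segments:
            for p in (seg.p0, seg.p1):
                assert np.all(p >= 0) and np.all(p <= ext)

    def test_junction_separation_respects_minimum(self, network_truth):
        pos = np.array([j.position_um for j in network_truth.junctions])
        d = np.linalg.norm(pos[:, None] - pos[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 10.0

    def test_impossible_density_raises(self):
        with pytest.raises(ph.PhantomTooDenseError):
            ph.sample_network(500, roi_extent_um=(60, 60, 60), seed=0,
                              max_attempts_factor=5)


class TestRender:
    def test_solid_voxel_count_matches_cylinder_volume(self, straight_tube_truth):
        vol = ph.render(straight_tube_truth, spacing_um=(1, 1, 1))
        analytic = math.pi * 4.0 ** 2 * 80.0
        measured = float((vol.voxels > 0).sum())  # voxel volume is 1 µm³
        assert measured == pytest.approx(analytic, rel=0.05)

    def test_hollow_is_shell_inside_solid(self, straight_tube_truth):
        solid = ph.render(straight_tube_truth, spacing_um=(1, 1, 1)).voxels > 0
        hollow = ph.render(straight_tube_truth, spacing_um=(1, 1, 1),
                           mode="hollow", wall_um=1.0).voxels > 0
        assert not (hollow & ~solid).any()          # shell ⊂ solid
        assert not hollow[50, 50, 50]               # lumen voxel is background
        assert hollow.sum() < solid.sum()

    def test_zero_noise_render_is_binary(self, straight_tube_truth):
        vol = ph.render(straight_tube_truth, spacing_um=(1, 1, 1), peak=200.0)
        assert set(np.unique(vol.voxels)) == {0.0, 200.0}

    def test_render_determinism_with_noise(self, network_truth):
        kw = dict(spacing_um=(2, 1, 1), blur_sigma_um=1.0,
                  noise=ph.NoiseModel(), seed=3)
        a = ph.render(network_truth, **kw)
        b = ph.render(network_truth, **kw)
        assert np.array_equal(a.voxels, b.voxels)

    def test_voxel_count_converges_with_spacing(self, straight_tube_truth):
        analytic = math.pi * 4.0 ** 2 * 80.0
        errors = []
        for s in (2.0, 1.0, 0.5):
            vol = ph.render(straight_tube_truth, spacing_um=(s, s, s))
            measured = float((vol.voxels > 0).sum()) * s ** 3
            errors.append(abs(measured - analytic) / analytic)
        assert errors[0] >= errors[1] >= errors[2]

    def test_thin_tube_warns_and_rasterizes(self):
        truth = ph.PhantomTruth(
            segments=[ph.TubeSegment.straight((20, 20, 5), (20, 20, 35), 0.7)],
            roi_extent_um=(40, 40, 40))
        with pytest.warns(UserWarning, match="thinner than one voxel"):
            vol = ph.render(truth, spacing_um=(2.0, 2.0, 2.0))
        assert (vol.voxels > 0).sum() >= 15  # at least one voxel per step


class TestTruthMetrics:
    def test_single_tube_hand_computed_densities(self):
        truth = ph.PhantomTruth(
            segments=[ph.TubeSegment.straight((50, 50, 0), (50, 50, 100), 4.0)],
            roi_extent_um=(100.0, 100.0, 100.0))
        rep = ph.truth_metrics(truth)
        assert rep.length_density_um_per_um3 == pytest.approx(100 / 1e6)
        assert rep.branch_density_per_um3 * 1e6 == pytest.approx(1.0)
        assert rep.n_junctions == 0
        assert rep.mean_tortuosity == pytest.approx(1.0)
        assert rep.mean_diameter_um == pytest.approx(8.0)
        assert rep.volume_density == pytest.approx(math.pi * 16 * 100 / 1e6)

    def test_semicircle_tortuosity_is_half_pi(self, semicircle_truth):
        rep = ph.truth_metrics(semicircle_truth)
        assert rep.mean_tortuosity == pytest.approx(math.pi / 2, rel=1e-12)

    def test_y_tree_branch_and_junction_densities(self, y_tree_truth):
        rep = ph.truth_metrics(y_tree_truth)
        assert rep.n_branches == 3
        assert rep.n_junctions == 1

    def test_per_class_length_densities_sum_to_total(self, network_truth):
        rep = ph.truth_metrics(network_truth)
        total = sum(rep.per_class[c].length_density_um_per_um3
                    for c in CALIBER_CLASSES)
        assert total == pytest.approx(rep.length_density_um_per_um3, abs=1e-15)


class TestPlaceSpots:
    def test_planned_distances_give_expected_labels(self):
        # one small tube only: 5 µm away -> small; 15 µm away -> unassociated
        truth = ph.PhantomTruth(
            segments=[ph.TubeSegment.straight((50, 50, 10), (50, 50, 90), 1.5)],
            roi_extent_um=(100.0, 100.0, 100.0))
        out = ph.place_spots(truth, distance_plan=[("small", 5.0),
                                                  ("unassociated", 15.0)],
                             seed=2)
        assert [s.label for s in out.spots] == ["small", "unassociated"]
        assert out.spots[0].distances_um["small"] == pytest.approx(5.0, abs=1e-9)
        assert out.spots[1].distances_um["small"] == pytest.approx(15.0, abs=1e-9)

    def test_boundary_distance_10um_is_associated(self):
        truth = ph.PhantomTruth(
            segments=[ph.TubeSegment.straight((50, 50, 10), (50, 50, 90), 1.5)],
            roi_extent_um=(100.0, 100.0, 100.0))
        out = ph.place_spots(truth, distance_plan=[("small", 10.0)], seed=4)
        assert out.spots[0].label == "small"
        assert out.spots[0].distances_um["small"] == pytest.approx(10.0, abs=1e-9)

    def test_infeasible_placement_raises(self):
        truth = ph.PhantomTruth(
            segments=[ph.TubeSegment.straight((20, 20, 5), (20, 20, 35), 1.5)],
            roi_extent_um=(40.0, 40.0, 40.0))
        with pytest.raises(ph.SpotPlacementError):
            # no large-class tube exists
            ph.place_spots(truth, distance_plan=[("large", 5.0)], seed=0)

    def test_recorded_distances_match_analytic_recomputation(self, network_truth):
        out = ph.place_spots(network_truth, n_spots=10, seed=8)
        for spot in out.spots:
            again = network_truth.surface_distances(spot.center_um)
            for label in CALIBER_CLASSES:
                a, b = spot.distances_um[label], again[label]
                assert (math.isinf(a) and math.isinf(b)) or a == pytest.approx(b, abs=1e-12)


class TestTruthIO:
    def test_json_roundtrip_preserves_truth(self, tmp_path, network_truth):
        p = tmp_path / "truth.json"
        out = ph.place_spots(network_truth, n_spots=3, seed=1)
        out.save(p)
        back = ph.PhantomTruth.load(p)
        assert len(back.segments) == len(out.segments)
        assert back.n_junctions == out.n_junctions
        assert [s.label for s in back.spots] == [s.label for s in out.spots]
        a, b = out.segments[0], back.segments[0]
        assert np.allclose(a.p0, b.p0) and a.radius_um == b.radius_um
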