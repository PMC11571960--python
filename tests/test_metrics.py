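"""Network metrics: hand-computed values, caliber classification, and the
stratification partition identity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microvasc import phantom as ph
from microvasc.graph import extract_graph
from microvasc.metrics import (
    classify_caliber,
    compute_metrics,
    stratified_metrics,
    build_report,
    CALIBER_CLASSES,
)
from microvasc.volume import BinaryMask


class TestClassifyCaliber:
    @pytest.mark.parametrize("diameter, expected", [
        (3.2, "small"),
        (4.7, "intermediate"),
        (6.0, "large"),
        (4.0, "intermediate"),   # boundary: closed interval
        (5.4, "intermediate"),   # boundary: closed interval
        (3.999999, "small"),
        (5.400001, "large"),
    ])
    def test_bounds(self, diameter, expected):
        assert classify_caliber(diameter) == expected

    @pytest.mark.parametrize("bad", [0.0, -1.0, math.inf, math.nan])
    def test_invalid_diameters_raise(self, bad):
        with pytest.raises(ValueError):
            classify_caliber(bad)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=1e-6, max_value=1e3,
                     allow_nan=False, allow_infinity=False))
    def test_every_positive_diameter_maps_to_exactly_one_class(self, d):
        assert classify_caliber(d) in CALIBER_CLASSES


class TestComputeMetrics:
    def test_single_tube_hand_computed(self):
        truth = ph.PhantomTruth(
            segments=[ph.TubeSegment.straight((50, 50, 0), (50, 50, 100), 2.5)],
            roi_extent_um=(100.0, 100.0, 100.0))
        mask = BinaryMask(ph.render(truth, spacing_um=(1, 1, 1)).voxels > 0,
                          (1, 1, 1))
        sg, _ = extract_graph(mask)
        rep = compute_metrics(sg, mask)
        assert rep.length_density_um_per_um3 == pytest.approx(1e-4, rel=0.05)
        assert rep.branch_density_per_um3 * 1e6 == pytest.approx(1.0)
        assert rep.length_density_mm_per_mm3 == pytest.approx(
            rep.length_density_um_per_um3 * 1e6)

    def test_cylinder_volume_density_analytic(self):
        truth = ph.PhantomTruth(
            segments=[ph.TubeSegment.straight((50, 50, 0), (50, 50, 100), 5.0)],
            roi_extent_um=(100.0, 100.0, 100.0))
        mask = BinaryMask(ph.render(truth, spacing_um=(1, 1, 1)).voxels > 0,
                          (1, 1, 1))
        sg, _ = extract_graph(mask)
        rep = compute_metrics(sg, mask)
        assert rep.volume_density == pytest.approx(math.pi * 25 * 100 / 1e6,
                                                   rel=0.1)

    def test_empty_mask_gives_zero_densities_and_absent_means(self):
        mask = BinaryMask(np.zeros((20, 20, 20), bool), (1, 1, 1))
        sg, _ = extract_graph(mask)
        rep = compute_metrics(sg, mask)
        assert rep.length_density_um_per_um3 == 0.0
        assert rep.branch_density_per_um3 == 0.0
        assert rep.volume_density == 0.0
        assert rep.mean_branch_length_um is None
        assert rep.mean_tortuosity is None
        assert rep.mean_diameter_um is None

    def test_scale_equivariance_of_densities(self):
        lengths, torts, diams = [30.0, 50.0], [1.0, 1.2], [3.0, 6.0]
        r1 = build_report(lengths, torts, diams, n_junctions=2,
                          vessel_volume_um3=500.0, roi_volume_um3=1e6)
        r2 = build_report(lengths, torts, diams, n_junctions=2,
                          vessel_volume_um3=500.0, roi_volume_um3=2e6)
        assert r2.length_density_um_per_um3 == pytest.approx(
            r1.length_density_um_per_um3 / 2)
        assert r2.branching_point_density_per_um3 == pytest.approx(
            r1.branching_point_density_per_um3 / 2)
        assert r2.branch_density_per_um3 == pytest.approx(
            r1.branch_density_per_um3 / 2)
        assert r2.volume_density == pytest.approx(r1.volume_density / 2)

    def test_cycle_branches_excluded_from_tortuosity_mean(self):
        rep = build_report([10.0, 20.0], [1.5, math.nan], [3.0, 3.0],
                           n_junctions=0, vessel_volume_um3=10.0,
                           roi_volume_um3=1e6)
        assert rep.mean_tortuosity == pytest.approx(1.5)
        assert rep.n_branches == 2

    def test_length_weighted_mean_diameter(self):
        rep = build_report([10.0, 30.0], [1.0, 1.0], [2.0, 6.0],
                           n_junctions=0, vessel_volume_um3=1.0,
                           roi_volume_um3=1e6)
        assert rep.mean_diameter_um == pytest.approx((10 * 2 + 30 * 6) / 40)
        assert rep.mean_diameter_unweighted_um == pytest.approx(4.0)


class TestStratification:
    def test_three_tube_classes_equal_branch_density(self):
        segs, y = [], 15.0
        for r in (1.5, 2.5, 3.5):          # diameters 3, 5, 7 µm
            segs.append(ph.TubeSegment.straight((25, y, 10), (25, y, 90), r))
            y += 20
        truth = ph.PhantomTruth(segments=segs, roi_extent_um=(50, 70, 100))
        mask = BinaryMask(ph.render(truth, spacing_um=(1, 1, 1)).voxels > 0,
                          (1, 1, 1))
        sg, _ = extract_graph(mask)
        per = stratified_metrics(sg, roi_volume_um3=truth.roi_volume_um3)
        counts = [per[c].n_branches for c in CALIBER_CLASSES]
        assert counts == [1, 1, 1]

    def test_partition_identity_is_exact(self, network_mask):
        sg, _ = extract_graph(network_mask)
        rep = compute_metrics(sg, network_mask)
        assert sum(rep.per_class[c].length_density_um_per_um3
                   for c in CALIBER_CLASSES) == pytest.approx(
            rep.length_density_um_per_um3, abs=1e-15)
        assert sum(rep.per_class[c].n_branches
                   for c in CALIBER_CLASSES) == rep.n_branches

    def test_caliber_length_composition_recovered(self):
        # length split designed as 15% small / 80% intermediate / 5% large,
        # the composition reported for healthy cortex
        rng = np.random.default_rng(5)
        segs = []
        y = 12.0
        plan = [("small", 1.6, 3), ("intermediate", 2.35, 16), ("large", 3.2, 1)]
        for _, r, n in plan:
            for _ in range(n):
                off = rng.uniform(-0.4, 0.4, 2)
                segs.append(ph.TubeSegment.straight(
                    (25 + off[0], y + off[1], 10), (25 + off[0], y + off[1], 60), r))
                y += 11
        truth = ph.PhantomTruth(segments=segs, roi_extent_um=(50, y + 5, 70))
        true_rep = ph.truth_metrics(truth)
        true_frac = {c: true_rep.per_class[c].length_um / true_rep.total_length_um
                     for c in CALIBER_CLASSES}
        assert true_frac["small"] == pytest.approx(0.15, abs=0.001)
        assert true_frac["intermediate"] == pytest.approx(0.80, abs=0.001)
        assert true_frac["large"] == pytest.approx(0.05, abs=0.001)

        mask = BinaryMask(ph.render(truth, spacing_um=(1, 1, 1)).voxels > 0,
                          (1, 1, 1))
        sg, _ = extract_graph(mask)
        rep = compute_metrics(sg, mask)
        for c in CALIBER_CLASSES:
            frac = rep.per_class[c].length_um / rep.total_length_um
            assert frac == pytest.approx(true_frac[c], abs=0.05)

    def test_report_frame_has_all_class_rows(self, network_mask):
        sg, _ = extract_graph(network_mask)
        rep = compute_metrics(sg, network_mask)
        df = rep.to_frame(sample="s", roi="r")
        assert list(df["caliber_class"]) == ["all", *CALIBER_CLASSES]
        for col in ("length_density_mm_per_mm3", "branch_density_per_mm3",
                    "mean_branch_length_um", "mean_tortuosity"):
            assert col in df.columns
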