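"""Network metrics for a vascular ROI, overall and stratified by caliber.

The seven characteristics reported per ROI:

(a) length density        — total centerline length per ROI volume
(b) branching-point density — junction count per ROI volume
(c) volume density        — vessel (foreground) volume fraction
(d) branch density        — branch count per ROI volume
(e) mean branch length    — mean centerline length between nodes, µm
(f) mean tortuosity       — branch length / end-to-end chord, over branches
                            with a nonzero chord
(g) mean diameter         — length-weighted mean branch diameter, µm

Stratification uses three caliber classes of mean branch diameter d:
small d < 4 µm, intermediate 4 ≤ d ≤ 5.4 µm, large d > 5.4 µm. The classes
partition (0, ∞); both printed bounds belong to the intermediate class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Caliber class labels in canonical order.
CALIBER_CLASSES = ("small", "intermediate", "large")

#: Diameter bounds (µm): small < SMALL_MAX <= intermediate <= LARGE_MIN < large.
SMALL_MAX_UM = 4.0
LARGE_MIN_UM = 5.4


def classify_caliber(diameter_um: float) -> str:
    """Map a vessel diameter (µm) to its caliber class.

    Bounds: small < 4 µm, intermediate 4–5.4 µm (closed interval),
    large > 5.4 µm. Raises ``ValueError`` for non-positive or non-finite
    diameters.
    """
    d = float(diameter_um)
    if not math.isfinite(d) or d <= 0:
        raise ValueError(f"diameter must be positive and finite, got {diameter_um!r}")
    if d < SMALL_MAX_UM:
        return "small"
    if d <= LARGE_MIN_UM:
        return "intermediate"
    return "large"


@dataclass
class ClassMetrics:
    """Per-caliber-class slice of a :class:`MetricsReport`."""

    n_branches: int
    length_um: float
    length_density_um_per_um3: float
    branch_density_per_mm3: float
    mean_branch_length_um: float | None
    mean_tortuosity: float | None

    @property
    def length_density_mm_per_mm3(self) -> float:
        # µm/µm³ · 1e9 µm³/mm³ · 1e-3 mm/µm = ×1e6
        return self.length_density_um_per_um3 * 1e6


@dataclass
class MetricsReport:
    """Network characteristics of one ROI.

    Densities are stored in µm-based units with mm-based conversions exposed
    as properties; the tidy-CSV export carries explicit unit columns.
    Means over an empty branch set are ``None`` (absent), never zero.
    """

    roi_volume_um3: float
    total_length_um: float
    n_junctions: int
    n_branches: int
    vessel_volume_um3: float
    length_density_um_per_um3: float
    branching_point_density_per_um3: float
    volume_density: float
    branch_density_per_um3: float
    mean_branch_length_um: float | None
    mean_tortuosity: float | None
    mean_diameter_um: float | None          # length-weighted
    mean_diameter_unweighted_um: float | None
    per_class: dict[str, ClassMetrics] = field(default_factory=dict)

    @property
    def length_density_mm_per_mm3(self) -> float:
        return self.length_density_um_per_um3 * 1e6

    @property
    def branching_point_density_per_mm3(self) -> float:
        return self.branching_point_density_per_um3 * 1e9

    @property
    def branch_density_per_mm3(self) -> float:
        return self.branch_density_per_um3 * 1e9

    def to_frame(self, sample: str = "sample", roi: str = "roi") -> pd.DataFrame:
        """One tidy row per class in {all, small, intermediate, large}."""
        rows = [{
            "sample": sample,
            "roi": roi,
            "caliber_class": "all",
            "roi_volume_um3": self.roi_volume_um3,
            "n_branches": self.n_branches,
            "n_junctions": self.n_junctions,
            "total_length_um": self.total_length_um,
            "length_density_um_per_um3": self.length_density_um_per_um3,
            "length_density_mm_per_mm3": self.length_density_mm_per_mm3,
            "branching_point_density_per_mm3": self.branching_point_density_per_mm3,
            "volume_density_fraction": self.volume_density,
            "branch_density_per_mm3": self.branch_density_per_mm3,
            "mean_branch_length_um": self.mean_branch_length_um,
            "mean_tortuosity": self.mean_tortuosity,
            "mean_diameter_um": self.mean_diameter_um,
            "mean_diameter_unweighted_um": self.mean_diameter_unweighted_um,
        }]
        for label in CALIBER_CLASSES:
            cm = self.per_class.get(label)
            if cm is None:
                continue
            rows.append({
                "sample": sample,
                "roi": roi,
                "caliber_class": label,
                "roi_volume_um3": self.roi_volume_um3,
                "n_branches": cm.n_branches,
                "n_junctions": np.nan,
                "total_length_um": cm.length_um,
                "length_density_um_per_um3": cm.length_density_um_per_um3,
                "length_density_mm_per_mm3": cm.length_density_mm_per_mm3,
                "branching_point_density_per_mm3": np.nan,
                "volume_density_fraction": np.nan,
                "branch_density_per_mm3": cm.branch_density_per_mm3,
                "mean_branch_length_um": cm.mean_branch_length_um,
                "mean_tortuosity": cm.mean_tortuosity,
                "mean_diameter_um": np.nan,
                "mean_diameter_unweighted_um": np.nan,
            })
        return pd.DataFrame(rows)


def _safe_mean(values) -> float | None:
    values = np.asarray(values, dtype=float)
    return float(values.mean()) if values.size else None


def build_report(
    branch_lengths_um,
    branch_tortuosities,
    branch_diameters_um,
    n_junctions: int,
    vessel_volume_um3: float,
    roi_volume_um3: float,
) -> MetricsReport:
    """Assemble a :class:`MetricsReport` from per-branch geometry.

    ``branch_tortuosities`` may contain NaN for cycle branches whose two
    endpoints coincide (zero chord): those are excluded from tortuosity
    means but still counted as branches.
    """
    if roi_volume_um3 <= 0:
        raise ValueError("roi_volume_um3 must be positive")
    lengths = np.asarray(branch_lengths_um, dtype=float)
    torts = np.asarray(branch_tortuosities, dtype=float)
    diams = np.asarray(branch_diameters_um, dtype=float)
    if not (lengths.shape == torts.shape == diams.shape):
        raise ValueError("per-branch arrays must have identical length")
    n = lengths.size
    total_length = float(lengths.sum())
    finite_t = torts[np.isfinite(torts)]
    total_weight = lengths.sum()

    report = MetricsReport(
        roi_volume_um3=float(roi_volume_um3),
        total_length_um=total_length,
        n_junctions=int(n_junctions),
        n_branches=int(n),
        vessel_volume_um3=float(vessel_volume_um3),
        length_density_um_per_um3=total_length / roi_volume_um3,
        branching_point_density_per_um3=n_junctions / roi_volume_um3,
        volume_density=float(vessel_volume_um3) / roi_volume_um3,
        branch_density_per_um3=n / roi_volume_um3,
        mean_branch_length_um=_safe_mean(lengths),
        mean_tortuosity=_safe_mean(finite_t),
        mean_diameter_um=(float((lengths * diams).sum() / total_weight)
                          if n and total_weight > 0 else None),
        mean_diameter_unweighted_um=_safe_mean(diams) if n else None,
    )

    labels = np.array([classify_caliber(d) for d in diams]) if n else np.array([])
    for label in CALIBER_CLASSES:
        sel = labels == label
        sel_lengths = lengths[sel]
        sel_t = torts[sel]
        sel_t = sel_t[np.isfinite(sel_t)]
        report.per_class[label] = ClassMetrics(
            n_branches=int(sel.sum()),
            length_um=float(sel_lengths.sum()),
            length_density_um_per_um3=float(sel_lengths.sum()) / roi_volume_um3,
            branch_density_per_mm3=float(sel.sum()) / roi_volume_um3 * 1e9,
            mean_branch_length_um=_safe_mean(sel_lengths),
            mean_tortuosity=_safe_mean(sel_t),
        )
    return report


def compute_metrics(graph, mask=None, roi_volume_um3: float | None = None) -> MetricsReport:
    """Metrics (a)–(g) with per-caliber stratification for one ROI.

    Parameters
    ----------
    graph : SkeletonGraph
        Pruned vascular graph of the ROI.
    mask : BinaryMask, optional
        Solid segmentation on the same grid; supplies the vessel volume for
        the volume-density metric. If omitted, volume density is 0.
    roi_volume_um3 : float, optional
        Defaults to the physical extent of ``mask`` (or of the graph's
        source grid).
    """
    branches = graph.branches
    if roi_volume_um3 is None:
        if mask is not None:
            roi_volume_um3 = float(np.prod(mask.extent_um))
        elif graph.roi_volume_um3 is not None:
            roi_volume_um3 = graph.roi_volume_um3
        else:
            raise ValueError("roi_volume_um3 required when no mask is given")
    vessel_volume = mask.foreground_volume_um3 if mask is not None else 0.0
    return build_report(
        branch_lengths_um=[b.length_um for b in branches],
        branch_tortuosities=[b.tortuosity for b in branches],
        branch_diameters_um=[b.mean_diameter_um for b in branches],
        n_junctions=graph.n_junctions,
        vessel_volume_um3=vessel_volume,
        roi_volume_um3=roi_volume_um3,
    )


def stratified_metrics(graph, roi_volume_um3: float) -> dict[str, ClassMetrics]:
    """Per-caliber sub-reports only (length/branch density, mean branch
    length, mean tortuosity), keyed by class label."""
    report = compute_metrics(graph, mask=None, roi_volume_um3=roi_volume_um3)
    return report.per_class
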