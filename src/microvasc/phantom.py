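"""Synthetic vascular phantoms with analytic ground truth.

A phantom is a set of tubes (straight segments or circular arcs, each of
constant radius) inside an ROI box, together with the junctions where tubes
meet. From the same truth one can rasterize either a *solid* render (the
lumen-filled appearance of intravascular hydrogel labeling) or a *hollow*
render (the wall-only appearance of antibody labeling), add PSF blur and
camera noise, and compute every network metric analytically — which makes
the whole downstream pipeline testable without any acquired data.

Geometry conventions follow :mod:`microvasc.volume`: axis order (z, y, x),
coordinates and radii in µm, voxel centers at (index + 0.5) · spacing.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

from microvasc.volume import Volume3D, BinaryMask
from microvasc.metrics import MetricsReport, build_report, classify_caliber, CALIBER_CLASSES
from microvasc.spots import Spot

JUNCTION_TOL_UM = 0.1  # endpoint coincidence tolerance for junction detection


class PhantomError(Exception):
    """Base error for phantom construction."""


class PhantomTooDenseError(PhantomError):
    """Rejection sampling could not place the requested network."""


class SpotPlacementError(PhantomError):
    """A requested spot placement is infeasible inside the ROI."""


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis``."""
    axis = _unit(np.asarray(axis, dtype=float))
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


@dataclass
class TubeSegment:
    """One tube of constant radius: a straight segment or a circular arc.

    ``p0``/``p1`` are the centerline endpoints in (z,y,x) µm. For arcs,
    ``arc_center`` and unit ``arc_axis`` define the supporting circle and
    ``arc_span`` the swept angle in (0, 2π); ``p1`` is derived from ``p0``.
    """

    p0: np.ndarray
    p1: np.ndarray
    radius_um: float
    arc_center: np.ndarray | None = None
    arc_axis: np.ndarray | None = None
    arc_span: float | None = None

    def __post_init__(self):
        self.p0 = np.asarray(self.p0, dtype=float)
        self.p1 = np.asarray(self.p1, dtype=float)
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        if self.is_arc:
            if not (0 < self.arc_span < 2 * math.pi):
                raise ValueError("arc span must lie in (0, 2π)")
            self.arc_center = np.asarray(self.arc_center, dtype=float)
            self.arc_axis = _unit(np.asarray(self.arc_axis, dtype=float))
        elif np.allclose(self.p0, self.p1):
            raise ValueError("straight segment endpoints must differ")

    @property
    def is_arc(self) -> bool:
        return self.arc_center is not None

    @classmethod
    def straight(cls, p0, p1, radius_um: float) -> "TubeSegment":
        return cls(p0=np.asarray(p0, float), p1=np.asarray(p1, float), radius_um=radius_um)

    @classmethod
    def arc(cls, center, axis, p0, span: float, radius_um: float) -> "TubeSegment":
        center = np.asarray(center, dtype=float)
        p0 = np.asarray(p0, dtype=float)
        p1 = center + _rotate(p0 - center, axis, span)
        return cls(p0=p0, p1=p1, radius_um=radius_um,
                   arc_center=center, arc_axis=np.asarray(axis, float), arc_span=span)

    @property
    def arc_radius_um(self) -> float:
        return float(np.linalg.norm(self.p0 - self.arc_center)) if self.is_arc else math.nan

    def length_um(self) -> float:
        if self.is_arc:
            return self.arc_radius_um * self.arc_span
        return float(np.linalg.norm(self.p1 - self.p0))

    def chord_um(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    def tortuosity(self) -> float:
        chord = self.chord_um()
        return self.length_um() / chord if chord > 0 else math.nan

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.radius_um

    def polyline(self, step_um: float = 0.2) -> np.ndarray:
        """Centerline sampled as an (n, 3) polyline; exact for straight tubes."""
        if not self.is_arc:
            return np.stack([self.p0, self.p1])
        r = self.arc_radius_um
        n = max(int(math.ceil(self.arc_span * r / step_um)), 8)
        angles = np.linspace(0.0, self.arc_span, n + 1)
        v0 = self.p0 - self.arc_center
        pts = np.stack([self.arc_center + _rotate(v0, self.arc_axis, a) for a in angles])
        return pts

    def distance_to_centerline(self, points: np.ndarray, step_um: float = 0.05) -> np.ndarray:
        """Distance from (n,3) points to the centerline curve (µm).

        Exact for straight segments; arcs use a fine polyline (chord error
        ≤ step²/8r, negligible at the default step).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if not self.is_arc:
            return _dist_point_segment(points, self.p0, self.p1)
        poly = self.polyline(step_um=step_um)
        return _dist_points_polyline(points, poly)

    def signed_field(self, points: np.ndarray) -> np.ndarray:
        """Inside/outside indicator field for rasterization (≤ 0 inside).

        Straight tubes are *flat-capped* finite cylinders (volume exactly
        π r² L): the field is max(radial distance − r, axial overshoot),
        which has the correct sign everywhere and, inside, equals minus the
        distance to the nearest surface (lateral wall or cap plane) — so the
        (−wall, 0] band is a closed shell including the end disks. Arcs use
        the capsule field (centerline distance − r).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.is_arc:
            return self.distance_to_centerline(points) - self.radius_um
        ab = self.p1 - self.p0
        L = float(np.linalg.norm(ab))
        d = ab / L
        s = (points - self.p0) @ d                     # axial coordinate, µm
        radial = np.linalg.norm(points - self.p0 - s[:, None] * d, axis=1)
        ax_out = np.maximum(-s, s - L)                 # negative inside
        return np.maximum(radial - self.radius_um, ax_out)

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance from points to the tube surface (negative inside).

        Uses the capsule distance (to the centerline segment minus radius),
        which equals the cylinder surface distance except within one radius
        of the tube ends.
        """
        return self.distance_to_centerline(points) - self.radius_um


def _dist_point_segment(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(np.dot(ab, ab))
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def _dist_points_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    best = np.full(len(points), np.inf)
    for a, b in zip(poly[:-1], poly[1:]):
        np.minimum(best, _dist_point_segment(points, a, b), out=best)
    return best


def _dist_segment_segment(a0, a1, b0, b1) -> float:
    """Minimum distance between two 3D line segments."""
    d1, d2 = a1 - a0, b1 - b0
    r = a0 - b0
    a = np.dot(d1, d1)
    e = np.dot(d2, d2)
    f = np.dot(d2, r)
    c = np.dot(d1, r)
    b = np.dot(d1, d2)
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
    t = (b * s + f) / e
    if t < 0.0:
        t = 0.0
        s = np.clip(-c / a, 0.0, 1.0)
    elif t > 1.0:
        t = 1.0
        s = np.clip((b - c) / a, 0.0, 1.0)
    pa = a0 + s * d1
    pb = b0 + t * d2
    return float(np.linalg.norm(pa - pb))


@dataclass
class Junction:
    """A point where >= 3 tube endpoints coincide."""

    position_um: np.ndarray
    segment_ids: list[int]
    radii_um: list[float]

    @property
    def degree(self) -> int:
        return len(self.segment_ids)


def junctions_from_segments(segments, tol_um: float = JUNCTION_TOL_UM) -> list[Junction]:
    """Cluster coincident segment endpoints; clusters of >= 3 are junctions."""
    endpoints = []  # (point, segment_id, radius)
    for i, seg in enumerate(segments):
        endpoints.append((seg.p0, i, seg.radius_um))
        endpoints.append((seg.p1, i, seg.radius_um))
    used = np.zeros(len(endpoints), dtype=bool)
    junctions = []
    pts = np.array([e[0] for e in endpoints]) if endpoints else np.empty((0, 3))
    for i in range(len(endpoints)):
        if used[i]:
            continue
        d = np.linalg.norm(pts - pts[i], axis=1)
        members = np.where((d <= tol_um) & ~used)[0]
        used[members] = True
        if len(members) >= 3:
            junctions.append(Junction(
                position_um=pts[members].mean(axis=0),
                segment_ids=[endpoints[m][1] for m in members],
                radii_um=[endpoints[m][2] for m in members],
            ))
    return junctions


@dataclass
class PhantomTruth:
    """Generative description of a synthetic network with known metrics.

    ``roi_extent_um`` is the (z, y, x) size of the ROI box in µm; all
    centerlines lie inside it. Junctions are derived from coincident
    endpoints (tolerance 0.1 µm) unless supplied.
    """

    segments: list[TubeSegment]
    roi_extent_um: tuple[float, float, float]
    junctions: list[Junction] = None
    spots: list[Spot] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self):
        self.roi_extent_um = tuple(float(e) for e in self.roi_extent_um)
        if any(e <= 0 for e in self.roi_extent_um):
            raise ValueError("roi_extent_um must be positive")
        if self.junctions is None:
            self.junctions = junctions_from_segments(self.segments)
        ext = np.asarray(self.roi_extent_um)
        for seg in self.segments:
            for p in seg.polyline(step_um=1.0):
                if np.any(p < -1e-9) or np.any(p > ext + 1e-9):
                    raise ValueError("segment centerline leaves the ROI box")
        for spot in self.spots:
            if spot.diameter_um <= 0:
                raise ValueError("spot diameters must be positive")

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    @property
    def roi_volume_um3(self) -> float:
        return float(np.prod(self.roi_extent_um))

    def caliber_of(self, segment: TubeSegment) -> str:
        return classify_caliber(segment.diameter_um)

    def surface_distances(self, point) -> dict[str, float]:
        """Exact surface distance (µm) from a point to the nearest tube of
        each caliber class (inf if the class is absent)."""
        point = np.asarray(point, dtype=float)[None, :]
        out = {label: math.inf for label in CALIBER_CLASSES}
        for seg in self.segments:
            label = self.caliber_of(seg)
            d = float(seg.surface_distance(point)[0])
            out[label] = min(out[label], d)
        return out

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        def seg_dict(s: TubeSegment):
            d = {"p0": s.p0.tolist(), "p1": s.p1.tolist(), "radius_um": s.radius_um}
            if s.is_arc:
                d.update(arc_center=s.arc_center.tolist(),
                         arc_axis=s.arc_axis.tolist(), arc_span=s.arc_span)
            return d

        return {
            "roi_extent_um": list(self.roi_extent_um),
            "rng_seed": int(self.rng_seed),
            "segments": [seg_dict(s) for s in self.segments],
            "junctions": [{"position_um": j.position_um.tolist(),
                           "segment_ids": j.segment_ids} for j in self.junctions],
            "spots": [s.to_dict() for s in self.spots],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomTruth":
        segments = []
        for s in d["segments"]:
            if "arc_center" in s:
                segments.append(TubeSegment.arc(s["arc_center"], s["arc_axis"],
                                                s["p0"], s["arc_span"], s["radius_um"]))
            else:
                segments.append(TubeSegment.straight(s["p0"], s["p1"], s["radius_um"]))
        spots = [Spot.from_dict(sd) for sd in d.get("spots", [])]
        return cls(segments=segments, roi_extent_um=tuple(d["roi_extent_um"]),
                   spots=spots, rng_seed=d.get("rng_seed", 0))

    @classmethod
    def load(cls, path: str | Path) -> "PhantomTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Network sampling
# ---------------------------------------------------------------------------

def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(d, helper))
    e2 = np.cross(d, e1)
    return e1, e2


def _clearance_ok(cand_p0, cand_p1, cand_r, segments, shared_point, gap_um) -> bool:
    """Candidate centerline must keep its distance from every existing tube.

    Non-adjacent tubes: centerline clearance >= r_cand + r_other + gap.
    Tubes sharing an endpoint: the same clearance must hold once both
    centerlines are trimmed away from the shared point, so tubes overlap
    only inside the junction ball.
    """
    for seg in segments:
        req = cand_r + seg.radius_um + gap_um
        shares = shared_point is not None and (
            np.linalg.norm(seg.p0 - shared_point) < 1e-6
            or np.linalg.norm(seg.p1 - shared_point) < 1e-6
        )
        a0, a1 = cand_p0, cand_p1
        b0, b1 = seg.p0, seg.p1
        if shares:
            trim = min(2.0 * req, 0.45 * min(np.linalg.norm(a1 - a0),
                                             np.linalg.norm(b1 - b0)))
            da = _unit(a1 - a0)
            if np.linalg.norm(a0 - shared_point) < 1e-6:
                a0 = a0 + trim * da
            else:
                a1 = a1 - trim * da
            db = _unit(b1 - b0)
            if np.linalg.norm(b0 - shared_point) < 1e-6:
                b0 = b0 + trim * db
            else:
                b1 = b1 - trim * db
        if _dist_segment_segment(a0, a1, b0, b1) < req:
            return False
    return True


def sample_network(
    n_segments: int,
    roi_extent_um=(600.0, 305.0, 305.0),
    radius_range_um=(2.0, 3.2),
    branching_prob: float = 0.7,
    seed: int = 0,
    length_range_um=(25.0, 80.0),
    min_junctions: int = 0,
    min_junction_sep_um: float = 12.0,
    clearance_gap_um: float = 4.0,
    max_attempts_factor: int = 400,
) -> PhantomTruth:
    """Grow a random branching tube network inside an ROI box.

    Growth alternates between seeding isolated root tubes and bifurcating at
    an existing tube tip (probability ``branching_prob``); every bifurcation
    creates one degree-3 junction. Candidate tubes are rejection-sampled
    against containment, inter-tube clearance and junction separation until
    ``n_segments`` tubes (and at least ``min_junctions`` junctions) exist.

    Raises :class:`PhantomTooDenseError` when the attempt budget
    (``max_attempts_factor`` · ``n_segments``) is exhausted — the requested
    network does not fit the box.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    r_lo, r_hi = radius_range_um
    if not (0.5 < r_lo <= r_hi < 10.0):
        raise ValueError("radius_range_um must lie within (0.5, 10) µm")
    ext = np.asarray(roi_extent_um, dtype=float)
    if np.any(ext <= 0):
        raise ValueError("roi_extent_um must be positive")
    margin = r_hi + 2.0
    if np.any(ext - 2 * margin < length_range_um[0]):
        raise ValueError("ROI too small for the requested tube lengths and radii")

    rng = np.random.default_rng(seed)
    segments: list[TubeSegment] = []
    junction_pts: list[np.ndarray] = []
    tips: list[dict] = []  # {"point","direction"} — growable endpoints
    lo, hi = margin, ext - margin

    def inside(p):
        return np.all(p >= lo) and np.all(p <= hi)

    attempts = 0
    max_attempts = max_attempts_factor * max(n_segments, 1)
    while len(segments) < n_segments or len(junction_pts) < min_junctions:
        attempts += 1
        if attempts > max_attempts:
            raise PhantomTooDenseError(
                f"phantom too dense: gave up after {attempts - 1} attempts with "
                f"{len(segments)} segments and {len(junction_pts)} junctions placed"
            )
        need_junctions = len(junction_pts) < min_junctions and len(segments) + 2 > n_segments
        do_branch = bool(tips) and (need_junctions or rng.random() < branching_prob)
        if do_branch:
            tip_idx = int(rng.integers(len(tips)))
            tip = tips[tip_idx]
            p = tip["point"]
            if any(np.linalg.norm(p - q) < min_junction_sep_um for q in junction_pts):
                continue
            dp = tip["direction"]
            e1, e2 = _perp_basis(dp)
            children = []
            ok = True
            for _ in range(2):
                theta = rng.uniform(math.radians(20), math.radians(50))
                phi = rng.uniform(0, 2 * math.pi)
                d = math.cos(theta) * dp + math.sin(theta) * (math.cos(phi) * e1 + math.sin(phi) * e2)
                L = rng.uniform(*length_range_um)
                r = rng.uniform(r_lo, r_hi)
                p1 = p + L * d
                if not inside(p1):
                    ok = False
                    break
                children.append((p1, r, d))
            if not ok or len(children) < 2:
                continue
            d0, d1 = children[0][2], children[1][2]
            if np.dot(d0, d1) > math.cos(math.radians(40)):
                continue  # children too parallel
            cand_segs: list[TubeSegment] = []
            for p1, r, _ in children:
                if not _clearance_ok(p, p1, r, segments + cand_segs,
                                     shared_point=p, gap_um=clearance_gap_um):
                    ok = False
                    break
                cand_segs.append(TubeSegment.straight(p, p1, r))
            if not ok:
                continue
            for cand in cand_segs:
                segments.append(cand)
                tips.append({"point": cand.p1, "direction": _unit(cand.p1 - cand.p0)})
            junction_pts.append(p.copy())
            tips.pop(tip_idx)
        else:
            p0 = rng.uniform(lo, hi)
            d = _random_unit(rng)
            L = rng.uniform(*length_range_um)
            r = rng.uniform(r_lo, r_hi)
            p1 = p0 + L * d
            if not inside(p1):
                continue
            if not _clearance_ok(p0, p1, r, segments, shared_point=None,
                                 gap_um=clearance_gap_um):
                continue
            segments.append(TubeSegment.straight(p0, p1, r))
            tips.append({"point": p1, "direction": d})
            tips.append({"point": p0, "direction": -d})

    return PhantomTruth(segments=segments, roi_extent_um=tuple(ext),
                        rng_seed=int(seed))


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Camera model: Poisson shot noise plus Gaussian read noise.

    ``photons_at_peak`` sets the expected photon count at the foreground
    intensity (SNR ≈ √photons at the tube center); ``read_sigma`` is the
    read-noise standard deviation and ``baseline`` the detector offset, both
    in the same intensity units as the image.
    """

    photons_at_peak: float = 100.0
    read_sigma: float = 2.0
    baseline: float = 5.0


def _signed_surface_field(truth: PhantomTruth, spacing_um, pad_um: float) -> np.ndarray:
    """min over tubes of (distance to centerline − radius), on the voxel grid.

    Negative inside the tube union, positive outside; only accurate within
    ``pad_um`` of each tube (elsewhere left at +inf), which is all the
    rasterizer needs.
    """
    sp = np.asarray(spacing_um, dtype=float)
    shape = tuple(int(math.ceil(e / s)) for e, s in zip(truth.roi_extent_um, sp))
    F = np.full(shape, np.inf, dtype=np.float32)
    for seg in truth.segments:
        poly = seg.polyline(step_um=min(sp) / 2)
        pad = seg.radius_um + pad_um
        lo_um = poly.min(axis=0) - pad
        hi_um = poly.max(axis=0) + pad
        lo = np.maximum(np.floor(lo_um / sp - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil(hi_um / sp - 0.5).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = [np.arange(lo[a], hi[a]) for a in range(3)]
        grid = np.stack(np.meshgrid(zz, yy, xx, indexing="ij"), axis=-1).reshape(-1, 3)
        centers = (grid + 0.5) * sp
        d = seg.signed_field(centers)
        block = F[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        np.minimum(block, d.reshape(block.shape).astype(np.float32), out=block)
    return F


def _apply_blur_noise(img: np.ndarray, spacing_um, blur_sigma_um: float,
                      noise: NoiseModel | None, seed: int, peak: float) -> np.ndarray:
    sp = np.asarray(spacing_um, dtype=float)
    if blur_sigma_um > 0:
        img = ndi.gaussian_filter(img, sigma=blur_sigma_um / sp)
    if noise is not None:
        rng = np.random.default_rng(seed)
        gain = peak / noise.photons_at_peak
        img = rng.poisson(np.clip(img, 0, None) / gain).astype(np.float32) * gain
        img = img + rng.normal(0.0, noise.read_sigma, img.shape).astype(np.float32)
        img = img + noise.baseline
        img = np.clip(img, 0.0, None)
    return img.astype(np.float32)


def render(
    truth: PhantomTruth,
    spacing_um=(2.0, 1.0, 1.0),
    mode: str = "solid",
    wall_um: float = 1.0,
    blur_sigma_um: float = 0.0,
    noise: NoiseModel | None = None,
    seed: int = 0,
    peak: float = 200.0,
) -> Volume3D:
    """Rasterize a phantom into a :class:`Volume3D`.

    ``mode='solid'`` marks voxels whose center lies within the local radius
    of a centerline (lumen-filled appearance); ``mode='hollow'`` marks only
    the wall shell — centerline distance in (radius − wall_um, radius] — of
    the tube union (wall-labeled appearance). Blur and noise are applied
    after rasterization; a fixed seed gives a bit-identical result.
    """
    if mode not in ("solid", "hollow"):
        raise ValueError(f"mode must be 'solid' or 'hollow', got {mode!r}")
    sp = np.asarray(spacing_um, dtype=float)
    min_radius = min(s.radius_um for s in truth.segments)
    if mode == "hollow" and wall_um >= min_radius:
        raise ValueError("hollow mode requires wall_um < the thinnest tube radius")
    pad = (wall_um if mode == "hollow" else 0.0) + float(max(sp))
    F = _signed_surface_field(truth, sp, pad_um=pad)
    if mode == "solid":
        mask = F <= 0.0
    else:
        mask = (F <= 0.0) & (F > -wall_um)

    thin = [s for s in truth.segments if 2 * s.radius_um < max(sp)]
    if thin:
        warnings.warn(
            f"{len(thin)} tube(s) thinner than one voxel; forcing >= 1-voxel-wide "
            "centerline rasterization", stacklevel=2)
        shape = np.asarray(mask.shape)
        for seg in thin:
            pts = seg.polyline(step_um=min(sp) / 2)
            if len(pts) == 2:  # resample straight segments densely
                n = max(int(seg.length_um() / (min(sp) / 2)), 2)
                pts = np.linspace(seg.p0, seg.p1, n)
            idx = np.clip(np.floor(pts / sp).astype(int), 0, shape - 1)
            mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    img = mask.astype(np.float32) * peak
    img = _apply_blur_noise(img, sp, blur_sigma_um, noise, seed, peak)
    return Volume3D(voxels=img, spacing_um=tuple(sp))


def render_class_masks(truth: PhantomTruth, spacing_um=(2.0, 1.0, 1.0)) -> dict[str, BinaryMask]:
    """Noiseless solid masks of the truth split by caliber class."""
    out = {}
    for label in CALIBER_CLASSES:
        segs = [s for s in truth.segments if truth.caliber_of(s) == label]
        sp = tuple(float(s) for s in spacing_um)
        shape = tuple(int(math.ceil(e / s)) for e, s in zip(truth.roi_extent_um, sp))
        if segs:
            sub = dataclasses.replace(truth, segments=segs, junctions=[], spots=[])
            F = _signed_surface_field(sub, np.asarray(sp), pad_um=float(max(sp)))
            vox = F <= 0.0
        else:
            vox = np.zeros(shape, dtype=bool)
        out[label] = BinaryMask(voxels=vox, spacing_um=sp)
    return out


def render_spots(
    truth: PhantomTruth,
    spacing_um=(2.0, 1.0, 1.0),
    blur_sigma_um: float = 0.0,
    noise: NoiseModel | None = None,
    seed: int = 0,
    peak: float = 200.0,
) -> Volume3D:
    """Rasterize the phantom's spots (spheres) as a second channel."""
    sp = np.asarray(spacing_um, dtype=float)
    shape = tuple(int(math.ceil(e / s)) for e, s in zip(truth.roi_extent_um, sp))
    img = np.zeros(shape, dtype=np.float32)
    for spot in truth.spots:
        c = np.asarray(spot.center_um, dtype=float)
        r = spot.diameter_um / 2.0
        lo = np.maximum(np.floor((c - r) / sp - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil((c + r) / sp - 0.5).astype(int) + 1, shape)
        zz, yy, xx = [np.arange(lo[a], hi[a]) for a in range(3)]
        grid = np.stack(np.meshgrid(zz, yy, xx, indexing="ij"), axis=-1).reshape(-1, 3)
        centers = (grid + 0.5) * sp
        inside = np.linalg.norm(centers - c, axis=1) <= r
        block = img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        np.maximum(block, inside.reshape(block.shape).astype(np.float32) * peak, out=block)
    img = _apply_blur_noise(img, sp, blur_sigma_um, noise, seed, peak)
    return Volume3D(voxels=img, spacing_um=tuple(sp))


# ---------------------------------------------------------------------------
# Analytic ground-truth metrics
# ---------------------------------------------------------------------------

def truth_metrics(truth: PhantomTruth) -> MetricsReport:
    """Analytic network metrics of a phantom (the oracle for the pipeline).

    Length, branch count, junction count, tortuosity and diameters are
    exact. Vessel volume sums the cylinder volumes π r² L and subtracts, at
    each junction of degree k with incident radii r_i, (k − 1)·(2/3)π·min(r_i)³
    for the tube overlap inside the junction ball — an approximation good to
    a few percent for the clearance-constrained networks generated here.
    """
    lengths = [s.length_um() for s in truth.segments]
    torts = [s.tortuosity() for s in truth.segments]
    diams = [s.diameter_um for s in truth.segments]
    volume = sum(math.pi * s.radius_um ** 2 * s.length_um() for s in truth.segments)
    for j in truth.junctions:
        volume -= (j.degree - 1) * (2.0 / 3.0) * math.pi * min(j.radii_um) ** 3
    return build_report(
        branch_lengths_um=lengths,
        branch_tortuosities=torts,
        branch_diameters_um=diams,
        n_junctions=truth.n_junctions,
        vessel_volume_um3=volume,
        roi_volume_um3=truth.roi_volume_um3,
    )


# ---------------------------------------------------------------------------
# Spot placement
# ---------------------------------------------------------------------------

def _derive_label(distances: dict[str, float], max_dist_um: float = 10.0) -> str:
    """Nearest caliber class within ``max_dist_um`` (inclusive), else
    'unassociated'; exact ties favor small > intermediate > large."""
    best, best_d = "unassociated", math.inf
    for label in CALIBER_CLASSES:  # precedence order for ties
        d = distances.get(label, math.inf)
        if d <= max_dist_um and d < best_d - 1e-12:
            best, best_d = label, d
    return best


def place_spots(
    truth: PhantomTruth,
    distance_plan: list[tuple[str, float]] | None = None,
    n_spots: int = 0,
    diameter_range_um=(4.0, 8.0),
    seed: int = 0,
    max_dist_um: float = 10.0,
    max_attempts: int = 5000,
) -> PhantomTruth:
    """Add spheres with exactly known surface distances to the phantom.

    ``distance_plan`` lists requested (class label, surface distance µm)
    pairs; each spot is placed at that distance from a random tube of the
    class and accepted only if no other tube changes the derived label.
    With ``n_spots`` instead, centers are sampled uniformly in the ROI and
    labels derived from their exact distances. Raises
    :class:`SpotPlacementError` when a request cannot be met.
    """
    rng = np.random.default_rng(seed)
    ext = np.asarray(truth.roi_extent_um)
    spots = list(truth.spots)
    next_id = len(spots)

    def record(center, diameter):
        nonlocal next_id
        distances = truth.surface_distances(center)
        label = _derive_label(distances, max_dist_um)
        spots.append(Spot(id=next_id, center_um=tuple(center),
                          diameter_um=float(diameter), label=label,
                          distances_um={k: (v if math.isfinite(v) else math.inf)
                                        for k, v in distances.items()}))
        next_id += 1
        return label

    if distance_plan:
        for want_label, want_dist in distance_plan:
            diameter = rng.uniform(*diameter_range_um)
            margin = diameter / 2 + 1.0
            placed = False
            for _ in range(max_attempts):
                if want_label == "unassociated":
                    seg = truth.segments[int(rng.integers(len(truth.segments)))]
                else:
                    cands = [s for s in truth.segments
                             if truth.caliber_of(s) == want_label]
                    if not cands:
                        break
                    seg = cands[int(rng.integers(len(cands)))]
                t = rng.uniform(0.2, 0.8)
                pt = seg.p0 + t * (seg.p1 - seg.p0)
                e1, e2 = _perp_basis(_unit(seg.p1 - seg.p0))
                phi = rng.uniform(0, 2 * math.pi)
                u = math.cos(phi) * e1 + math.sin(phi) * e2
                center = pt + (seg.radius_um + want_dist) * u
                if np.any(center < margin) or np.any(center > ext - margin):
                    continue
                distances = truth.surface_distances(center)
                label = _derive_label(distances, max_dist_um)
                ref = distances[truth.caliber_of(seg)] if want_label != "unassociated" \
                    else min(distances.values())
                if label == want_label and abs(ref - want_dist) < 1e-9:
                    record(center, diameter)
                    placed = True
                    break
            if not placed:
                raise SpotPlacementError(
                    f"could not place a spot with label {want_label!r} at "
                    f"surface distance {want_dist} µm inside the ROI"
                )
    for _ in range(n_spots):
        diameter = rng.uniform(*diameter_range_um)
        margin = diameter / 2 + 1.0
        for _ in range(max_attempts):
            center = rng.uniform(margin, ext - margin)
            distances = truth.surface_distances(center)
            if min(distances.values()) > 0.5:  # outside every tube
                record(center, diameter)
                break
        else:
            raise SpotPlacementError("could not place a random spot outside the tubes")

    return dataclasses.replace(truth, spots=spots)
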