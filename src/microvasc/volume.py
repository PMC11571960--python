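"""Physical-unit 3D volumes and masks.

Axis order is (z, y, x) everywhere; spacing is µm per voxel along each axis.
The physical coordinate of voxel index (i, j, k) is its center,
((i + 0.5)·sz, (j + 0.5)·sy, (k + 0.5)·sx) µm. ROI intervals are half-open
[offset, offset + extent) in µm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


def _validate_spacing(spacing_um) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing_um)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing_um must be 3 positive values (z,y,x), got {spacing_um!r}")
    return spacing


@dataclass
class Volume3D:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Scalar intensities. Must be finite.
    spacing_um : (sz, sy, sx)
        Voxel spacing in µm along (z, y, x).
    """

    voxels: np.ndarray
    spacing_um: tuple[float, float, float]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(f"voxels must be 3D with all dims >= 1, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")
        self.spacing_um = _validate_spacing(self.spacing_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (z, y, x) in µm."""
        return tuple(n * s for n, s in zip(self.voxels.shape, self.spacing_um))

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))

    def voxel_centers_um(self, indices: np.ndarray) -> np.ndarray:
        """Physical centers (µm) for an (n, 3) array of (z,y,x) voxel indices."""
        sp = np.asarray(self.spacing_um)
        return (np.asarray(indices, dtype=float) + 0.5) * sp

    def save(self, path: str | Path) -> None:
        """Write a multi-page TIFF (one page per z-plane) plus a JSON sidecar
        recording the voxel spacing."""
        path = Path(path)
        tifffile.imwrite(path, np.ascontiguousarray(self.voxels))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"spacing_um": list(self.spacing_um), "axes": "ZYX"}))

    @classmethod
    def load(cls, path: str | Path, spacing_um=None) -> "Volume3D":
        path = Path(path)
        voxels = tifffile.imread(path)
        if voxels.ndim == 2:
            voxels = voxels[None]
        if spacing_um is None:
            sidecar = path.with_suffix(path.suffix + ".json")
            if sidecar.exists():
                spacing_um = json.loads(sidecar.read_text())["spacing_um"]
            else:
                raise ValueError(
                    f"no spacing sidecar at {sidecar}; pass spacing_um explicitly"
                )
        return cls(voxels=voxels, spacing_um=tuple(spacing_um))


@dataclass
class BinaryMask:
    """A boolean segmentation aligned to a :class:`Volume3D` grid."""

    voxels: np.ndarray
    spacing_um: tuple[float, float, float]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.voxels.shape}")
        self.spacing_um = _validate_spacing(self.spacing_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.voxels.shape, self.spacing_um))

    @property
    def foreground_volume_um3(self) -> float:
        return float(np.count_nonzero(self.voxels)) * self.voxel_volume_um3

    def save(self, path: str | Path) -> None:
        """Masks are stored as 8-bit {0, 255} TIFF with a spacing sidecar."""
        path = Path(path)
        tifffile.imwrite(path, (self.voxels.astype(np.uint8) * 255))
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"spacing_um": list(self.spacing_um), "axes": "ZYX"}))

    @classmethod
    def load(cls, path: str | Path, spacing_um=None) -> "BinaryMask":
        vol = Volume3D.load(path, spacing_um=spacing_um)
        return cls(voxels=vol.voxels > 0, spacing_um=vol.spacing_um)


def crop_roi(vol: Volume3D | BinaryMask, offset_um, extent_um):
    """Crop a physical ROI out of a volume.

    The ROI is the half-open box [offset, offset + extent) in µm, axis order
    (z, y, x). Offsets are floored to voxel indices and extents rounded up,
    so e.g. a 600 × 305 × 305 µm (z,y,x) ROI at spacing (2, 1, 1) yields
    300 × 305 × 305 voxels.
    """
    offset = np.asarray(offset_um, dtype=float)
    extent = np.asarray(extent_um, dtype=float)
    if offset.shape != (3,) or extent.shape != (3,):
        raise ValueError("offset_um and extent_um must be (z,y,x) triples")
    if np.any(offset < 0) or np.any(extent <= 0):
        raise ValueError("offset must be non-negative and extent positive")
    sp = np.asarray(vol.spacing_um)
    start = np.floor(offset / sp).astype(int)
    n = np.ceil(extent / sp).astype(int)
    stop = start + n
    if np.any(stop > np.asarray(vol.shape)):
        raise ValueError(
            f"ROI [{tuple(offset)} .. {tuple(offset + extent)}) µm exceeds "
            f"volume extent {vol.extent_um} µm"
        )
    sub = vol.voxels[start[0]:stop[0], start[1]:stop[1], start[2]:stop[2]]
    return type(vol)(voxels=sub.copy(), spacing_um=vol.spacing_um)
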