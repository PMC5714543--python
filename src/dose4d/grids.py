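"""Core raster data model: grids, scalar volumes, binary masks, structure sets.

Conventions
-----------
Right-handed patient-like axes: x = left-right (LR), y = anterior-posterior
(AP), z = superior-inferior (SI, craniocaudal).  World coordinates are in mm.
Arrays are indexed ``values[ix, iy, iz]`` and voxel *centers* define the
sample points: the center of voxel ``(i, j, k)`` sits at
``origin + (i, j, k) * spacing``.  Indices are 0-based.

Mask membership is a voxel-center-in-region test; there are no partial
volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, Mapping, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "GridGeometry",
    "ScalarVolume",
    "BinaryMask",
    "StructureSet",
    "volume_cc",
    "expand_mask",
    "resample_to",
    "shift_mask",
    "signed_distance_mm",
]

_GEOM_TOL_MM = 1e-6


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing and origin of a regular 3D grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z); each entry >= 1.
    spacing : tuple of float
        Voxel size in mm along (x, y, z); all > 0.
    origin : tuple of float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("shape, spacing and origin must be length-3")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def center_mm(self) -> np.ndarray:
        """World coordinate of the grid center."""
        return np.asarray(self.origin) + np.asarray(self.spacing) * (
            np.asarray(self.shape, dtype=float) - 1.0
        ) / 2.0

    def meshgrid_mm(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate arrays (X, Y, Z) of voxel centers."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def world_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world points (..., 3) to fractional index coordinates (..., 3)."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def approx_equal(self, other: "GridGeometry", tol_mm: float = _GEOM_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol_mm for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol_mm for a, b in zip(self.origin, other.origin))
        )


def _require_same_geometry(a: GridGeometry, b: GridGeometry, what: str) -> None:
    if not a.approx_equal(b):
        raise ValueError(f"geometry mismatch: {what} ({a} vs {b})")


@dataclass
class ScalarVolume:
    """A scalar field on a grid: dose (Gy) or relative density (unitless)."""

    geometry: GridGeometry
    values: np.ndarray
    kind: str = "dose"  # "dose" | "density"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )
        if self.kind not in ("dose", "density"):
            raise ValueError(f"unknown volume kind {self.kind!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume values must be finite everywhere")
        if self.kind == "dose" and self.values.min() < 0:
            raise ValueError("dose values must be >= 0")

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.geometry, self.values.copy(), self.kind)


@dataclass
class BinaryMask:
    """A boolean membership flag per voxel."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.dtype != bool:
            uniq = np.unique(values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask values must be in {{0, 1}}, found {uniq[:8]}")
            values = values.astype(bool)
        if values.shape != self.geometry.shape:
            raise ValueError(
                f"mask shape {values.shape} != geometry shape {self.geometry.shape}"
            )
        self.values = values

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def issubset(self, other: "BinaryMask") -> bool:
        _require_same_geometry(self.geometry, other.geometry, "mask comparison")
        return bool(np.all(other.values[self.values]))

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.geometry, self.values.copy())


class StructureSet(Mapping[str, BinaryMask]):
    """Named binary masks sharing one grid geometry.

    ``GTV`` and ``BODY`` are required; GTV must be contained in BODY.
    """

    REQUIRED = ("GTV", "BODY")

    def __init__(self, masks: Dict[str, BinaryMask]):
        if not masks:
            raise ValueError("structure set may not be empty")
        names = list(masks)
        geom = masks[names[0]].geometry
        for name, m in masks.items():
            _require_same_geometry(geom, m.geometry, f"structure {name!r}")
        for req in self.REQUIRED:
            if req not in masks:
                raise ValueError(f"required structure {req!r} missing")
        if not masks["GTV"].issubset(masks["BODY"]):
            raise ValueError("GTV must be a subset of BODY")
        self._masks = dict(masks)
        self.geometry = geom

    def __getitem__(self, name: str) -> BinaryMask:
        return self._masks[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._masks)

    def __len__(self) -> int:
        return len(self._masks)

    def with_structure(self, name: str, mask: BinaryMask) -> "StructureSet":
        """Return a new set with ``name`` added or replaced."""
        masks = dict(self._masks)
        masks[name] = mask
        return StructureSet(masks)


def volume_cc(mask: BinaryMask) -> float:
    """Volume of a mask in cubic centimeters (voxel count x voxel volume)."""
    return mask.voxel_count * mask.geometry.voxel_volume_cc


def _ellipsoid_structuring_element(
    margin_mm: Sequence[float], spacing: Sequence[float]
) -> np.ndarray:
    """Voxel-offset ball of the ellipsoidal metric sum((dx_i/m_i)^2) <= 1."""
    margin = np.asarray(margin_mm, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    half = np.floor(margin / spacing + 1e-9).astype(int)
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    dx = axes[0][:, None, None]
    dy = axes[1][None, :, None]
    dz = axes[2][None, None, :]
    # zero-margin axes only admit zero offset
    terms = []
    for d, m in zip((dx, dy, dz), margin):
        if m > 0:
            terms.append((d / m) ** 2)
        else:
            terms.append(np.where(d == 0, 0.0, np.inf))
    return (terms[0] + terms[1] + terms[2]) <= 1.0 + 1e-12


def expand_mask(mask: BinaryMask, margin_mm: Sequence[float] | float) -> BinaryMask:
    """Expand a mask by an (an)isotropic margin.

    A voxel of the result is set iff its center lies within the ellipsoidal
    scaled distance ``sum((dx_i/m_i)^2) <= 1`` of some input-voxel center.
    Uniform margins reduce to Euclidean dilation; margin 0 on an axis means
    no growth along that axis.

    Parameters
    ----------
    margin_mm : float or (mx, my, mz)
        Non-negative margins in mm per axis.
    """
    if np.isscalar(margin_mm):
        margin_mm = (float(margin_mm),) * 3
    margin = tuple(float(m) for m in margin_mm)
    if any(m < 0 for m in margin):
        raise ValueError(f"margins must be >= 0, got {margin}")
    if all(m == 0 for m in margin) or not mask.values.any():
        return mask.copy()
    selem = _ellipsoid_structuring_element(margin, mask.geometry.spacing)
    out = ndimage.binary_dilation(mask.values, structure=selem)
    return BinaryMask(mask.geometry, out)


def resample_to(vol: ScalarVolume, target: GridGeometry) -> ScalarVolume:
    """Trilinearly resample a scalar volume onto a target geometry.

    Sample points are the target voxel centers; points outside the source
    extent evaluate to 0 (dose outside the calculated grid is unknown and
    treated conservatively as zero).
    """
    if vol.geometry.approx_equal(target):
        return ScalarVolume(target, vol.values.copy(), vol.kind)
    xi = (target.axis_coords(0) - vol.geometry.origin[0]) / vol.geometry.spacing[0]
    yi = (target.axis_coords(1) - vol.geometry.origin[1]) / vol.geometry.spacing[1]
    zi = (target.axis_coords(2) - vol.geometry.origin[2]) / vol.geometry.spacing[2]
    coords = np.meshgrid(xi, yi, zi, indexing="ij")
    out = ndimage.map_coordinates(
        vol.values, np.stack([c.ravel() for c in coords]), order=1,
        mode="grid-constant", cval=0.0,
    ).reshape(target.shape)
    if vol.kind == "dose":
        out = np.maximum(out, 0.0)
    return ScalarVolume(target, out, vol.kind)


def shift_mask(mask: BinaryMask, offset_mm: Sequence[float]) -> BinaryMask:
    """Rigidly translate a mask by ``offset_mm`` (voxel-center resampling).

    A result voxel is set iff its center minus the offset falls inside the
    source region (nearest-neighbor membership).  Used to place the GTV at a
    displaced breathing position.
    """
    offset = np.asarray(offset_mm, dtype=float)
    geom = mask.geometry
    idx = [
        np.arange(n) - offset[a] / geom.spacing[a]
        for a, n in enumerate(geom.shape)
    ]
    coords = np.meshgrid(*idx, indexing="ij")
    out = ndimage.map_coordinates(
        mask.values.astype(np.float32),
        np.stack([c.ravel() for c in coords]),
        order=0, mode="grid-constant", cval=0.0,
    ).reshape(geom.shape)
    return BinaryMask(geom, out > 0.5)


def signed_distance_mm(mask: BinaryMask) -> np.ndarray:
    """Signed Euclidean distance (mm) to the mask surface: negative inside.

    Computed with exact distance transforms using the physical spacing; the
    zero level sits between the boundary voxel layers (half-voxel
    quantization is inherent to the voxelized surface).
    """
    if not mask.values.any():
        raise ValueError("signed distance of an empty mask is undefined")
    spacing = mask.geometry.spacing
    outside = ndimage.distance_transform_edt(~mask.values, sampling=spacing)
    inside = ndimage.distance_transform_edt(mask.values, sampling=spacing)
    return outside - inside
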