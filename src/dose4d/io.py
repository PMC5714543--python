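"""Reading and writing volumes, masks and displacement fields.

NRRD (preferred) and NIfTI-1 via SimpleITK.  Arrays are stored internally
as ``values[ix, iy, iz]`` (x fastest-varying axis first) and transposed at
the I/O boundary to SimpleITK's (z, y, x) buffer order.  Files whose
direction matrix is not the identity are rejected with an explicit axis
diagnostic rather than silently reinterpreted.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import SimpleITK as sitk

from .grids import BinaryMask, GridGeometry, ScalarVolume, StructureSet
from .phantom import DisplacementField

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_field",
    "write_field",
    "read_structures",
    "write_structures",
]

_FORMATS = (".nrrd", ".nii", ".nii.gz")


def _check_path(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _FORMATS):
        raise ValueError(f"unknown volume format for {path.name!r}; use NRRD or NIfTI-1")


def _check_direction(img: sitk.Image, path: Path) -> None:
    d = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(d, np.eye(3), atol=1e-6):
        axes = ["x(LR)", "y(AP)", "z(SI)"]
        offending = [
            f"file axis {i} -> {np.round(d[:, i], 3).tolist()} (expected unit {axes[i]})"
            for i in range(3)
            if not np.allclose(d[:, i], np.eye(3)[:, i], atol=1e-6)
        ]
        raise ValueError(
            f"{path.name}: non-identity axis orientation is not supported; "
            + "; ".join(offending)
        )


def _geometry_of(img: sitk.Image) -> GridGeometry:
    return GridGeometry(
        shape=tuple(img.GetSize()),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def _to_image(values: np.ndarray, geom: GridGeometry, vector: bool = False) -> sitk.Image:
    if vector:
        buf = np.ascontiguousarray(np.transpose(values, (2, 1, 0, 3)))
        img = sitk.GetImageFromArray(buf, isVector=True)
    else:
        img = sitk.GetImageFromArray(np.ascontiguousarray(values.T))
    img.SetSpacing(geom.spacing)
    img.SetOrigin(geom.origin)
    return img


def write_volume(vol: ScalarVolume, path: str | Path) -> None:
    """Write a scalar volume as NRRD or NIfTI-1 (float64, geometry preserved)."""
    path = Path(path)
    _check_path(path)
    sitk.WriteImage(_to_image(vol.values.astype(np.float64), vol.geometry), str(path))


def read_volume(path: str | Path, kind: str = "dose") -> ScalarVolume:
    path = Path(path)
    _check_path(path)
    img = sitk.ReadImage(str(path))
    _check_direction(img, path)
    values = sitk.GetArrayFromImage(img).T.astype(float)
    return ScalarVolume(_geometry_of(img), values, kind=kind)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as 8-bit {0, 1}."""
    path = Path(path)
    _check_path(path)
    sitk.WriteImage(_to_image(mask.values.astype(np.uint8), mask.geometry), str(path))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a mask; values other than {0, 1} are rejected."""
    path = Path(path)
    _check_path(path)
    img = sitk.ReadImage(str(path))
    _check_direction(img, path)
    values = sitk.GetArrayFromImage(img).T
    uniq = np.unique(values)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"{path.name}: mask contains non-binary values {uniq[:8].tolist()}")
    return BinaryMask(_geometry_of(img), values.astype(bool))


def write_field(field: DisplacementField, path: str | Path) -> None:
    """Write a displacement field as a 3-component vector volume (mm)."""
    path = Path(path)
    _check_path(path)
    sitk.WriteImage(
        _to_image(field.vectors_mm.astype(np.float64), field.geometry, vector=True),
        str(path),
    )


def read_field(path: str | Path) -> DisplacementField:
    path = Path(path)
    _check_path(path)
    img = sitk.ReadImage(str(path))
    _check_direction(img, path)
    if img.GetNumberOfComponentsPerPixel() != 3:
        raise ValueError(
            f"{path.name}: displacement field needs 3 components per voxel, "
            f"found {img.GetNumberOfComponentsPerPixel()}"
        )
    arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3)
    vectors = np.transpose(arr, (2, 1, 0, 3)).astype(float)
    return DisplacementField(_geometry_of(img), vectors)


def write_structures(structures: StructureSet, directory: str | Path) -> None:
    """Write each mask as ``<name>.nrrd`` plus a ``structures.json`` index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mask in structures.items():
        write_mask(mask, directory / f"{name}.nrrd")
    (directory / "structures.json").write_text(
        json.dumps({"structures": sorted(structures)}, indent=2)
    )


def read_structures(directory: str | Path) -> StructureSet:
    directory = Path(directory)
    index = directory / "structures.json"
    if not index.exists():
        raise ValueError(f"missing structure index {index}")
    names = json.loads(index.read_text())["structures"]
    masks: Dict[str, BinaryMask] = {}
    geom = None
    for name in names:
        mask = read_mask(directory / f"{name}.nrrd")
        if geom is not None and not mask.geometry.approx_equal(geom):
            raise ValueError(f"structure {name!r} geometry differs from the others")
        geom = mask.geometry
        masks[name] = mask
    return StructureSet(masks)
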