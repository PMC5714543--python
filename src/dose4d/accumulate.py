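"""Equal-weight deformable dose accumulation onto the end-exhale reference.

Per-phase dose grids are warped to the reference (phase 0, end-exhale)
through pull-back displacement fields and averaged with equal time weights
1/N.  Warping is plain trilinear dose interpolation — a simple voxel
warping without congruent energy/mass transfer, which is adequate for the
geometric mechanism studied here and is documented as a limitation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grids import ScalarVolume
from .phantom import BreathingTrajectory, DisplacementField

__all__ = [
    "AccumulatedDose",
    "warp_dose",
    "accumulate_equal_weight",
    "select_midv_phase",
]


@dataclass
class AccumulatedDose:
    """A dose on the reference geometry with its accumulation provenance."""

    volume: ScalarVolume
    phase_indices: Tuple[int, ...]
    weights: Tuple[float, ...]
    technique: str = "4D"  # e.g. "4DCK-like" | "4DVMAT-like" | "3D"

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("accumulation weights must sum to 1")


def warp_dose(dose_phase_k: ScalarVolume, field_k: DisplacementField) -> ScalarVolume:
    """Warp a phase-k dose onto the reference geometry.

    For each reference voxel center ``p`` the output is the trilinear sample
    of the phase-k dose at ``p + u_k(p)`` (pull-back); sample points outside
    the source extent contribute 0.
    """
    geom = field_k.geometry
    if not dose_phase_k.geometry.approx_equal(geom):
        raise ValueError("dose and displacement field geometries differ; resample first")
    spacing = np.asarray(geom.spacing)
    # fractional index of p + u(p) in the phase-k grid
    base = np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in geom.shape], indexing="ij")
    )
    coords = base + np.moveaxis(field_k.vectors_mm, -1, 0) / spacing[:, None, None, None]
    out = ndimage.map_coordinates(
        dose_phase_k.values,
        coords.reshape(3, -1),
        order=1,
        mode="grid-constant",
        cval=0.0,
    ).reshape(geom.shape)
    return ScalarVolume(geom, np.maximum(out, 0.0), kind="dose")


def accumulate_equal_weight(
    per_phase_doses: Sequence[ScalarVolume],
    fields: Sequence[DisplacementField],
    weights: Optional[Sequence[float]] = None,
    technique: str = "4D",
) -> AccumulatedDose:
    """Warp every phase dose to the reference and average.

    ``weights`` defaults to equal weights 1/N; phase 0 must carry the
    identity field (it *is* the reference).  The operation is linear in each
    input dose.
    """
    n = len(per_phase_doses)
    if n < 1:
        raise ValueError("need at least one phase")
    if len(fields) != n:
        raise ValueError(f"{n} doses but {len(fields)} fields")
    if not fields[0].is_identity(1e-9):
        raise ValueError("phase 0 field must be the identity (reference phase)")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("one weight per phase required")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    geom = fields[0].geometry
    acc = np.zeros(geom.shape)
    for dose, fld, wk in zip(per_phase_doses, fields, w):
        acc += wk * warp_dose(dose, fld).values
    return AccumulatedDose(
        volume=ScalarVolume(geom, acc, kind="dose"),
        phase_indices=tuple(range(n)),
        weights=tuple(float(v) for v in w),
        technique=technique,
    )


def select_midv_phase(traj: "BreathingTrajectory | Sequence[float]") -> int:
    """Mid-ventilation phase: SI position closest to the time mean.

    Returns ``argmin_k |z_k - mean(z)|`` over the craniocaudal (SI) centroid
    sequence; exact ties go to the lower phase index.  Accepts either a
    :class:`~dose4d.phantom.BreathingTrajectory` or a raw sequence of SI
    offsets (one per phase).
    """
    if isinstance(traj, BreathingTrajectory):
        z = traj.offsets_mm[:, 2]
    else:
        z = np.asarray(traj, dtype=float)
        if z.ndim != 1 or z.size < 1:
            raise ValueError("need a 1D sequence of per-phase SI offsets")
    return int(np.argmin(np.abs(z - z.mean())))
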