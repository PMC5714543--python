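"""Scalar plan-quality metrics: DVH, Dx%/Vx, conformity, NTD2, margins, MU.

All DVH quantities are exact empirical statistics of the member-voxel dose
samples (no binning, whole-voxel membership).  Dose-at-volume uses the
largest-dose-covering convention with linear interpolation at the
fractional rank — stated explicitly because planning systems differ on
this and results for very small structures are sensitive to it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .grids import BinaryMask, ScalarVolume, volume_cc

__all__ = [
    "DVHCurve",
    "MetricsRecord",
    "MarginParams",
    "DeliveryModel",
    "dvh",
    "dose_at_volume",
    "volume_at_dose",
    "nci",
    "ntd2_volume",
    "normal_tissue_shells",
    "van_herk_margin",
    "beam_on_time",
]


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure.

    ``doses_gy`` holds every member voxel's dose sorted in descending
    order; the cumulative curve V(d) = fraction of structure volume
    receiving at least d is non-increasing from 1 at d=0.
    """

    structure: str
    doses_gy: np.ndarray  # descending
    voxel_volume_cc: float

    def __post_init__(self) -> None:
        d = np.asarray(self.doses_gy, dtype=float)
        if d.size == 0:
            raise ValueError("DVH of an empty structure is undefined")
        self.doses_gy = np.sort(d)[::-1]

    @property
    def n_voxels(self) -> int:
        return self.doses_gy.size

    @property
    def total_volume_cc(self) -> float:
        return self.n_voxels * self.voxel_volume_cc

    def dose_at_volume(self, x_pct: float) -> float:
        return dose_at_volume(self, x_pct)

    def volume_at_dose(self, d_gy: float) -> float:
        return volume_at_dose(self, d_gy)

    def volume_cc_at_dose(self, d_gy: float) -> float:
        """Absolute structure volume (cc) receiving at least ``d_gy``."""
        return self.volume_at_dose(d_gy) / 100.0 * self.total_volume_cc

    @property
    def mean_gy(self) -> float:
        return float(self.doses_gy.mean())


def dvh(dose: ScalarVolume, mask: BinaryMask, structure: str = "") -> DVHCurve:
    """Exact empirical DVH from the member-voxel dose samples."""
    if not dose.geometry.approx_equal(mask.geometry):
        raise ValueError("dose and mask geometries differ")
    if not mask.values.any():
        raise ValueError(f"structure {structure!r} is empty; DVH undefined")
    return DVHCurve(
        structure=structure,
        doses_gy=dose.values[mask.values],
        voxel_volume_cc=mask.geometry.voxel_volume_cc,
    )


def dose_at_volume(curve: DVHCurve, x_pct: float) -> float:
    """Dx%: the largest dose received by at least x% of the structure.

    With doses sorted descending d_(1) >= ... >= d_(n), rank r = x*n/100
    maps to d_(r), interpolating linearly between adjacent order statistics
    at fractional ranks (r <= 1 returns the maximum).
    """
    if not 0 < x_pct <= 100:
        raise ValueError(f"x must be in (0, 100], got {x_pct}")
    d = curve.doses_gy
    r = x_pct * d.size / 100.0
    if r <= 1.0:
        return float(d[0])
    k = int(np.floor(r))
    frac = r - k
    if k >= d.size:
        return float(d[-1])
    return float(d[k - 1] + frac * (d[k] - d[k - 1]))


def volume_at_dose(curve: DVHCurve, d_gy: float) -> float:
    """VxGy as a percentage: fraction of structure volume with dose >= d."""
    if d_gy < 0:
        raise ValueError("dose threshold must be >= 0")
    return float((curve.doses_gy >= d_gy).sum()) / curve.n_voxels * 100.0


def nci(
    dose: ScalarVolume,
    ptv: BinaryMask,
    prescription_gy: float,
    body: Optional[BinaryMask] = None,
) -> float:
    """New conformity index nCI = (PI x PTV) / TVIP^2.

    PI is the volume covered by the prescription isodose (restricted to
    BODY when given, to avoid counting dose in air), PTV the target volume
    and TVIP the target volume covered by the prescription isodose, all in
    cc.  1 is ideal; larger values indicate less conformity.
    """
    if prescription_gy <= 0:
        raise ValueError("prescription must be > 0")
    if not dose.geometry.approx_equal(ptv.geometry):
        raise ValueError("dose and PTV geometries differ")
    if not ptv.values.any():
        raise ValueError("PTV is empty")
    covered = dose.values >= prescription_gy
    if body is not None:
        covered = covered & body.values
    vv = ptv.geometry.voxel_volume_cc
    pi_cc = covered.sum() * vv
    ptv_cc = ptv.voxel_count * vv
    tvip_cc = (covered & ptv.values).sum() * vv
    if tvip_cc == 0:
        raise ValueError("prescription isodose misses the PTV entirely; nCI undefined")
    return float(pi_cc * ptv_cc / tvip_cc**2)


def ntd2_volume(
    dose: ScalarVolume, fractions: int, alpha_beta_gy: float = 3.0
) -> ScalarVolume:
    """Convert physical dose to the normalized total dose in 2 Gy fractions.

    Per voxel, with per-fraction dose d = D/fractions, the linear-quadratic
    equivalence gives NTD2 = D * (d + alpha/beta) / (2 + alpha/beta).
    Identity at 2 Gy/fraction; monotone increasing in D for alpha/beta > 0.
    """
    if fractions < 1:
        raise ValueError("fractions must be >= 1")
    D = dose.values
    d = D / fractions
    out = D * (d + alpha_beta_gy) / (2.0 + alpha_beta_gy)
    return ScalarVolume(dose.geometry, out, kind="dose")


def normal_tissue_shells(
    dose: ScalarVolume,
    body: BinaryMask,
    ptv: BinaryMask,
    prescription_gy: float,
    levels: Sequence[float] = (0.8, 0.5, 0.3, 0.1),
) -> Dict[str, float]:
    """Normal-tissue volume (cc) receiving >= each fraction of prescription.

    Normal tissue is BODY minus the (technique-specific) PTV; the default
    levels give the V80%/V50%/V30%/V10% shells.
    """
    if not (dose.geometry.approx_equal(body.geometry) and dose.geometry.approx_equal(ptv.geometry)):
        raise ValueError("dose, body and PTV geometries differ")
    nt = body.values & ~ptv.values
    vv = body.geometry.voxel_volume_cc
    out = {}
    for lvl in levels:
        key = f"V{int(round(lvl * 100))}%"
        out[key] = float((nt & (dose.values >= lvl * prescription_gy)).sum() * vv)
    return out


@dataclass(frozen=True)
class MarginParams:
    """Inputs of the van Herk nonlinear CTV-to-PTV margin recipe.

    Sigma (systematic SD) and sigma_rand (random SD, excluding breathing)
    are per-axis in mm; sigma_p is the penumbra SD; the breathing position
    SD is modelled as c x peak-to-peak amplitude with c = 0.36 (the SD of
    cos^4 motion relative to its peak-to-peak range).  alpha = 2.5 and
    beta = 1.64 are the standard coverage coefficients.
    """

    sigma_sys_mm: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    sigma_rand_mm: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    sigma_penumbra_mm: float = 3.2
    breathing_coeff: float = 0.36
    alpha: float = 2.5
    beta: float = 1.64

    def __post_init__(self) -> None:
        if any(v < 0 for v in (*self.sigma_sys_mm, *self.sigma_rand_mm)):
            raise ValueError("error SDs must be >= 0")
        if self.sigma_penumbra_mm < 0 or self.breathing_coeff < 0:
            raise ValueError("penumbra SD and breathing coefficient must be >= 0")


def van_herk_margin(
    params: MarginParams, amplitudes_mm: Sequence[float]
) -> np.ndarray:
    """Per-axis CTV-to-PTV margin (mm) from the nonlinear recipe.

    M = alpha*Sigma + beta*(sqrt(sigma^2 + (c*A)^2 + sigma_p^2) - sigma_p)

    per axis, clamped at >= 0; A is the peak-to-peak breathing amplitude.
    The breathing term enters through the random-error quadrature, which
    makes the margin grow sublinearly with amplitude.
    """
    A = np.asarray(amplitudes_mm, dtype=float)
    if np.any(A < 0):
        raise ValueError("amplitudes must be >= 0")
    sigma_sys = np.asarray(params.sigma_sys_mm)
    sigma_rand = np.asarray(params.sigma_rand_mm)
    sp = params.sigma_penumbra_mm
    sigma_tot = np.sqrt(sigma_rand**2 + (params.breathing_coeff * A) ** 2)
    m = params.alpha * sigma_sys + params.beta * (np.sqrt(sigma_tot**2 + sp**2) - sp)
    return np.maximum(m, 0.0)


@dataclass(frozen=True)
class DeliveryModel:
    """MU efficiency and dose rate of one delivery technique."""

    mu_per_gy: float
    dose_rate_mu_per_min: float  # 600 for tracking, 400 max for fixed-geometry
    prescription_gy: float
    fractions: int

    def __post_init__(self) -> None:
        if self.dose_rate_mu_per_min <= 0:
            raise ValueError("dose rate must be > 0")
        if self.mu_per_gy < 0 or self.prescription_gy <= 0 or self.fractions < 1:
            raise ValueError("invalid delivery model")


def beam_on_time(model: DeliveryModel, per_fraction_literal: bool = False) -> float:
    """Beam-on time in minutes.

    Default: (MU per Gy x total prescription dose) / dose rate — the
    relation consistent with the reference delivery tables across both
    fractionation schedules.  ``per_fraction_literal=True`` instead divides
    the per-fraction monitor units by the dose rate.
    """
    if per_fraction_literal:
        mu_fx = model.mu_per_gy * model.prescription_gy / model.fractions
        return mu_fx / model.dose_rate_mu_per_min
    return model.mu_per_gy * model.prescription_gy / model.dose_rate_mu_per_min


@dataclass
class MetricsRecord:
    """One plan's scalar dosimetric summary — the row type of cohort tables."""

    patient_id: int
    technique: str  # "tracking" | "fixed"
    evaluation: str  # "3D" | "4D"
    prescription_gy: float
    fractions: int
    nci: float
    gtv_mean_pct: float  # % of prescription
    gtv_d99_pct: float  # % of prescription
    ptv_v_presc_pct: float
    lung_v20_ntd2_pct: float
    cord_d1_gy: float
    esophagus_d1_gy: float
    trachea_d1_gy: float
    nt_v80_cc: float
    nt_v50_cc: float
    nt_v30_cc: float
    nt_v10_cc: float
    mu_per_gy: float
    beam_on_min: float
    gtv_cc: float = float("nan")
    ptv_cc: float = float("nan")
    motion_3d_mm: float = float("nan")
    si_amplitude_mm: float = float("nan")
    posterior: bool = False

    def as_dict(self) -> Dict[str, object]:
        return dict(self.__dict__)
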