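"""Synthetic 4D breathing phantoms and toy dose clouds.

The generator emulates a 10-phase 4D CT study of a lung tumor: a body
cylinder with a low-density lung compartment, a spherical gross tumor
volume (GTV) riding a cos^(2n) breathing trajectory, analytic displacement
fields (rigid tumor translation under a Gaussian spatial envelope), and two
delivery modes:

* ``tracking`` — the dose cloud follows the displaced target in every
  breathing phase (CyberKnife-like real-time tracking);
* ``fixed`` — one static room-coordinate dose cloud shaped to the
  mid-ventilation PTV; tissue moves through it (VMAT-like delivery under
  4D CBCT setup).

The dose model is an isodose-shaped cloud with a Gaussian penumbra in
signed distance from the PTV surface — not a radiation transport
calculation.  It preserves the geometric mechanism under study (dose cloud
vs. moving anatomy) at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.special import ndtri  # inverse standard normal CDF
from scipy.stats import norm

from .grids import (
    BinaryMask,
    GridGeometry,
    ScalarVolume,
    StructureSet,
    signed_distance_mm,
)

__all__ = [
    "BreathingTrajectory",
    "PhantomSpec",
    "PlanSpec",
    "DisplacementField",
    "Phase4DSet",
    "CohortSpec",
    "PatientCase",
    "make_trajectory",
    "build_phantom",
    "make_phase_set",
    "paint_dose_tracking",
    "paint_dose_fixed",
    "sample_cohort",
    "DEFAULT_GEOMETRY",
]

# 120 x 120 x 180 mm at a clinical 2.5 mm 4D CT slice thickness: large enough for
# the biggest cohort tumor (78 cc) at the largest SI excursion (22.5 mm).
DEFAULT_GEOMETRY = GridGeometry(
    shape=(48, 48, 72),
    spacing=(2.5, 2.5, 2.5),
    origin=(-58.75, -58.75, -88.75),
)


@dataclass(frozen=True)
class BreathingTrajectory:
    """Periodic cos^(2n) breathing motion sampled at N equal time bins.

    Per-phase centroid offsets are expressed relative to phase 0, which is
    the end-exhale (dwell) extreme:

        off_k = A * cos^(2n)(pi * (k - N/2) / N),   k = 0..N-1

    so offsets span exactly [0, A] (peak-to-peak amplitude A per axis) and
    the breather spends most of the cycle near phase 0.  All axes move in
    phase (one respiratory signal drives the 3D excursion).

    Parameters
    ----------
    amplitudes_mm : (A_x, A_y, A_z)
        Peak-to-peak excursion per axis (LR, AP, SI) in mm.
    n_phases : int
        Number of time bins N >= 2 (default 10).
    exponent : int
        n of the cos^(2n) model; n=2 (cos^4) puts more time at exhale.
    period_s : float
        Breathing period in seconds (bookkeeping only; equal time weights
        do not depend on it).
    """

    amplitudes_mm: Tuple[float, float, float]
    n_phases: int = 10
    exponent: int = 2
    period_s: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "amplitudes_mm", tuple(float(a) for a in self.amplitudes_mm)
        )
        if any(a < 0 for a in self.amplitudes_mm):
            raise ValueError(f"amplitudes must be >= 0, got {self.amplitudes_mm}")
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.exponent < 1:
            raise ValueError("exponent must be >= 1")

    @property
    def phase_fractions(self) -> np.ndarray:
        """Unit cos^(2n) waveform: 0 at phase 0 (exhale), 1 at inhale."""
        k = np.arange(self.n_phases)
        # cos(pi (k - N/2) / N) == sin(pi k / N); the sine form is exactly
        # zero at the exhale phase k = 0
        c = np.sin(np.pi * k / self.n_phases)
        return c ** (2 * self.exponent)

    @property
    def offsets_mm(self) -> np.ndarray:
        """Per-phase centroid offsets relative to phase 0, shape (N, 3)."""
        return self.phase_fractions[:, None] * np.asarray(self.amplitudes_mm)

    @property
    def motion_3d_mm(self) -> float:
        """Peak-to-peak Euclidean excursion of the centroid sequence."""
        off = self.offsets_mm
        return float(np.linalg.norm(off[np.argmax(self.phase_fractions)] - off[0]))

    @property
    def weights(self) -> np.ndarray:
        """Equal time-bin weights, exactly 1/N each."""
        return np.full(self.n_phases, 1.0 / self.n_phases)


def make_trajectory(
    amplitudes_mm: Sequence[float],
    n_phases: int = 10,
    exponent: int = 2,
    period_s: float = 4.0,
) -> BreathingTrajectory:
    """Build a breathing trajectory; see :class:`BreathingTrajectory`."""
    return BreathingTrajectory(
        tuple(amplitudes_mm), n_phases=n_phases, exponent=exponent, period_s=period_s
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Anatomy of one synthetic patient at the reference (exhale) phase.

    The body is an elliptic cylinder; the lung is an ellipsoid centered on
    the trajectory midpoint, auto-sized to contain the tumor at every phase;
    cord/esophagus/trachea are cylinders and the heart an ellipsoid, placed
    posterior-medial / anterior as fixed defaults.
    """

    geometry: GridGeometry = DEFAULT_GEOMETRY
    gtv_center_mm: Tuple[float, float, float] = (0.0, 0.0, -8.0)
    gtv_radius_mm: float = 9.5
    body_semiaxes_mm: Tuple[float, float] = (52.5, 52.5)
    body_z_halfextent_mm: float = 87.5
    lung_pad_mm: float = 6.0
    density_body: float = 1.0
    density_lung: float = 0.26
    density_tumor: float = 1.0
    posterior: bool = False

    def __post_init__(self) -> None:
        if self.gtv_radius_mm <= 0:
            raise ValueError("gtv_radius_mm must be > 0")

    @property
    def gtv_volume_cc(self) -> float:
        return 4.0 / 3.0 * np.pi * self.gtv_radius_mm**3 / 1000.0


@dataclass(frozen=True)
class PlanSpec:
    """Prescription and toy delivery parameters for one technique.

    ``isodose_pct`` is the prescription isodose in % of the maximum dose
    (tracking plans 62-83%, fixed-geometry plans 78-85%); the cloud maximum
    is prescription / isodose.  ``mu_per_gy`` and the dose rate feed the
    delivery-efficiency model only.
    """

    technique: str  # "tracking" | "fixed"
    prescription_gy: float = 60.0
    fractions: int = 3
    isodose_pct: float = 70.0
    penumbra_sigma_mm: float = 3.0
    target_name: str = "PTV_CK"
    mu_per_gy: float = 223.0
    dose_rate_mu_per_min: float = 600.0

    def __post_init__(self) -> None:
        if self.technique not in ("tracking", "fixed"):
            raise ValueError(f"unknown technique {self.technique!r}")
        if not 0 < self.isodose_pct <= 100:
            raise ValueError("isodose_pct must be in (0, 100]")
        if self.prescription_gy <= 0 or self.fractions < 1:
            raise ValueError("invalid prescription")
        if self.penumbra_sigma_mm <= 0:
            raise ValueError("penumbra sigma must be > 0")

    @property
    def dmax_gy(self) -> float:
        return self.prescription_gy / (self.isodose_pct / 100.0)


@dataclass
class DisplacementField:
    """Per-voxel 3-vector (mm) mapping reference points to a phase.

    Pull-back convention: for a reference-phase point ``p`` the
    corresponding phase-k material point is ``p + u_k(p)``.
    """

    geometry: GridGeometry
    vectors_mm: np.ndarray  # (nx, ny, nz, 3)

    def __post_init__(self) -> None:
        self.vectors_mm = np.asarray(self.vectors_mm, dtype=float)
        if self.vectors_mm.shape != self.geometry.shape + (3,):
            raise ValueError(
                f"vector shape {self.vectors_mm.shape} != {self.geometry.shape + (3,)}"
            )

    @property
    def max_magnitude_mm(self) -> float:
        return float(np.sqrt((self.vectors_mm**2).sum(axis=-1)).max())

    def is_identity(self, tol_mm: float = 1e-9) -> bool:
        return self.max_magnitude_mm <= tol_mm


@dataclass
class Phase4DSet:
    """Ten (by default) breathing phases sharing one grid geometry.

    Phase 0 is the reference (end-exhale); its displacement field is the
    identity, and the time weights are exactly 1/N.
    """

    geometry: GridGeometry
    densities: List[ScalarVolume]
    fields: List[DisplacementField]
    centroids_mm: np.ndarray  # (N, 3) tumor centroid per phase
    weights: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        n = len(self.densities)
        if n < 2 or len(self.fields) != n:
            raise ValueError("need >= 2 phases with one field per phase")
        self.centroids_mm = np.asarray(self.centroids_mm, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-12):
            raise ValueError("phase weights must sum to 1")
        if not self.fields[0].is_identity(1e-9):
            raise ValueError("phase 0 must be the reference (identity field)")

    @property
    def n_phases(self) -> int:
        return len(self.densities)


def _sphere_mask(geom: GridGeometry, center: Sequence[float], radius: float) -> np.ndarray:
    x, y, z = geom.meshgrid_mm()
    return (
        (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
        <= radius**2
    )


def _ellipsoid_mask(
    geom: GridGeometry, center: Sequence[float], semi: Sequence[float]
) -> np.ndarray:
    x, y, z = geom.meshgrid_mm()
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
        <= 1.0
    )


def _cylinder_mask(
    geom: GridGeometry,
    center_xy: Sequence[float],
    radius: float,
    z_range: Tuple[float, float],
) -> np.ndarray:
    x, y, z = geom.meshgrid_mm()
    radial = (x - center_xy[0]) ** 2 + (y - center_xy[1]) ** 2 <= radius**2
    return radial & (z >= z_range[0]) & (z <= z_range[1])


def build_phantom(spec: PhantomSpec, traj: BreathingTrajectory) -> StructureSet:
    """Rasterize the reference-phase structure set for one patient.

    The lung ellipsoid is centered on the trajectory midpoint and sized so
    the GTV stays strictly inside it at every sampled phase; OAR masks have
    the lung and GTV excursion region carved out.
    """
    geom = spec.geometry
    c0 = np.asarray(spec.gtv_center_mm, dtype=float)
    amp = np.asarray(traj.amplitudes_mm)
    c_mid = c0 + amp / 2.0
    center = geom.center_mm()

    bx, by = spec.body_semiaxes_mm
    x, y, z = geom.meshgrid_mm()
    body = (
        (((x - center[0]) / bx) ** 2 + ((y - center[1]) / by) ** 2 <= 1.0)
        & (np.abs(z - center[2]) <= spec.body_z_halfextent_mm)
    )

    lung_semi = spec.gtv_radius_mm + amp / 2.0 + spec.lung_pad_mm
    lung = _ellipsoid_mask(geom, c_mid, lung_semi)
    if not np.all(body[lung]):
        raise ValueError(
            "lung compartment does not fit inside the body for this tumor "
            f"size/motion (semi-axes {np.round(lung_semi, 1)} mm at {np.round(c_mid, 1)})"
        )

    gtv = _sphere_mask(geom, c0, spec.gtv_radius_mm)
    if not gtv.any():
        raise ValueError("GTV rasterized to an empty mask; radius below grid resolution")
    # tumor must stay inside lung (hence body) at every breathing phase
    for k, off in enumerate(traj.offsets_mm):
        displaced = _sphere_mask(geom, c0 + off, spec.gtv_radius_mm)
        if not np.all(lung[displaced]):
            raise ValueError(
                f"tumor leaves the lung compartment at phase {k} "
                f"(offset {np.round(off, 1)} mm); increase lung_pad_mm or reduce motion"
            )

    zr = (c_mid[2] - 70.0, c_mid[2] + 70.0)
    cord = _cylinder_mask(geom, (center[0], center[1] + 45.0), 4.0, zr)
    eso = _cylinder_mask(geom, (center[0] + 10.0, center[1] + 40.0), 5.0, zr)
    trachea = _cylinder_mask(geom, (center[0] - 10.0, center[1] - 38.0), 6.0, zr)
    heart = _ellipsoid_mask(
        geom, (center[0], center[1] - 28.0, center[2] - 40.0), (22.0, 16.0, 25.0)
    )
    # sweep of the tumor over all phases, used to keep OARs disjoint from it
    sweep = np.zeros(geom.shape, dtype=bool)
    for off in traj.offsets_mm:
        sweep |= _sphere_mask(geom, c0 + off, spec.gtv_radius_mm)
    carve = lung | sweep

    masks = {
        "BODY": BinaryMask(geom, body),
        "GTV": BinaryMask(geom, gtv & lung),
        "LUNGS": BinaryMask(geom, lung),
        "CORD": BinaryMask(geom, cord & body & ~carve),
        "ESOPHAGUS": BinaryMask(geom, eso & body & ~carve),
        "TRACHEA": BinaryMask(geom, trachea & body & ~carve),
        "HEART": BinaryMask(geom, heart & body & ~carve),
    }
    return StructureSet(masks)


#: lung tissue within this distance (mm) of the tumor surface moves fully
#: coherently with it; beyond, the motion tapers smoothly to zero
ENVELOPE_PLATEAU_MM = 15.0
#: distance (mm) beyond the tumor surface at which the motion reaches zero
ENVELOPE_CUTOFF_MM = 40.0


def _motion_envelope(spec: PhantomSpec, geom: GridGeometry) -> np.ndarray:
    """Spatial envelope of the displacement field.

    Exactly 1 on the GTV and out to a plateau distance beyond its surface
    (the tumor and surrounding parenchyma breathe rigidly together), then a
    smooth Gaussian-like cos^2 taper to exactly zero at the cutoff — the
    chest wall and mediastinum do not follow the tumor.  For the default
    phantom the cutoff lies inside the body wall, so the field vanishes at
    the body edge.
    """
    x, y, z = geom.meshgrid_mm()
    c = spec.gtv_center_mm
    r = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)
    d = np.maximum(0.0, r - spec.gtv_radius_mm)
    t = np.clip(
        (d - ENVELOPE_PLATEAU_MM) / (ENVELOPE_CUTOFF_MM - ENVELOPE_PLATEAU_MM), 0.0, 1.0
    )
    return np.cos(0.5 * np.pi * t) ** 2


def make_phase_set(
    spec: PhantomSpec, traj: BreathingTrajectory
) -> Tuple[Phase4DSet, StructureSet]:
    """Generate the 4D phase set and the reference-phase structures.

    Each phase holds a density volume with the tumor at its displaced
    position and a displacement field u_k = (centroid offset) x (Gaussian
    envelope); phase 0 is end-exhale with the identity field.
    """
    structures = build_phantom(spec, traj)
    geom = spec.geometry
    env = _motion_envelope(spec, geom)
    body = structures["BODY"].values
    lung = structures["LUNGS"].values
    c0 = np.asarray(spec.gtv_center_mm)

    densities: List[ScalarVolume] = []
    fields: List[DisplacementField] = []
    centroids = []
    for off in traj.offsets_mm:
        u = env[..., None] * off[None, None, None, :]
        fields.append(DisplacementField(geom, u))
        dens = np.zeros(geom.shape)
        dens[body] = spec.density_body
        dens[lung] = spec.density_lung
        dens[_sphere_mask(geom, c0 + off, spec.gtv_radius_mm)] = spec.density_tumor
        densities.append(ScalarVolume(geom, dens, kind="density"))
        centroids.append(c0 + off)

    phases = Phase4DSet(
        geometry=geom,
        densities=densities,
        fields=fields,
        centroids_mm=np.asarray(centroids),
        weights=traj.weights,
    )
    return phases, structures


def _cloud_from_signed_distance(
    sdist_mm: np.ndarray, plan: PlanSpec
) -> np.ndarray:
    """Isodose-shaped dose cloud from signed distance to the PTV surface.

    dose(d) = D_max * Phi((d0 - d) / sigma) with d0 = sigma * Phi^-1(iso),
    which pins the prescription isodose surface to the PTV boundary (d = 0)
    and saturates to D_max deep inside the target.
    """
    iso = plan.isodose_pct / 100.0
    sigma = plan.penumbra_sigma_mm
    d0 = sigma * ndtri(iso)
    return plan.dmax_gy * norm.cdf((d0 - sdist_mm) / sigma)


def _sample_at_offset(values: np.ndarray, geom: GridGeometry, offset_mm: np.ndarray) -> np.ndarray:
    """Trilinearly sample ``values`` at p - offset (rigid-shift evaluation)."""
    idx = [
        np.arange(n) - offset_mm[a] / geom.spacing[a]
        for a, n in enumerate(geom.shape)
    ]
    coords = np.meshgrid(*idx, indexing="ij")
    return ndimage.map_coordinates(
        values, np.stack([c.ravel() for c in coords]), order=1, mode="nearest"
    ).reshape(geom.shape)


def paint_dose_tracking(
    phases: Phase4DSet, structures: StructureSet, plan: PlanSpec
) -> List[ScalarVolume]:
    """Per-phase dose for a target-tracking delivery.

    The dose cloud rigidly follows the displaced target: in phase k the
    cloud is the reference PTV_CK cloud translated by the phase-k centroid
    offset, so the prescription isodose surface tracks the displaced PTV
    boundary.
    """
    if plan.technique != "tracking":
        raise ValueError("paint_dose_tracking requires a tracking plan")
    if plan.target_name not in structures:
        raise ValueError(f"structure {plan.target_name!r} (tracking PTV) missing")
    sdist = signed_distance_mm(structures[plan.target_name])
    offsets = phases.centroids_mm - phases.centroids_mm[0]
    doses = []
    for off in offsets:
        d_k = _sample_at_offset(sdist, phases.geometry, off)
        doses.append(ScalarVolume(phases.geometry, _cloud_from_signed_distance(d_k, plan)))
    return doses


def paint_dose_fixed(
    phases: Phase4DSet,
    structures: StructureSet,
    plan: PlanSpec,
    midv_index: int,
) -> List[ScalarVolume]:
    """Per-phase dose for a fixed-geometry delivery.

    One static room-coordinate dose cloud is shaped to the mid-ventilation
    PTV and evaluated identically on every phase grid — the tissue moves
    through it, which is what the 4D accumulation then resolves.
    """
    if plan.technique != "fixed":
        raise ValueError("paint_dose_fixed requires a fixed-geometry plan")
    if plan.target_name not in structures:
        raise ValueError(f"structure {plan.target_name!r} (fixed-geometry PTV) missing")
    if not 0 <= midv_index < phases.n_phases:
        raise ValueError(f"midv_index {midv_index} out of range")
    sdist = signed_distance_mm(structures[plan.target_name])
    cloud = _cloud_from_signed_distance(sdist, plan)
    return [ScalarVolume(phases.geometry, cloud.copy()) for _ in range(phases.n_phases)]


@dataclass(frozen=True)
class CohortSpec:
    """Sampling ranges for a synthetic patient cohort.

    Defaults emulate the study population: GTV volumes 0.6-78 cc
    (log-uniform), per-axis peak-to-peak amplitudes SI 2-22.5 mm,
    AP 0.1-3.5 mm, LR 0.2-3.8 mm with the resulting 3D motion restricted to
    2-23 mm, two central lesions in fourteen (48 Gy/6 fx instead of
    60 Gy/3 fx), and half the lesions posterior.
    """

    n_patients: int = 14
    seed: int = 0
    gtv_volume_range_cc: Tuple[float, float] = (0.6, 78.0)
    si_amplitude_range_mm: Tuple[float, float] = (2.0, 22.5)
    ap_amplitude_range_mm: Tuple[float, float] = (0.1, 3.5)
    lr_amplitude_range_mm: Tuple[float, float] = (0.2, 3.8)
    motion_3d_range_mm: Tuple[float, float] = (2.0, 23.0)
    central_fraction: float = 2.0 / 14.0
    posterior_fraction: float = 0.5
    geometry: GridGeometry = DEFAULT_GEOMETRY

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be > 0")


@dataclass
class PatientCase:
    """One sampled patient: anatomy, motion, and the two plan specs."""

    patient_id: int
    phantom: PhantomSpec
    trajectory: BreathingTrajectory
    plans: Dict[str, PlanSpec]  # keys "tracking", "fixed"


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # per-patient substream: cohort-size changes never reshuffle earlier patients
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(index,))))


def sample_cohort(spec: CohortSpec) -> List[PatientCase]:
    """Draw a reproducible synthetic cohort.

    Tumor volume is log-uniform over the cohort range; amplitudes are
    uniform per axis with rejection until the 3D motion falls in the stated
    window; the tumor rest position is shifted posteriorly/anteriorly
    (clipped so the auto-sized lung stays inside the body).
    """
    cases: List[PatientCase] = []
    for i in range(spec.n_patients):
        rng = _patient_rng(spec.seed, i)
        lo, hi = spec.gtv_volume_range_cc
        vol_cc = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        radius = (3.0 * vol_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)

        for _ in range(1000):
            a_si = rng.uniform(*spec.si_amplitude_range_mm)
            a_ap = rng.uniform(*spec.ap_amplitude_range_mm)
            a_lr = rng.uniform(*spec.lr_amplitude_range_mm)
            m3d = float(np.sqrt(a_si**2 + a_ap**2 + a_lr**2))
            if spec.motion_3d_range_mm[0] <= m3d <= spec.motion_3d_range_mm[1]:
                break
        else:  # pragma: no cover - ranges guarantee acceptance
            raise RuntimeError("could not sample a 3D motion in range")
        traj = make_trajectory((a_lr, a_ap, a_si), n_phases=10, exponent=2)

        posterior = bool(rng.random() < spec.posterior_fraction)
        central = bool(rng.random() < spec.central_fraction)

        # posterior/anterior placement, clipped so lung fits in the body
        geom = spec.geometry
        center = geom.center_mm()
        lung_semi_y = radius + a_ap / 2.0 + 6.0
        max_off = max(0.0, 52.5 - 2.0 - lung_semi_y)
        y_off = (1.0 if posterior else -1.0) * min(10.0, max_off)
        amp = np.array([a_lr, a_ap, a_si])
        c0 = center + np.array([0.0, y_off, 0.0]) - amp / 2.0
        phantom = PhantomSpec(
            geometry=geom,
            gtv_center_mm=tuple(c0),
            gtv_radius_mm=radius,
            posterior=posterior,
        )

        if central:
            dose, fx = 48.0, 6
        else:
            dose, fx = 60.0, 3
        mu_ck = float(np.clip(rng.normal(223.0, 55.0), 160.0, 360.0))
        mu_vmat = float(np.clip(rng.normal(85.0 if central else 57.0, 8.0), 44.0, 95.0))
        plans = {
            "tracking": PlanSpec(
                technique="tracking",
                prescription_gy=dose,
                fractions=fx,
                isodose_pct=float(rng.uniform(62.0, 83.0)),
                penumbra_sigma_mm=3.0,
                target_name="PTV_CK",
                mu_per_gy=mu_ck,
                dose_rate_mu_per_min=600.0,
            ),
            "fixed": PlanSpec(
                technique="fixed",
                prescription_gy=dose,
                fractions=fx,
                isodose_pct=float(rng.uniform(78.0, 85.0)),
                penumbra_sigma_mm=5.0,
                target_name="PTV_VMAT",
                mu_per_gy=mu_vmat,
                dose_rate_mu_per_min=400.0,
            ),
        }
        cases.append(PatientCase(i + 1, phantom, traj, plans))
    return cases
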