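"""Shared fixtures: small grids and a compact phantom patient."""

import numpy as np
import pytest

from dose4d import (
    BinaryMask,
    BreathingTrajectory,
    GridGeometry,
    PatientCase,
    PhantomSpec,
    PlanSpec,
    ScalarVolume,
)

SMALL_GEOMETRY = GridGeometry(
    shape=(36, 36, 44), spacing=(2.5, 2.5, 2.5), origin=(-43.75, -43.75, -53.75)
)


@pytest.fixture
def unit_geometry():
    """10x10x10 grid at 1 mm spacing (for counting oracles)."""
    return GridGeometry(shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20130708)


def sphere_mask(geom: GridGeometry, center, radius) -> BinaryMask:
    x, y, z = geom.meshgrid_mm()
    values = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= radius**2
    return BinaryMask(geom, values)


def small_patient(amplitude_si=10.0, gtv_radius=8.0, seed_plans=True) -> PatientCase:
    """A compact phantom patient on a reduced grid for fast unit tests."""
    traj = BreathingTrajectory((1.0, 1.0, amplitude_si), n_phases=10, exponent=2)
    amp = np.asarray(traj.amplitudes_mm)
    center = SMALL_GEOMETRY.center_mm()
    phantom = PhantomSpec(
        geometry=SMALL_GEOMETRY,
        gtv_center_mm=tuple(center - amp / 2.0),
        gtv_radius_mm=gtv_radius,
        body_semiaxes_mm=(40.0, 40.0),
        body_z_halfextent_mm=52.0,
    )
    plans = {
        "tracking": PlanSpec(
            technique="tracking", prescription_gy=60.0, fractions=3,
            isodose_pct=70.0, penumbra_sigma_mm=3.0, target_name="PTV_CK",
            mu_per_gy=223.0, dose_rate_mu_per_min=600.0,
        ),
        "fixed": PlanSpec(
            technique="fixed", prescription_gy=60.0, fractions=3,
            isodose_pct=80.0, penumbra_sigma_mm=5.0, target_name="PTV_VMAT",
            mu_per_gy=56.0, dose_rate_mu_per_min=400.0,
        ),
    }
    return PatientCase(1, phantom, traj, plans)


@pytest.fixture(scope="session")
def moving_patient_phases():
    """Phase set + structures for a 10 mm SI mover, shared across tests."""
    from dose4d import make_phase_set

    case = small_patient(amplitude_si=10.0)
    phases, structures = make_phase_set(case.phantom, case.trajectory)
    return case, phases, structures
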