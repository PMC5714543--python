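"""Breathing trajectories, phantom generation and the toy dose models."""

import numpy as np
import pytest

from dose4d import (
    CohortSpec,
    PlanSpec,
    expand_mask,
    make_phase_set,
    make_trajectory,
    paint_dose_fixed,
    paint_dose_tracking,
    sample_cohort,
    select_midv_phase,
    shift_mask,
    volume_cc,
)
from dose4d.phantom import PhantomSpec

from conftest import SMALL_GEOMETRY, small_patient


class TestTrajectory:
    def test_static_trajectory_has_zero_offsets(self):
        traj = make_trajectory((0, 0, 0))
        assert np.all(traj.offsets_mm == 0.0)
        assert traj.motion_3d_mm == 0.0

    def test_peak_to_peak_equals_amplitude(self):
        traj = make_trajectory((0, 0, 10), n_phases=10, exponent=1)
        z = traj.offsets_mm[:, 2]
        assert z.max() - z.min() == pytest.approx(10.0)
        assert z[0] == 0.0  # phase 0 is the exhale extreme

    def test_cos4_time_average_is_closer_to_exhale(self):
        # n=2: mean offset 0.375*A < A/2, i.e. the breather dwells at exhale
        traj = make_trajectory((0, 0, 10), n_phases=10, exponent=2)
        z = traj.offsets_mm[:, 2]
        assert z.mean() < 5.0
        assert z.mean() == pytest.approx(3.75, abs=1e-9)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            make_trajectory((-1, 0, 0))

    def test_weights_sum_to_one_exactly(self):
        traj = make_trajectory((1, 2, 3), n_phases=10)
        assert traj.weights.sum() == 1.0
        assert np.all(traj.weights == 0.1)


class TestPhaseSet:
    def test_zero_amplitude_gives_identical_phases(self):
        case = small_patient(amplitude_si=0.0)
        phases, _ = make_phase_set(case.phantom, make_trajectory((0, 0, 0)))
        for k in range(1, phases.n_phases):
            assert np.array_equal(phases.densities[k].values, phases.densities[0].values)
            assert phases.fields[k].max_magnitude_mm == 0.0

    def test_field_maps_centroid_along_trajectory(self, moving_patient_phases):
        case, phases, _ = moving_patient_phases
        geom = phases.geometry
        c0 = np.asarray(case.phantom.gtv_center_mm)
        idx = np.rint(geom.world_to_index(c0)).astype(int)
        for k in (3, 5, 7):
            u = phases.fields[k].vectors_mm[tuple(idx)]
            # rigid inside the tumor: the field carries the full phase offset
            assert np.allclose(u, case.trajectory.offsets_mm[k], atol=1e-6)
        assert np.allclose(
            phases.centroids_mm[5], c0 + case.trajectory.offsets_mm[5], atol=1e-9
        )

    def test_field_vanishes_at_body_edge_of_default_phantom(self):
        from scipy import ndimage

        spec = PhantomSpec()  # default geometry and tumor
        phases, structures = make_phase_set(spec, make_trajectory((2.0, 2.0, 15.0)))
        body = structures["BODY"].values
        edge = body & ~ndimage.binary_erosion(body)
        mag = np.sqrt((phases.fields[5].vectors_mm ** 2).sum(axis=-1))
        assert mag[edge].max() < 0.01

    def test_field_bounded_by_amplitude(self, moving_patient_phases):
        case, phases, _ = moving_patient_phases
        amp = np.linalg.norm(case.trajectory.amplitudes_mm)
        for f in phases.fields:
            assert f.max_magnitude_mm <= 1.5 * amp

    def test_structures_nested_and_shared_geometry(self, moving_patient_phases):
        _, phases, structures = moving_patient_phases
        assert structures["GTV"].issubset(structures["LUNGS"])
        assert structures["LUNGS"].issubset(structures["BODY"])
        assert structures.geometry.approx_equal(phases.geometry)

    def test_tumor_leaving_body_rejected(self):
        spec = PhantomSpec(
            geometry=SMALL_GEOMETRY,
            gtv_center_mm=tuple(SMALL_GEOMETRY.center_mm()),
            gtv_radius_mm=8.0,
            body_semiaxes_mm=(40.0, 40.0),
            body_z_halfextent_mm=52.0,
        )
        with pytest.raises(ValueError, match="lung|body"):
            make_phase_set(spec, make_trajectory((0, 0, 80.0)))


class TestDosePainting:
    def test_tracking_static_trajectory_identical_phases(self):
        case = small_patient(amplitude_si=0.0)
        phases, structures = make_phase_set(case.phantom, make_trajectory((0, 0, 0)))
        structures = structures.with_structure("PTV_CK", expand_mask(structures["GTV"], 5.0))
        doses = paint_dose_tracking(phases, structures, case.plans["tracking"])
        for k in range(1, len(doses)):
            assert np.allclose(doses[k].values, doses[0].values, atol=1e-12)

    def test_tracking_displaced_centroid_receives_dmax(self, moving_patient_phases):
        case, phases, structures = moving_patient_phases
        structures = structures.with_structure("PTV_CK", expand_mask(structures["GTV"], 5.0))
        plan = case.plans["tracking"]
        doses = paint_dose_tracking(phases, structures, plan)
        geom = phases.geometry
        for k in (0, 5):
            idx = np.rint(geom.world_to_index(phases.centroids_mm[k])).astype(int)
            assert doses[k].values[tuple(idx)] == pytest.approx(plan.dmax_gy, rel=0.01)

    def test_tracking_requires_ptv(self, moving_patient_phases):
        case, phases, structures = moving_patient_phases
        with pytest.raises(ValueError, match="PTV_CK"):
            paint_dose_tracking(phases, structures, case.plans["tracking"])

    def test_fixed_cloud_is_static_across_phases(self, moving_patient_phases):
        case, phases, structures = moving_patient_phases
        midv = select_midv_phase(case.trajectory)
        gtv_midv = shift_mask(structures["GTV"], case.trajectory.offsets_mm[midv])
        structures = structures.with_structure("PTV_VMAT", expand_mask(gtv_midv, 7.0))
        doses = paint_dose_fixed(phases, structures, case.plans["fixed"], midv)
        for k in range(1, len(doses)):
            assert np.array_equal(doses[k].values, doses[0].values)

    def test_fixed_dose_at_displaced_centroid_decreases_with_amplitude(self):
        values = []
        for amp in (0.0, 12.0, 20.0):
            case = small_patient(amplitude_si=amp)
            phases, structures = make_phase_set(case.phantom, case.trajectory)
            midv = select_midv_phase(case.trajectory)
            gtv_midv = shift_mask(structures["GTV"], case.trajectory.offsets_mm[midv])
            structures = structures.with_structure("PTV_VMAT", expand_mask(gtv_midv, 7.0))
            doses = paint_dose_fixed(phases, structures, case.plans["fixed"], midv)
            k_inhale = int(np.argmax(case.trajectory.phase_fractions))
            idx = np.rint(
                phases.geometry.world_to_index(phases.centroids_mm[k_inhale])
            ).astype(int)
            values.append(doses[k_inhale].values[tuple(idx)])
        assert values[0] > values[1] > values[2]


class TestCohortSampling:
    def test_same_seed_reproduces_cohort(self):
        a = sample_cohort(CohortSpec(n_patients=5, seed=42))
        b = sample_cohort(CohortSpec(n_patients=5, seed=42))
        for ca, cb in zip(a, b):
            assert ca.phantom == cb.phantom
            assert ca.trajectory == cb.trajectory
            assert ca.plans == cb.plans

    def test_growing_cohort_preserves_earlier_patients(self):
        a = sample_cohort(CohortSpec(n_patients=3, seed=7))
        b = sample_cohort(CohortSpec(n_patients=6, seed=7))
        for ca, cb in zip(a, b[:3]):
            assert ca.phantom == cb.phantom and ca.trajectory == cb.trajectory

    def test_cohort_within_stated_ranges(self):
        cases = sample_cohort(CohortSpec(n_patients=14, seed=3))
        assert len(cases) == 14
        for c in cases:
            assert 0.6 <= c.phantom.gtv_volume_cc <= 78.0
            assert 2.0 <= c.trajectory.motion_3d_mm <= 23.0
            assert c.plans["tracking"].prescription_gy in (60.0, 48.0)
            assert 62 <= c.plans["tracking"].isodose_pct <= 83
            assert 78 <= c.plans["fixed"].isodose_pct <= 85

    def test_large_sample_approaches_range_bounds(self):
        cases = sample_cohort(CohortSpec(n_patients=200, seed=11))
        vols = np.array([c.phantom.gtv_volume_cc for c in cases])
        motions = np.array([c.trajectory.motion_3d_mm for c in cases])
        assert vols.min() < 1.5 and vols.max() > 50.0
        assert motions.min() < 3.5 and motions.max() > 20.0

    def test_invalid_cohort_size_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_patients=0)
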