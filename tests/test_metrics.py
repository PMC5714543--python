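"""DVH statistics, conformity, NTD2, margins and delivery efficiency."""

import numpy as np
import pytest
from scipy.optimize import brentq

from dose4d import (
    BinaryMask,
    DeliveryModel,
    GridGeometry,
    MarginParams,
    ScalarVolume,
    beam_on_time,
    dose_at_volume,
    dvh,
    nci,
    normal_tissue_shells,
    ntd2_volume,
    van_herk_margin,
    volume_at_dose,
)


def ramp_curve(unit_geometry):
    """100 selected voxels dosed 1..100 Gy."""
    values = np.zeros(unit_geometry.shape)
    mask = np.zeros(unit_geometry.shape, bool)
    mask.flat[:100] = True
    values.flat[:100] = np.arange(1, 101)
    return dvh(ScalarVolume(unit_geometry, values), BinaryMask(unit_geometry, mask))


class TestDVH:
    def test_uniform_dose_step_curve(self, unit_geometry):
        vol = ScalarVolume(unit_geometry, np.full(unit_geometry.shape, 10.0))
        mask = BinaryMask(unit_geometry, np.ones(unit_geometry.shape, bool))
        curve = dvh(vol, mask)
        assert volume_at_dose(curve, 10.0) == 100.0
        assert volume_at_dose(curve, 10.0001) == 0.0
        assert volume_at_dose(curve, 0.0) == 100.0

    def test_ramp_counting_oracle(self, unit_geometry):
        curve = ramp_curve(unit_geometry)
        assert volume_at_dose(curve, 20.0) == pytest.approx(81.0)
        assert volume_at_dose(curve, 60.0) == pytest.approx(41.0)

    def test_curve_monotone_non_increasing(self, unit_geometry, rng):
        vol = ScalarVolume(unit_geometry, rng.random(unit_geometry.shape) * 50)
        mask = BinaryMask(unit_geometry, rng.random(unit_geometry.shape) < 0.5)
        curve = dvh(vol, mask)
        levels = np.linspace(0, 55, 40)
        v = [volume_at_dose(curve, d) for d in levels]
        assert all(a >= b for a, b in zip(v, v[1:]))

    def test_empty_mask_rejected(self, unit_geometry):
        vol = ScalarVolume(unit_geometry, np.zeros(unit_geometry.shape))
        with pytest.raises(ValueError):
            dvh(vol, BinaryMask(unit_geometry, np.zeros(unit_geometry.shape, bool)))

    def test_matches_brute_force_on_random_grids(self, rng):
        # exhaustive check against counting/sorting oracles on small grids
        for _ in range(5):
            geom = GridGeometry(tuple(rng.integers(3, 20, 3)), (1, 1, 1))
            values = rng.random(geom.shape) * 60
            member = rng.random(geom.shape) < 0.4
            if not member.any():
                continue
            curve = dvh(ScalarVolume(geom, values), BinaryMask(geom, member))
            samples = values[member]
            for d in rng.random(5) * 60:
                assert volume_at_dose(curve, d) == pytest.approx(
                    (samples >= d).mean() * 100.0
                )
            srt = np.sort(samples)[::-1]
            for x in (1.0, 50.0, 99.0, 100.0):
                r = x * srt.size / 100.0
                if r <= 1:
                    expected = srt[0]
                else:
                    k = int(np.floor(r))
                    expected = srt[k - 1] + (r - k) * (srt[min(k, srt.size - 1)] - srt[k - 1])
                assert dose_at_volume(curve, x) == pytest.approx(expected, abs=1e-12)


class TestDoseAtVolume:
    def test_uniform_dose_constant(self, unit_geometry):
        vol = ScalarVolume(unit_geometry, np.full(unit_geometry.shape, 12.5))
        curve = dvh(vol, BinaryMask(unit_geometry, np.ones(unit_geometry.shape, bool)))
        for x in (1, 37.5, 99, 100):
            assert dose_at_volume(curve, x) == 12.5

    def test_ramp_d99_rank_convention(self, unit_geometry):
        # 100 voxels dosed 1..100: D99% is the 99th largest value = 2 Gy
        assert dose_at_volume(ramp_curve(unit_geometry), 99.0) == pytest.approx(2.0)

    def test_d1_at_least_d99(self, unit_geometry, rng):
        vol = ScalarVolume(unit_geometry, rng.random(unit_geometry.shape) * 30)
        curve = dvh(vol, BinaryMask(unit_geometry, np.ones(unit_geometry.shape, bool)))
        assert dose_at_volume(curve, 1.0) >= dose_at_volume(curve, 99.0)

    def test_out_of_range_rejected(self, unit_geometry):
        curve = ramp_curve(unit_geometry)
        for x in (0.0, -5.0, 101.0):
            with pytest.raises(ValueError):
                dose_at_volume(curve, x)


class TestNCI:
    def test_perfectly_conformal_plan_scores_one(self, unit_geometry):
        values = np.zeros(unit_geometry.shape)
        ptv = np.zeros(unit_geometry.shape, bool)
        ptv[3:7, 3:7, 3:7] = True
        values[ptv] = 60.0
        assert nci(ScalarVolume(unit_geometry, values), BinaryMask(unit_geometry, ptv), 60.0) == 1.0

    def test_arithmetic_of_definition(self, unit_geometry):
        # PI = 20 cc-equivalent, PTV = TVIP = 10 -> (20*10)/10^2 = 2
        values = np.zeros(unit_geometry.shape)
        values.flat[:20] = 60.0
        ptv = np.zeros(unit_geometry.shape, bool)
        ptv.flat[:10] = True
        assert nci(ScalarVolume(unit_geometry, values), BinaryMask(unit_geometry, ptv), 60.0) == pytest.approx(2.0)

    def test_matches_counting_oracle_on_random_volume(self, rng):
        geom = GridGeometry((18, 16, 14), (1.5, 1.5, 2.0))
        values = rng.random(geom.shape) * 70
        ptv = rng.random(geom.shape) < 0.3
        body = np.ones(geom.shape, bool)
        body[0] = False
        got = nci(
            ScalarVolume(geom, values), BinaryMask(geom, ptv), 35.0, body=BinaryMask(geom, body)
        )
        vv = geom.voxel_volume_cc
        covered = (values >= 35.0) & body  # isodose restricted to BODY
        pi = np.sum(covered) * vv
        tvip = np.sum(covered & ptv) * vv
        expect = pi * (ptv.sum() * vv) / tvip**2
        assert got == pytest.approx(expect, rel=1e-12)

    def test_isodose_missing_ptv_rejected(self, unit_geometry):
        values = np.zeros(unit_geometry.shape)
        ptv = np.zeros(unit_geometry.shape, bool)
        ptv.flat[:10] = True
        with pytest.raises(ValueError):
            nci(ScalarVolume(unit_geometry, values), BinaryMask(unit_geometry, ptv), 60.0)


class TestNTD2:
    def test_two_gray_per_fraction_fixed_point(self, unit_geometry):
        vol = ScalarVolume(unit_geometry, np.full(unit_geometry.shape, 10.0))
        out = ntd2_volume(vol, fractions=5)  # 2 Gy/fx
        assert np.allclose(out.values, 10.0)

    def test_direct_formula_arithmetic(self, unit_geometry):
        vol = ScalarVolume(unit_geometry, np.full(unit_geometry.shape, 20.0))
        out = ntd2_volume(vol, fractions=3)
        assert np.allclose(out.values, 20.0 * (20.0 / 3.0 + 3.0) / 5.0)
        assert out.values.flat[0] == pytest.approx(38.6667, abs=1e-3)

    def test_quadratic_inversion_oracle(self):
        # physical dose at 3 fx whose NTD2 is 20 Gy: (-9 + sqrt(1281)) / 2
        geom = GridGeometry((1, 1, 1), (1, 1, 1))

        def ntd2_of(d):
            return ntd2_volume(ScalarVolume(geom, np.full((1, 1, 1), d)), 3).values[0, 0, 0]

        d = brentq(lambda x: ntd2_of(x) - 20.0, 0.0, 40.0, xtol=1e-12)
        assert d == pytest.approx((-9 + np.sqrt(1281)) / 2, abs=1e-9)

    def test_monotone_in_dose(self, unit_geometry, rng):
        a = rng.random(unit_geometry.shape) * 30
        hi = ntd2_volume(ScalarVolume(unit_geometry, a + 1.0), 4).values
        lo = ntd2_volume(ScalarVolume(unit_geometry, a), 4).values
        assert np.all(hi > lo)


class TestShells:
    def test_zero_dose_gives_empty_shells(self, unit_geometry):
        body = BinaryMask(unit_geometry, np.ones(unit_geometry.shape, bool))
        ptv = BinaryMask(unit_geometry, np.zeros(unit_geometry.shape, bool))
        ptv.values.flat[:5] = True
        shells = normal_tissue_shells(
            ScalarVolume(unit_geometry, np.zeros(unit_geometry.shape)), body, ptv, 60.0
        )
        assert all(v == 0.0 for v in shells.values())

    def test_uniform_prescription_fills_body_minus_ptv(self, unit_geometry):
        body_values = np.ones(unit_geometry.shape, bool)
        ptv_values = np.zeros(unit_geometry.shape, bool)
        ptv_values.flat[:100] = True
        dosev = np.where(body_values, 60.0, 0.0)
        shells = normal_tissue_shells(
            ScalarVolume(unit_geometry, dosev),
            BinaryMask(unit_geometry, body_values),
            BinaryMask(unit_geometry, ptv_values),
            60.0,
        )
        expect = (1000 - 100) * unit_geometry.voxel_volume_cc
        assert all(v == pytest.approx(expect) for v in shells.values())


class TestVanHerkMargin:
    def test_zero_errors_give_zero_margin(self):
        p = MarginParams(sigma_sys_mm=(0, 0, 0), sigma_rand_mm=(0, 0, 0))
        assert np.allclose(van_herk_margin(p, (0, 0, 0)), 0.0)

    def test_arithmetic_example(self):
        p = MarginParams(sigma_sys_mm=(2, 2, 2), sigma_rand_mm=(2, 2, 2),
                         sigma_penumbra_mm=3.2)
        m = van_herk_margin(p, (0, 0, 0))
        assert m[2] == pytest.approx(2.5 * 2 + 1.64 * (np.sqrt(4 + 10.24) - 3.2), abs=1e-9)
        assert m[2] == pytest.approx(5.941, abs=1e-3)

    def test_monotone_and_sublinear_in_amplitude(self):
        p = MarginParams()
        amps = np.linspace(1.0, 22.5, 50)
        margins = np.array([van_herk_margin(p, (0, 0, a))[2] for a in amps])
        assert np.all(np.diff(margins) > 0)
        secant = (margins[-1] - margins[0]) / (amps[-1] - amps[0])
        assert secant < 0.5

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            van_herk_margin(MarginParams(), (-1, 0, 0))
        with pytest.raises(ValueError):
            MarginParams(sigma_sys_mm=(-1, 0, 0))


class TestBeamOnTime:
    @pytest.mark.parametrize(
        "mu_per_gy,dose,rate,expected",
        [
            (167.0, 60.0, 600.0, 16.7),  # reference patient 1
            (271.0, 48.0, 600.0, 21.7),  # reference patient 12
            (10.0, 60.0, 600.0, 1.0),  # 600 MU at 600 MU/min
        ],
    )
    def test_total_dose_relation(self, mu_per_gy, dose, rate, expected):
        model = DeliveryModel(mu_per_gy, rate, dose, 3)
        assert round(beam_on_time(model), 1) == expected

    def test_literal_per_fraction_variant(self):
        model = DeliveryModel(167.0, 600.0, 60.0, 3)
        assert beam_on_time(model, per_fraction_literal=True) == pytest.approx(16.7 / 3)

    def test_zero_dose_rate_rejected(self):
        with pytest.raises(ValueError):
            DeliveryModel(100.0, 0.0, 60.0, 3)
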