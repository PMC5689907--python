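"""Film dosimetry chain: PV -> OD -> net-OD -> dose -> relative map."""

import numpy as np
import pytest
from scipy import ndimage

import dapcal as dc
from dapcal.film_dosimetry import (
    EBT3_CURVE,
    combine_exposures,
    film_to_dose,
    find_beam_center,
    median_filter,
    normalize_to_cax,
    od_to_dose,
    pixel_to_od,
    register_and_net_od,
)
from dapcal.types import DoseMap2D, FilmScan, ODMap


class TestPixelToOd:
    @pytest.mark.parametrize(
        "pv, od",
        [(65536.0, 0.0), (6553.6, 1.0), (32768.0, np.log10(2.0))],
    )
    def test_reference_values(self, pv, od):
        scan = FilmScan(np.full((4, 4), pv), dpi=300)
        assert pixel_to_od(scan).od == pytest.approx(od, abs=1e-9)

    def test_black_pixel_rejected(self):
        with pytest.raises(ValueError):
            FilmScan(np.zeros((4, 4)), dpi=300)

    def test_pitch_from_dpi(self):
        scan = FilmScan(np.full((4, 4), 30000.0), dpi=300)
        assert scan.pitch == pytest.approx(25.4 / 300)

    def test_identity_with_generator_inverse(self):
        # PV = 2^16 * 10^-OD then back must be exact to 1e-12
        od_true = np.linspace(0.05, 1.2, 50).reshape(5, 10)
        scan = FilmScan(2**16 * 10.0 ** (-od_true), dpi=300)
        assert np.allclose(pixel_to_od(scan).od, od_true, atol=1e-12)


class TestMedianFilter:
    def test_constant_map_unchanged(self):
        m = np.full((50, 50), 3.3)
        assert np.array_equal(median_filter(m, 30), m)

    def test_dust_pixel_removed(self):
        m = np.full((40, 40), 1.0)
        m[20, 20] = 50.0
        assert np.allclose(median_filter(m, 5), 1.0)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(0)
        m = rng.random((40, 40))
        w = 5
        out = median_filter(m, w)
        padded = np.pad(m, w // 2, mode="symmetric")  # ndimage 'reflect'
        for r, c in rng.integers(0, 40, size=(20, 2)):
            window = padded[r : r + w, c : c + w]
            assert out[r, c] == pytest.approx(np.median(window), abs=1e-15)

    def test_idempotent_on_piecewise_constant(self):
        m = np.zeros((40, 40))
        m[:, 20:] = 1.0
        once = median_filter(m, 5)
        assert np.array_equal(median_filter(once, 5), once)


class TestRegistration:
    def _od(self, arr):
        return ODMap(np.asarray(arr, dtype=float), pitch=0.1)

    def test_identity_marks_give_zero_net_od(self):
        rng = np.random.default_rng(1)
        od = rng.random((30, 30))
        marks = np.array([[5.0, 5.0], [25.0, 5.0], [5.0, 25.0]])
        net = register_and_net_od(self._od(od), self._od(od), marks, marks)
        assert np.allclose(net.od, 0.0, atol=1e-12)

    def test_known_integer_shift_recovered(self):
        rng = np.random.default_rng(2)
        base = ndimage.gaussian_filter(rng.random((60, 60)), 3)
        shift_xy = (4, -3)
        shifted = ndimage.shift(base, (shift_xy[1], shift_xy[0]), order=1,
                                mode="nearest")
        marks_post = np.array([[10.0, 10.0], [50.0, 10.0], [10.0, 50.0]])
        marks_pre = marks_post + np.array(shift_xy)
        net = register_and_net_od(self._od(shifted), self._od(base),
                                  marks_pre, marks_post, clamp_negative=False)
        inner = (slice(8, -8), slice(8, -8))
        assert np.max(np.abs(net.od[inner])) < 1e-3

    def test_mark_count_mismatch_rejected(self):
        od = self._od(np.ones((10, 10)))
        with pytest.raises(ValueError):
            register_and_net_od(od, od, np.zeros((3, 2)), np.zeros((2, 2)))

    def test_synthetic_exposure_round_trip(self, cone_spec):
        dose = dc.make_field(cone_spec, extent=6.0, pitch=0.5, dose_scale=1.2)
        pre, post = dc.render_film_scan(dose, EBT3_CURVE, noise_sd=0.0)
        net = register_and_net_od(pixel_to_od(pre), pixel_to_od(post),
                                  pre.marks, post.marks)
        assert np.allclose(net.od, EBT3_CURVE.net_od(dose.values), atol=1e-6)


class TestOdToDose:
    def test_zero_net_od_is_zero_dose(self):
        net = ODMap(np.zeros((4, 4)), pitch=0.1)
        assert np.all(od_to_dose(net).values == 0.0)

    def test_printed_coefficients_at_0p1(self):
        # direct evaluation of the 5th-order calibration polynomial
        net = ODMap(np.full((2, 2), 0.1), pitch=0.1)
        assert od_to_dose(net).values == pytest.approx(0.9440935, abs=1e-6)

    def test_strictly_increasing_on_domain(self):
        grid = np.linspace(0.0, EBT3_CURVE.max_net_od, 400)
        dose = EBT3_CURVE.dose(grid)
        assert np.all(np.diff(dose) > 0)

    def test_extrapolation_refused_but_clampable(self):
        net = ODMap(np.full((2, 2), 0.5), pitch=0.1)
        with pytest.raises(ValueError, match="extrapolation refused"):
            od_to_dose(net)
        clamped = od_to_dose(net, clamp=True)
        assert np.all(clamped.values == pytest.approx(2.8, abs=1e-9))


class TestCombineExposures:
    def test_equal_maps_ratio_one_unchanged(self, cone_map):
        out = combine_exposures(cone_map, cone_map, 1.0)
        assert np.allclose(out.values, cone_map.values, atol=1e-9)

    def test_high_is_exact_multiple(self, cone_map):
        out = combine_exposures(cone_map, cone_map.scaled(10.0), 10.0)
        assert np.allclose(out.values, cone_map.values, atol=1e-9)

    def test_tail_taken_from_high_exposure(self, cone_spec):
        dose = dc.make_field(cone_spec, extent=10.0, pitch=0.5, dose_scale=1.5)
        # low exposure under-responds below ~10% of CAX dose
        low = DoseMap2D(np.where(dose.values < 0.15, dose.values * 0.5, dose.values),
                        dose.pitch, dose.origin)
        out = combine_exposures(low, dose.scaled(10.0), 10.0)
        tail = dose.radius_cm() > 3.2
        assert np.max(np.abs(out.values[tail] / dose.values[tail] - 1.0)) < 0.02

    def test_scale_consistency(self, cone_map):
        low, high = cone_map, cone_map.scaled(10.0)
        once = combine_exposures(low, high, 10.0)
        twice = combine_exposures(low.scaled(2.0), high.scaled(2.0), 10.0)
        assert np.allclose(twice.values, 2.0 * once.values)


class TestNormalizeToCax:
    def test_scale_invariance(self, cone_map):
        a = normalize_to_cax(cone_map)
        b = normalize_to_cax(cone_map.scaled(7.3))
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_uniform_map_all_ones(self):
        m = DoseMap2D(np.full((60, 60), 2.0), 0.5, (29.5, 29.5))
        assert np.allclose(normalize_to_cax(m).values, 1.0)

    def test_center_value_under_noise(self, cone_spec):
        dose = dc.make_field(cone_spec, extent=8.0, pitch=0.5, dose_scale=1.5)
        pre, post = dc.render_film_scan(dose, EBT3_CURVE, noise_sd=0.002, seed=3)
        rel = normalize_to_cax(film_to_dose(pre, post, window=10))
        r0, c0 = (int(round(o)) for o in rel.origin)
        assert rel.values[r0, c0] == pytest.approx(1.0, abs=0.005)

    def test_beam_center_found(self, cone_map):
        center = find_beam_center(cone_map)
        assert center[0] == pytest.approx(cone_map.origin[0], abs=0.1)
        assert center[1] == pytest.approx(cone_map.origin[1], abs=0.1)


class TestPipelineInvariants:
    def test_noiseless_round_trip(self, cone_spec):
        dose = dc.make_field(cone_spec, extent=6.0, pitch=0.5, dose_scale=1.5)
        pre, post = dc.render_film_scan(dose, EBT3_CURVE, noise_sd=0.0)
        rec = film_to_dose(pre, post, window=1)
        assert np.allclose(rec.values, dose.values, atol=1e-10)

    def test_noisy_recovery_within_noise_budget(self, cone_spec):
        noise_sd = 0.002
        dose = dc.make_field(cone_spec, extent=10.0, pitch=0.25, dose_scale=1.5)
        pre, post = dc.render_film_scan(dose, EBT3_CURVE, noise_sd=noise_sd,
                                        dust_density=3e-4, seed=2)
        rec = film_to_dose(pre, post, window=10)
        infield = dose.radius_cm() < 1.8
        mare = np.mean(np.abs(rec.values - dose.values)[infield]
                       / dose.values[infield])
        assert mare < 3 * noise_sd

    def test_median_filter_changes_integral_below_half_percent(self, cone_spec):
        dose = dc.make_field(cone_spec, extent=10.0, pitch=0.25, dose_scale=1.5)
        pre, post = dc.render_film_scan(dose, EBT3_CURVE, noise_sd=0.002,
                                        dust_density=3e-4, seed=2)
        with_filter = normalize_to_cax(film_to_dose(pre, post, window=10))
        without = normalize_to_cax(film_to_dose(pre, post, window=1, clamp=True))
        ia = dc.integrate_disc_2d(with_filter, r_lac=4.08).value
        ib = dc.integrate_disc_2d(without, r_lac=4.08).value
        assert abs(ib / ia - 1.0) < 0.005
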