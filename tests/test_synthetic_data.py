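"""Generator fidelity: every synthetic input must match its closed form."""

import numpy as np
import pytest
from scipy import integrate as sint

import dapcal as dc
from dapcal.film_dosimetry import EBT3_CURVE, film_to_dose
from dapcal.types import ChamberReading, FieldSpec


class TestMakeField:
    def test_cax_normalization(self, cone_spec, cone_map):
        r0, c0 = (int(round(o)) for o in cone_map.origin)
        assert cone_map.values[r0, c0] == pytest.approx(1.0, abs=1e-9)

    def test_tail_plateau(self, cone_spec):
        m = dc.make_field(cone_spec, extent=14.0, pitch=1.0)
        y, x = m.coords_cm()
        j = int(np.argmin(np.abs(x - 6.0)))
        i = int(round(m.origin[0]))
        assert m.values[i, j] == pytest.approx(0.04, abs=1e-4)

    def test_disc_integral_matches_quadrature_oracle(self, cone_spec, cone_map):
        grid = dc.integrate_disc_2d(cone_map, r_lac=4.08).value
        oracle = sint.quad(
            lambda r: 2 * np.pi * r * cone_spec.radial(r), 0.0, 4.08, limit=200
        )[0]
        assert grid == pytest.approx(oracle, rel=1e-3)

    def test_extent_too_small_raises(self, cone_spec):
        with pytest.raises(ValueError, match="field exceeds grid"):
            dc.make_field(cone_spec, extent=4.0, pitch=0.5)

    def test_deterministic(self, cone_spec):
        a = dc.make_field(cone_spec, extent=8.0, pitch=0.5)
        b = dc.make_field(cone_spec, extent=8.0, pitch=0.5)
        assert np.array_equal(a.values, b.values)


class TestRenderFilmScan:
    def test_zero_dose_gives_identical_scans(self):
        from dapcal.types import DoseMap2D

        dose = DoseMap2D(np.zeros((40, 40)), 0.5, (19.5, 19.5))
        pre, post = render = dc.render_film_scan(dose, EBT3_CURVE, noise_sd=0.0)
        assert np.array_equal(pre.pv, post.pv)

    def test_single_pixel_net_od_round_trip(self):
        from dapcal.types import DoseMap2D

        target_dose = float(EBT3_CURVE.dose(0.1))
        dose = DoseMap2D(np.full((8, 8), target_dose), 0.5, (3.5, 3.5))
        pre, post = dc.render_film_scan(dose, EBT3_CURVE, noise_sd=0.0)
        net = np.log10(pre.pv / post.pv)
        assert net == pytest.approx(0.1, abs=1e-6)

    def test_noisy_mean_recovery_within_3_se(self, cone_spec):
        noise_sd = 0.002
        dose = dc.make_field(cone_spec, extent=6.0, pitch=0.5, dose_scale=1.5)
        pre, post = dc.render_film_scan(dose, EBT3_CURVE, noise_sd=noise_sd, seed=7)
        rec = film_to_dose(pre, post, window=1, clamp=True)
        infield = dose.radius_cm() < 1.5
        resid = (rec.values - dose.values)[infield] / dose.values[infield]
        se = resid.std(ddof=1) / np.sqrt(resid.size)
        assert abs(resid.mean()) < 3 * se + 1e-4

    def test_dose_above_range_rejected(self):
        from dapcal.types import DoseMap2D

        dose = DoseMap2D(np.full((4, 4), 3.5), 0.5, (1.5, 1.5))
        with pytest.raises(ValueError, match="outside calibration range"):
            dc.render_film_scan(dose, EBT3_CURVE)

    def test_seeded_determinism(self, cone_spec):
        dose = dc.make_field(cone_spec, extent=6.0, pitch=1.0, dose_scale=1.0)
        a = dc.render_film_scan(dose, EBT3_CURVE, noise_sd=0.01, dust_density=1e-3, seed=5)
        b = dc.render_film_scan(dose, EBT3_CURVE, noise_sd=0.01, dust_density=1e-3, seed=5)
        assert np.array_equal(a[1].pv, b[1].pv)


class TestSampleProfiles:
    def test_uniform_map_gives_unity(self):
        from dapcal.types import DoseMap2D

        m = DoseMap2D(np.ones((81, 81)), 1.0, (40.0, 40.0))
        for p in dc.sample_profiles(m, n_directions=2, step=1.0):
            assert np.allclose(p.value, 1.0)

    def test_matches_closed_form_without_blur(self, gaussian_map):
        profs = dc.sample_profiles(gaussian_map, n_directions=1, step=0.5,
                                   detector_fwhm=0.0)
        for p in profs:
            assert np.allclose(p.value, np.exp(-p.r**2 / 2.0), atol=5e-4)

    def test_orthogonal_directions_identical_on_symmetric_field(self, cone_map):
        p = dc.sample_profiles(cone_map, n_directions=2, step=0.5)
        assert np.max(np.abs(p[0].value - p[2].value)) < 1e-12

    def test_bad_step_rejected(self, cone_map):
        with pytest.raises(ValueError):
            dc.sample_profiles(cone_map, n_directions=2, step=0.0)


class TestVoltageSeries:
    def test_zero_slope_is_saturated(self):
        series = dc.simulate_voltage_series(100.0, 0.0, [80, 200, 400])
        assert all(r.charge == pytest.approx(100.0) for r in series)

    def test_printed_example(self):
        (r,) = dc.simulate_voltage_series(100.0, 0.36, [400.0])
        assert r.charge == pytest.approx(99.91, abs=5e-3)

    def test_jaffe_recovers_generator_k_s_exactly(self):
        series = dc.simulate_voltage_series(100.0, 0.36, [100, 150, 200, 300, 400])
        fit = dc.k_s_jaffe(series)
        assert fit.k_s == pytest.approx(1.0 + 0.36 / 400.0, abs=1e-10)

    def test_negative_voltage_rejected(self):
        with pytest.raises(ValueError):
            dc.simulate_voltage_series(100.0, 0.36, [-100, 400])


class TestChamberReading:
    def test_reference_conditions_no_corrections(self):
        r = dc.simulate_chamber_reading(500.0, 160.0)
        assert r.charge == pytest.approx(500.0 / 160.0, rel=1e-12)

    def test_full_round_trip_recovers_n_true(self):
        n_true = 163.7
        r = dc.simulate_chamber_reading(
            1000.0, n_true, temperature=23.1, pressure=98.7,
            ks_true=1.0009, kpol_true=0.999, mu=100.0,
        )
        m_cor = r.charge * dc.k_tp(r.temperature, r.pressure)
        cs = dc.CorrectionSet(k_s=1.0009, k_pol=0.999)
        n = dc.calibration_coefficient(10.0, 100.0, m_cor, cs)
        assert n == pytest.approx(n_true, rel=1e-9)

    def test_noise_level_reproduces_requested_sd(self):
        charges = [
            dc.simulate_chamber_reading(500.0, 160.0, noise_pct=0.07, seed=s).charge
            for s in range(200)
        ]
        from dapcal.chamber_corrections import reproducibility_pct

        assert reproducibility_pct(charges) == pytest.approx(0.07, rel=0.25)


class TestLacScan:
    def test_uniform_map_flat(self):
        from dapcal.types import DoseMap2D

        m = DoseMap2D(np.ones((121, 121)), 1.0, (60.0, 60.0))
        for _, s in dc.lac_scan(m, [0.5, 1.0], r_lac=4.08):
            assert s == pytest.approx(1.0, abs=1e-12)

    def test_small_field_lateral_tolerance(self, square_1x1_spec):
        m = dc.make_field(square_1x1_spec, extent=14.0, pitch=1.0)
        for _, s in dc.lac_scan(m, [0.25, 0.5], r_lac=4.08):
            assert abs(s - 1.0) < 0.002  # < 0.2% up to 0.5 cm off axis

    def test_matches_pixel_sum_oracle_at_large_offset(self, square_1x1_spec):
        m = dc.make_field(square_1x1_spec, extent=26.0, pitch=1.0)
        ((off, signal),) = dc.lac_scan(m, [8.0], r_lac=4.08)
        y, x = m.coords_cm()
        rr0 = np.hypot(y[:, None], x[None, :])
        rr8 = np.hypot(y[:, None], (x - 8.0)[None, :])
        oracle = m.values[rr8 <= 4.08].mean() / m.values[rr0 <= 4.08].mean()
        assert signal == pytest.approx(oracle, rel=1e-12)

    def test_disc_exiting_grid_rejected(self, square_1x1_spec):
        m = dc.make_field(square_1x1_spec, extent=10.0, pitch=1.0)
        with pytest.raises(ValueError, match="disc exits grid"):
            dc.lac_scan(m, [3.0], r_lac=4.08)


class TestChamberVolume:
    def test_recovers_gap_thickness(self):
        vol = dc.make_chamber_volume(gap_thickness=2.01, gap_radius=2.0,
                                     noise_sd=0.0, lateral_margin=0.5)
        tm = dc.thickness_map(vol, gap_radius_cm=0.18, block=10)
        assert tm.gap_mean_mm == pytest.approx(2.01, abs=0.082)

    def test_zero_gap_reports_zero(self):
        vol = dc.make_chamber_volume(gap_thickness=0.0, gap_radius=2.0,
                                     noise_sd=0.0, lateral_margin=0.5)
        tm = dc.thickness_map(vol, gap_radius_cm=0.18, block=10)
        assert tm.gap_mean_mm == pytest.approx(0.0, abs=1e-12)

    def test_tilted_gap_shows_gradient(self):
        vol = dc.make_chamber_volume(gap_thickness=2.01, gap_radius=4.0,
                                     gap_tilt=0.02, noise_sd=0.0,
                                     lateral_margin=0.5)
        tm = dc.thickness_map(vol, gap_radius_cm=0.38, block=10)
        assert tm.tilt_pvalue < 1e-6

    def test_gap_outside_body_rejected(self):
        with pytest.raises(ValueError, match="gap must lie inside"):
            dc.make_chamber_volume(body_thickness=2.0, gap_thickness=3.0)

    def test_seeded_determinism(self):
        a = dc.make_chamber_volume(gap_radius=1.0, noise_sd=50.0,
                                   lateral_margin=0.3, seed=11)
        b = dc.make_chamber_volume(gap_radius=1.0, noise_sd=50.0,
                                   lateral_margin=0.3, seed=11)
        assert np.array_equal(a.values, b.values)
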