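import numpy as np
import pytest
from hypothesis import given, strategies as st

from lightniche import visual_model as vm


def write_spectrum(tmp_path, rows, name="s.txt"):
    path = tmp_path / name
    path.write_text("\n".join(f"{w} {v}" for w, v in rows) + "\n")
    return path


class TestLoadSpectrum:
    def test_zero_spectrum(self, tmp_path):
        s = vm.load_spectrum(write_spectrum(tmp_path, [(310, 0.0), (670, 0.0)]))
        assert s.units == "energy"
        np.testing.assert_array_equal(s.wavelengths_nm, [310, 670])
        np.testing.assert_array_equal(s.values, [0.0, 0.0])

    def test_sort_invariance(self, tmp_path):
        a = vm.load_spectrum(write_spectrum(tmp_path, [(400, 1.0), (350, 2.0), (500, 3.0)], "a.txt"))
        b = vm.load_spectrum(write_spectrum(tmp_path, [(350, 2.0), (400, 1.0), (500, 3.0)], "b.txt"))
        np.testing.assert_array_equal(a.wavelengths_nm, b.wavelengths_nm)
        np.testing.assert_array_equal(a.values, b.values)

    def test_duplicate_wavelength_rejected(self, tmp_path):
        path = write_spectrum(tmp_path, [(350, 1.0), (350, 2.0), (400, 1.0)])
        with pytest.raises(vm.SpectrumError, match="duplicated"):
            vm.load_spectrum(path)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("310 1.0\nnot numbers here\n")
        with pytest.raises(vm.SpectrumError, match=":2"):
            vm.load_spectrum(path)

    def test_comments_and_commas(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text("# header\n310, 1.0\n670, 2.0  # tail\n")
        s = vm.load_spectrum(path)
        np.testing.assert_array_equal(s.values, [1.0, 2.0])

    def test_negative_readings_clipped(self, tmp_path):
        s = vm.load_spectrum(write_spectrum(tmp_path, [(310, -0.5), (670, 1.0)]))
        assert s.values[0] == 0.0


class TestCalibration:
    def test_identity_gain(self):
        s = vm.Spectrum(np.array([400.0, 500.0]), np.array([1.0, 2.0]))
        cal = vm.CalibrationCurve(np.array([300.0, 700.0]), np.array([1.0, 1.0]))
        out = vm.apply_calibration(s, cal)
        np.testing.assert_allclose(out.values, s.values)

    def test_scaling_gain(self):
        s = vm.Spectrum(np.array([400.0, 500.0]), np.array([1.0, 2.0]))
        cal = vm.CalibrationCurve(np.array([300.0, 700.0]), np.array([2.0, 2.0]))
        np.testing.assert_allclose(vm.apply_calibration(s, cal).values, [2.0, 4.0])

    def test_interpolated_gain(self):
        # gain 1 at 300, 3 at 700 -> 2 at 500 by hand linear interpolation
        s = vm.Spectrum(np.array([400.0, 500.0]), np.array([1.0, 1.0]))
        cal = vm.CalibrationCurve(np.array([300.0, 700.0]), np.array([1.0, 3.0]))
        out = vm.apply_calibration(s, cal)
        np.testing.assert_allclose(out.values, [1.5, 2.0])

    def test_coverage_error(self):
        s = vm.Spectrum(np.array([250.0, 500.0]), np.array([1.0, 1.0]))
        cal = vm.CalibrationCurve(np.array([300.0, 700.0]), np.array([1.0, 1.0]))
        with pytest.raises(vm.SpectrumError, match="span"):
            vm.apply_calibration(s, cal)


class TestToQuantal:
    def test_known_conversion_at_500nm(self):
        # oracle: direct evaluation of lambda / (h c) with CODATA constants
        expected = 500e-9 / (6.62607015e-34 * 2.99792458e8)
        s = vm.Spectrum(np.array([500.0, 501.0]), np.array([1.0, 0.0]))
        out = vm.to_quantal(s)
        np.testing.assert_allclose(out.values[0], expected, rtol=1e-12)
        assert out.units == "quantal"

    def test_zero_maps_to_zero(self):
        s = vm.Spectrum(np.array([400.0, 500.0]), np.array([0.0, 0.0]))
        np.testing.assert_array_equal(vm.to_quantal(s).values, [0.0, 0.0])

    def test_linearity(self):
        wl = np.array([400.0, 500.0, 600.0])
        v = np.array([1.0, 2.0, 3.0])
        a = vm.to_quantal(vm.Spectrum(wl, v)).values
        b = vm.to_quantal(vm.Spectrum(wl, 2 * v)).values
        np.testing.assert_allclose(b, 2 * a)

    def test_double_conversion_rejected(self):
        s = vm.to_quantal(vm.Spectrum(np.array([400.0, 500.0]), np.array([1.0, 1.0])))
        with pytest.raises(vm.SpectrumError, match="already"):
            vm.to_quantal(s)


class TestReceptorSensitivity:
    def test_peak_normalized_at_lambda_max(self):
        for lmax in (340.0, 435.0, 545.0):
            t = vm.receptor_sensitivity(lmax)
            assert t.curve.max() == 1.0
            peak_wl = t.wavelengths_nm[np.argmax(t.curve)]
            assert abs(peak_wl - lmax) <= 1.0

    def test_monotone_decay_above_peak(self):
        t = vm.receptor_sensitivity(545.0)
        sel = (t.wavelengths_nm >= 545) & (t.wavelengths_nm <= 695)
        assert np.all(np.diff(t.curve[sel]) < 0)

    def test_template_value_matches_hand_formula(self):
        # independent evaluation of the alpha-band pigment template at 500 nm
        lmax, wl = 545.0, 500.0
        x = lmax / wl
        a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
        raw = 1.0 / (
            np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
            + np.exp(-14.9 * (1.104 - x)) + 0.674
        )
        t = vm.receptor_sensitivity(lmax)
        # the implementation renormalizes by the grid maximum
        grid_max = max(
            1.0 / (np.exp(69.7 * (a - lmax / w)) + np.exp(28.0 * (0.922 - lmax / w))
                   + np.exp(-14.9 * (1.104 - lmax / w)) + 0.674)
            for w in t.wavelengths_nm
        )
        idx = int(np.where(t.wavelengths_nm == wl)[0][0])
        np.testing.assert_allclose(t.curve[idx], raw / grid_max, rtol=1e-10)

    def test_bounds(self):
        t = vm.receptor_sensitivity(435.0, include_beta_band=True)
        assert np.all(t.curve >= 0) and np.all(t.curve <= 1)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            vm.receptor_sensitivity(250.0)


def smooth_random_spectrum(rng, quantal=True):
    wl = np.arange(310.0, 671.0)
    vals = np.zeros_like(wl)
    for _ in range(4):
        mu = rng.uniform(320, 660)
        sig = rng.uniform(30, 150)
        vals += rng.uniform(0.1, 1.0) * np.exp(-(((wl - mu) / sig) ** 2))
    return vm.Spectrum(wl, vals, units="quantal" if quantal else "energy")


def riemann_oracle(s, template, lo=310.0, hi=670.0, step=0.01):
    grid = np.arange(lo, hi + step / 2, step)
    f = np.interp(grid, s.wavelengths_nm, s.values) * np.interp(
        grid, template.wavelengths_nm, template.curve, left=0, right=0
    )
    return np.trapezoid(f, grid)


class TestQuantumCatch:
    def test_zero_spectrum(self):
        s = vm.Spectrum(np.array([310.0, 670.0]), np.array([0.0, 0.0]), units="quantal")
        t = vm.receptor_sensitivity(545.0)
        assert vm.quantum_catch(s, t) == 0.0

    def test_linearity(self, rng):
        t = vm.receptor_sensitivity(435.0)
        s1 = smooth_random_spectrum(rng)
        s2 = smooth_random_spectrum(rng)
        combo = vm.Spectrum(s1.wavelengths_nm, 2 * s1.values + 3 * s2.values, units="quantal")
        q = vm.quantum_catch(combo, t)
        np.testing.assert_allclose(
            q, 2 * vm.quantum_catch(s1, t) + 3 * vm.quantum_catch(s2, t), rtol=1e-10
        )

    def test_flat_spectrum_vs_riemann_oracle(self):
        s = vm.Spectrum(np.array([300.0, 700.0]), np.array([1.0, 1.0]), units="quantal")
        t = vm.receptor_sensitivity(545.0)
        q = vm.quantum_catch(s, t)
        oracle = riemann_oracle(s, t)
        assert abs(q - oracle) / oracle < 1e-6

    def test_random_spectra_vs_riemann_oracle(self, rng):
        t = vm.receptor_sensitivity(340.0)
        for _ in range(5):
            s = smooth_random_spectrum(rng)
            q = vm.quantum_catch(s, t)
            oracle = riemann_oracle(s, t)
            assert abs(q - oracle) / oracle < 1e-6

    def test_no_overlap_error(self):
        s = vm.Spectrum(np.array([800.0, 900.0]), np.array([1.0, 1.0]), units="quantal")
        with pytest.raises(vm.SpectrumError, match="overlap"):
            vm.quantum_catch(s, vm.receptor_sensitivity(545.0, grid=(300, 700)))


class TestMichelson:
    def test_equality(self):
        assert vm.michelson_relative_catch(1, 1, 1) == 0.0

    def test_arithmetic_identity(self):
        np.testing.assert_allclose(vm.michelson_relative_catch(2, 1, 1), 1 / 3)

    def test_boundary(self):
        assert vm.michelson_relative_catch(0, 1, 1) == -1.0

    def test_all_zero_undefined(self):
        with pytest.raises(ZeroDivisionError):
            vm.michelson_relative_catch(0, 0, 0)

    @given(
        st.floats(0, 1e6), st.floats(0, 1e6), st.floats(0, 1e6)
    )
    def test_bounded(self, a, b, c):
        if a + (b + c) / 2 == 0:
            return
        assert -1.0 <= vm.michelson_relative_catch(a, b, c) <= 1.0


class TestCatchSet:
    def test_scale_invariance_of_contrasts(self, rng):
        s = smooth_random_spectrum(rng)
        c1 = vm.catch_set(s)
        c2 = vm.catch_set(vm.Spectrum(s.wavelengths_nm, 7.0 * s.values, units="quantal"))
        np.testing.assert_allclose(
            [c2.q_uv, c2.q_b, c2.q_lw], [7 * c1.q_uv, 7 * c1.q_b, 7 * c1.q_lw], rtol=1e-10
        )
        np.testing.assert_allclose(
            [c2.rel_uv, c2.rel_b, c2.rel_lw], [c1.rel_uv, c1.rel_b, c1.rel_lw], rtol=1e-10
        )

    def test_long_pass_sign_pattern(self):
        wl = np.arange(310.0, 671.0)
        vals = 1.0 / (1.0 + np.exp(-(wl - 560.0) / 10.0))  # long-pass
        c = vm.catch_set(vm.Spectrum(wl, vals, units="quantal"))
        assert c.rel_lw > 0 > c.rel_uv

    def test_photon_catch_lw_equals_q_lw(self, rng):
        c = vm.catch_set(smooth_random_spectrum(rng))
        assert c.photon_catch_lw == c.q_lw
        np.testing.assert_allclose(c.photon_catch_mean, (c.q_uv + c.q_b + c.q_lw) / 3)

    def test_energy_autoconversion(self, rng):
        s = smooth_random_spectrum(rng, quantal=False)
        c_energy = vm.catch_set(s)
        c_quantal = vm.catch_set(vm.to_quantal(s))
        np.testing.assert_allclose(c_energy.q_lw, c_quantal.q_lw, rtol=1e-12)


class TestLog10PhotonCatch:
    def test_power_of_ten(self):
        c = vm.CatchSet(1e10, 1e10, 1e10)
        lw, mean = vm.log10_photon_catch(c)
        assert lw == 10.0 and mean == 10.0

    def test_unity(self):
        assert vm.log10_photon_catch(vm.CatchSet(1, 1, 1)) == (0.0, 0.0)

    def test_hand_log(self):
        c = vm.CatchSet(3.2e10, 3.2e10, 3.2e10)
        lw, _ = vm.log10_photon_catch(c)
        np.testing.assert_allclose(lw, np.log10(3.2e10))
        assert round(lw, 3) == 10.505

    def test_zero_catch_error(self):
        with pytest.raises(ValueError):
            vm.log10_photon_catch(vm.CatchSet(1.0, 1.0, 0.0))
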