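import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oakselect.spectra import (Spectrum, SpectrumSet, band, cci,
                               qc_reflectance, read_spectra, resample,
                               splice_sensors, to_transmittance, wbi,
                               write_spectra)


def _smooth_spectrum(seed=0, n=200, lo=400.0, hi=2400.0):
    rng = np.random.default_rng(seed)
    wl = np.linspace(lo, hi, n)
    r = 0.3 + 0.1 * np.sin(wl / 300.0) + 0.02 * rng.standard_normal(n).cumsum() / n
    return Spectrum(wl, np.clip(r, 0.01, 0.99), {"id": f"s{seed}"})


class TestIO:
    def test_csv_matrix_parse(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("wavelength,a,b\n400,0.1,0.2\n410,0.15,0.25\n420,0.2,0.3\n")
        ss = read_spectra(p)
        assert len(ss) == 2 and ss.grid.size == 3
        assert ss["a"].reflectance[1] == 0.15

    def test_duplicate_wavelength_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("wl,a\n400,0.1\n410,0.2\n410,0.3\n")
        with pytest.raises(ValueError, match="duplicate wavelength"):
            read_spectra(p)

    def test_non_monotone_rejected(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("wl,a\n400,0.1\n420,0.2\n410,0.3\n")
        with pytest.raises(ValueError, match="non-monotone"):
            read_spectra(p)

    def test_non_numeric_cell_names_id_and_wavelength(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("wl,a\n400,0.1\n410,oops\n")
        with pytest.raises(ValueError, match="'a'.*410"):
            read_spectra(p)

    def test_round_trip_full_precision(self, tmp_path, rng):
        wl = np.sort(rng.uniform(400, 2400, 50))
        spectra = [Spectrum(wl, rng.uniform(0.05, 0.95, 50), {"id": f"i{k}"})
                   for k in range(4)]
        ss = SpectrumSet(spectra)
        path = tmp_path / "round.csv"
        write_spectra(ss, path)
        back = read_spectra(path)
        for orig, rec in zip(ss, back):
            np.testing.assert_allclose(rec.reflectance, orig.reflectance,
                                       rtol=1e-10, atol=0)

    def test_instrument_ascii(self, tmp_path):
        p = tmp_path / "leaf1.sig"
        p.write_text("# header\n400 0.10\n410 0.12\n420 0.14\n")
        ss = read_spectra(p, format="instrument_ascii")
        assert len(ss) == 1 and ss[0].id == "leaf1"
        assert ss[0].reflectance[2] == 0.14


class TestSplice:
    def test_empty_splice_is_identity(self):
        s = _smooth_spectrum()
        out = splice_sensors(s, [], [])
        np.testing.assert_array_equal(out.reflectance, s.reflectance)

    def test_continuous_spectrum_nearly_unchanged(self):
        wl = np.arange(900.0, 1101.0)
        s = Spectrum(wl, 0.2 + 1e-4 * (wl - 900.0))  # affine = its own interp
        out = splice_sensors(s, [990.0], [5.0])
        assert np.max(np.abs(out.reflectance - s.reflectance)) < 1e-12

    def test_step_discontinuity_repaired(self):
        wl = np.arange(900.0, 1101.0)
        r = np.full(wl.size, 0.3)
        r[wl >= 990.0] += 0.02
        out = splice_sensors(Spectrum(wl, r), [990.0], [5.0])
        assert np.max(np.abs(np.diff(out.reflectance))) < 0.005

    def test_idempotent(self):
        s = _smooth_spectrum(3)
        once = splice_sensors(s, [990.0, 1100.0], [5.0, 1.0])
        twice = splice_sensors(once, [990.0, 1100.0], [5.0, 1.0])
        np.testing.assert_allclose(twice.reflectance, once.reflectance,
                                   atol=1e-14)

    def test_window_past_grid_end_errors(self):
        s = _smooth_spectrum()
        with pytest.raises(ValueError, match="past grid"):
            splice_sensors(s, [2399.0], [5.0])

    def test_overlapping_windows_error(self):
        s = _smooth_spectrum()
        with pytest.raises(ValueError, match="overlap"):
            splice_sensors(s, [990.0, 992.0], [5.0, 5.0])


class TestResample:
    def test_count_on_10nm_grid(self):
        s = _smooth_spectrum(n=2001, lo=340, hi=2500)
        out = resample(s, np.arange(400.0, 2401.0, 10.0))
        assert out.wavelengths.size == 201

    def test_affine_exact(self):
        wl = np.linspace(400, 2400, 101)
        s = Spectrum(wl, 0.1 + 1e-4 * wl)
        grid = np.linspace(450, 2350, 57)
        out = resample(s, grid)
        np.testing.assert_allclose(out.reflectance, 0.1 + 1e-4 * grid,
                                   atol=1e-12)

    def test_matches_pointwise_interpolation_oracle(self, rng):
        s = _smooth_spectrum(7)
        grid = np.sort(rng.uniform(450, 2350, 40))
        out = resample(s, grid)
        # brute-force segment-by-segment interpolation
        for g, v in zip(grid, out.reflectance):
            i = np.searchsorted(s.wavelengths, g) - 1
            x0, x1 = s.wavelengths[i], s.wavelengths[i + 1]
            y0, y1 = s.reflectance[i], s.reflectance[i + 1]
            expect = y0 + (g - x0) * (y1 - y0) / (x1 - x0)
            assert abs(v - expect) < 1e-12

    def test_extrapolation_forbidden(self):
        s = _smooth_spectrum()
        with pytest.raises(ValueError, match="outside source range"):
            resample(s, np.array([300.0, 500.0]))

    def test_band_consistent_after_resample(self):
        s = _smooth_spectrum(5)
        grid = s.wavelengths[10:100]
        out = resample(s, grid)
        for lam in grid[::13]:
            assert abs(band(out, lam) - band(s, lam)) < 1e-12


class TestTransmittanceAndBand:
    def test_transmittance_values(self):
        s = Spectrum([600, 700, 800], [0.0, 0.3, 1.0])
        t = to_transmittance(s)
        np.testing.assert_allclose(t.reflectance, [1.0, 0.7, 0.0])

    def test_transmittance_involution(self):
        s = _smooth_spectrum(9)
        back = to_transmittance(to_transmittance(s))
        np.testing.assert_allclose(back.reflectance, s.reflectance, atol=1e-15)

    def test_transmittance_rejects_out_of_range(self):
        s = Spectrum([600, 700], [0.5, 1.2])
        with pytest.raises(ValueError, match="700"):
            to_transmittance(s)

    def test_band_on_grid_and_midpoint(self):
        s = Spectrum([690, 700, 710], [0.10, 0.12, 0.20])
        assert band(s, 700) == 0.12
        assert abs(band(s, 705) - 0.16) < 1e-12

    def test_band_out_of_range(self):
        s = Spectrum([690, 700], [0.1, 0.2])
        with pytest.raises(ValueError, match="outside grid"):
            band(s, 800)


class TestIndices:
    def _flat(self, r531, r645, r900=0.5, r970=0.45):
        wl = np.array([500.0, 531.0, 645.0, 700.0, 900.0, 970.0, 1000.0])
        r = np.array([0.1, r531, r645, 0.2, r900, r970, 0.5])
        return Spectrum(wl, r)

    def test_cci_arithmetic(self):
        assert abs(cci(self._flat(0.10, 0.05)) - 1.0 / 3.0) < 1e-12
        assert cci(self._flat(0.07, 0.07)) == 0.0
        assert cci(self._flat(0.10, 0.0)) == 1.0

    def test_cci_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            cci(self._flat(0.0, 0.0))

    def test_wbi_arithmetic(self):
        assert abs(wbi(self._flat(0.1, 0.05, r900=0.50, r970=0.45)) - 0.9) < 1e-12
        assert wbi(self._flat(0.1, 0.05, r900=0.4, r970=0.4)) == 1.0

    def test_wbi_scale_invariant(self):
        s = _smooth_spectrum(4)
        s2 = Spectrum(s.wavelengths, s.reflectance * 0.5)
        assert abs(wbi(s) - wbi(s2)) < 1e-12

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_cci_bounded_wbi_positive(self, a, b):
        s = self._flat(a, b, r900=max(a, 1e-3), r970=b)
        assert -1.0 <= cci(s) <= 1.0
        assert wbi(s) > 0


def test_qc_excludes_out_of_range_spectra():
    wl = np.array([500.0, 600.0])
    good = Spectrum(wl, [0.4, 0.5], {"id": "good"})
    bad = Spectrum(wl, [0.4, 1.03], {"id": "bad"})
    clean, report = qc_reflectance(SpectrumSet([good, bad]))
    assert [s.id for s in clean] == ["good"]
    row = report.set_index("id").loc["bad"]
    assert row["n_out_of_range"] == 1 and row["worst_value"] == 1.03
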