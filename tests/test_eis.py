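import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petkit import eis, synth
from petkit.errors import DataError


def make_spectrum(params, freqs=None, time_h=0.0):
    freqs = np.logspace(3, 6, 51) if freqs is None else freqs
    return eis.ImpedanceSpectrum(time_h, freqs, eis.randles_impedance(params, freqs))


class TestRandlesImpedance:
    def test_high_frequency_limit_is_rs(self):
        p = eis.RandlesParams(100.0, 1e6, 5e-12)
        z = eis.randles_impedance(p, 1e12)
        assert z.real == pytest.approx(100.0, rel=1e-3)
        assert abs(z.imag) < 1.0

    def test_low_frequency_limit_is_rs_plus_rct(self):
        p = eis.RandlesParams(100.0, 1e6, 5e-12)
        z = eis.randles_impedance(p, 1e-6)
        assert z.real == pytest.approx(100.0 + 1e6, rel=1e-6)

    def test_corner_frequency_closed_form(self):
        # at omega = 1/(R_ct C): Z = R_s + R_ct (1 - i)/2
        p = eis.RandlesParams(100.0, 1e6, 5.805e-12)
        f = 1.0 / (2 * np.pi * p.R_ct * p.C_film)
        z = eis.randles_impedance(p, f)
        assert z.real == pytest.approx(500_100.0)
        assert z.imag == pytest.approx(-500_000.0)

    def test_negative_frequency_rejected(self):
        with pytest.raises(DataError):
            eis.randles_impedance(eis.RandlesParams(1, 1, 1), -5.0)

    def test_nonpositive_params_rejected(self):
        with pytest.raises(DataError):
            eis.RandlesParams(0.0, 1e6, 5e-12)

    def test_imaginary_part_nonpositive_everywhere(self):
        p = eis.RandlesParams(50.0, 2e6, 8e-12)
        z = eis.randles_impedance(p, np.logspace(0, 9, 200))
        assert np.all(z.imag <= 0)


class TestFitRandles:
    def test_noiseless_round_trip(self):
        truth = eis.RandlesParams(120.0, 8e5, 6e-12)
        fit = eis.fit_randles(make_spectrum(truth)).params
        assert fit.R_s == pytest.approx(truth.R_s, rel=1e-6)
        assert fit.R_ct == pytest.approx(truth.R_ct, rel=1e-6)
        assert fit.C_film == pytest.approx(truth.C_film, rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_one_percent_noise_recovers_within_3pct(self, seed):
        # Monte-Carlo over 100 seeds: R_ct and C recover to < 0.5%; R_s is
        # weakly identified (R_ct/R_s = 1e4, its signature sits above the
        # sampled band) with errors up to ~45%, so only a loose bound is
        # asserted for it
        rng = np.random.default_rng(seed)
        truth = eis.RandlesParams(100.0, 1e6, 5.8e-12)
        freqs = np.logspace(3, 6, 51)
        z = eis.randles_impedance(truth, freqs)
        z = z.real * (1 + 0.01 * rng.standard_normal(51)) + 1j * z.imag * (
            1 + 0.01 * rng.standard_normal(51)
        )
        fit = eis.fit_randles(eis.ImpedanceSpectrum(0.0, freqs, z)).params
        assert fit.R_s == pytest.approx(truth.R_s, rel=0.5)
        assert fit.R_ct == pytest.approx(truth.R_ct, rel=0.03)
        assert fit.C_film == pytest.approx(truth.C_film, rel=0.03)

    def test_underdetermined_spectrum_rejected(self):
        with pytest.raises(DataError):
            eis.ImpedanceSpectrum(0.0, np.array([1e3, 1e4]), np.array([1 + 0j, 1 + 0j]))

    def test_fit_invariant_under_frequency_reordering(self):
        # the validated container keeps frequencies sorted; fitting a
        # spectrum assembled from shuffled rows gives identical parameters
        truth = eis.RandlesParams(90.0, 5e5, 7e-12)
        freqs = np.logspace(3, 6, 31)
        z = eis.randles_impedance(truth, freqs)
        order = np.random.default_rng(0).permutation(31)
        resorted = np.argsort(freqs[order])
        spec = eis.ImpedanceSpectrum(0.0, freqs[order][resorted], z[order][resorted])
        fit = eis.fit_randles(spec).params
        assert fit.C_film == pytest.approx(truth.C_film, rel=1e-6)


class TestThicknessConversion:
    def test_derived_example(self):
        d = eis.capacitance_to_thickness(5.805e-12)
        assert d == pytest.approx(225.0, abs=0.05)

    def test_doubling_c_halves_d(self):
        d1 = eis.capacitance_to_thickness(5e-12)
        d2 = eis.capacitance_to_thickness(1e-11)
        assert d1 == pytest.approx(2 * d2)

    @given(st.floats(min_value=1e-13, max_value=1e-9))
    def test_round_trip_exact(self, c):
        assert eis.thickness_to_capacitance(eis.capacitance_to_thickness(c)) == pytest.approx(
            c, rel=1e-12
        )

    def test_nonpositive_rejected(self):
        with pytest.raises(DataError):
            eis.capacitance_to_thickness(0.0)


class TestDegradationRate:
    def test_exact_on_linear_series(self):
        t = np.arange(0, 10, 0.05)
        series = eis.ThicknessSeries(t, 225.0 - 21.0 * t)
        r = eis.degradation_rate(series, (3.0, 8.0))
        assert r.rate_um_per_h == pytest.approx(21.0, rel=1e-9)

    def test_zero_on_constant_series(self):
        t = np.arange(0, 10, 0.05)
        series = eis.ThicknessSeries(t, np.full_like(t, 200.0))
        assert eis.degradation_rate(series).rate_um_per_h == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noisy_linear_series_within_tolerance(self, seed):
        # sigma 0.5 um at 3-min sampling: Monte-Carlo tolerance +/- 0.3 um/h
        rng = np.random.default_rng(seed)
        t = np.arange(0, 20, 0.05)
        d = 225.0 - 21.0 * t
        d = np.clip(d, 1.0, None) + rng.normal(0, 0.5, t.size)
        series = eis.ThicknessSeries(t, np.clip(d, 0.5, None))
        r = eis.degradation_rate(series, (3.0, 8.0))
        assert r.rate_um_per_h == pytest.approx(21.0, abs=0.3)

    def test_rate_invariant_under_time_shift_and_thickness_offset(self):
        rng = np.random.default_rng(7)
        t = np.arange(0, 12, 0.05)
        d = 225.0 - 10.0 * t + rng.normal(0, 0.3, t.size)
        r1 = eis.degradation_rate(eis.ThicknessSeries(t, d), (3, 8))
        r2 = eis.degradation_rate(eis.ThicknessSeries(t + 5.0, d + 40.0), (8, 13))
        assert r1.rate_um_per_h == pytest.approx(r2.rate_um_per_h, rel=1e-9)

    def test_window_outside_measurements_rejected(self):
        t = np.arange(0, 2, 0.1)
        series = eis.ThicknessSeries(t, 225.0 - t)
        with pytest.raises(DataError):
            eis.degradation_rate(series, (3.0, 8.0))


class TestPipelineRoundTrip:
    @settings(deadline=None, max_examples=3)
    @given(rate=st.sampled_from([5.0, 12.5, 21.0]))
    def test_noiseless_pipeline_recovers_rate_exactly(self, rate):
        spectra = synth.gen_eis_timeseries(
            rate_um_per_h=rate, duration_h=9.0, sample_interval_min=15, noise=0.0, seed=0
        )
        series, _ = eis.fit_spectra_series(spectra)
        r = eis.degradation_rate(series, (3.0, 8.0))
        assert r.rate_um_per_h == pytest.approx(rate, rel=1e-4)

    def test_noisy_pipeline_recovers_rate_within_2pct(self):
        spectra = synth.gen_eis_timeseries(rate_um_per_h=21.0, duration_h=10.0, noise=0.01, seed=11)
        series, _ = eis.fit_spectra_series(spectra)
        r = eis.degradation_rate(series, (3.0, 8.0))
        assert r.rate_um_per_h == pytest.approx(21.0, rel=0.02)


class TestSpectraCsv:
    def test_round_trip(self, tmp_path):
        spectra = synth.gen_eis_timeseries(duration_h=0.2, noise=0.01, seed=0)
        path = tmp_path / "spectra.csv"
        eis.write_spectra_csv(spectra, path)
        back = eis.read_spectra_csv(path)
        assert len(back) == len(spectra)
        np.testing.assert_allclose(back[0].impedance_ohm, spectra[0].impedance_ohm)
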