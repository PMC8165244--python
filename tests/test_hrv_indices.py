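"""HRV index oracles: hand-computed values, Parseval checks, known processes."""

import numpy as np
import pytest

from facepulse import hrv_indices as hrv
from facepulse import pulse_extraction as pe
from facepulse import synthetic_cohort as sc
from conftest import rr_from_list


def uniform(values, fs=4.0):
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    return hrv.UniformTachogram(values=values - mean, fs=fs, t0=0.0, mean=mean)


class TestTachogram:
    def test_constant_rr_detrends_to_zero(self, rr_800):
        tach = hrv.interpolate_tachogram(rr_800)
        assert np.allclose(tach.values, 0.0, atol=1e-9)
        assert tach.mean == pytest.approx(800.0)

    def test_sample_count_contract(self, rr_800):
        tach = hrv.interpolate_tachogram(rr_800)
        span = rr_800.t[-1] - rr_800.t[0]
        assert tach.values.size == int(np.floor(span * 4.0)) + 1

    def test_spline_matches_modulation_at_knots(self):
        t = np.cumsum(np.full(200, 0.8))
        values = 800 + 50 * np.sin(2 * np.pi * 0.1 * t)
        rr = pe.RRSeries(intervals=values, t=t)
        tach = hrv.interpolate_tachogram(rr)
        from scipy.interpolate import CubicSpline

        recon = CubicSpline(
            tach.t0 + np.arange(tach.values.size) / tach.fs, tach.values + tach.mean
        )
        assert np.abs(recon(t[5:-5]) - values[5:-5]).max() < 1.0

    def test_too_few_intervals_error(self):
        with pytest.raises(pe.UnusableSegmentError):
            hrv.interpolate_tachogram(rr_from_list([800] * 5))


class TestSpectra:
    def test_pure_hf_sinusoid_power_and_band(self):
        t = np.arange(0, 300, 0.25)
        a = 30.0
        tach = uniform(a * np.sin(2 * np.pi * 0.25 * t))
        spec = hrv.fft_spectrum(tach)
        bp = hrv.band_powers(spec)
        assert bp.hf / bp.total >= 0.90
        assert bp.hf == pytest.approx(a**2 / 2, rel=0.10)

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 20, size=2400)
        tach = uniform(x)
        spec = hrv.fft_spectrum(tach)
        total = np.trapezoid(spec.density, spec.frequencies)
        assert total == pytest.approx(np.var(x), rel=0.10)

    def test_zero_series_zero_spectrum(self):
        tach = uniform(np.zeros(400))
        assert np.allclose(hrv.fft_spectrum(tach).density, 0.0)
        assert np.allclose(hrv.ar_spectrum(tach).density, 0.0)

    def test_short_series_error(self):
        tach = uniform(np.zeros(40))
        with pytest.raises(ValueError, match="too short"):
            hrv.fft_spectrum(tach)
        with pytest.raises(ValueError, match="too short"):
            hrv.ar_spectrum(tach)

    def test_burg_locates_ar2_peak(self):
        rng = np.random.default_rng(5)
        fs, f0, rho = 4.0, 0.1, 0.97
        a1 = -2 * rho * np.cos(2 * np.pi * f0 / fs)
        a2 = rho**2
        x = np.zeros(4000)
        w = rng.normal(size=4000)
        for t in range(2, 4000):
            x[t] = -a1 * x[t - 1] - a2 * x[t - 2] + w[t]
        spec = hrv.ar_spectrum(uniform(x))
        peak = spec.frequencies[np.argmax(spec.density)]
        assert abs(peak - f0) <= 0.01

    def test_ar_sinusoid_dominant_in_hf(self):
        t = np.arange(0, 300, 0.25)
        tach = uniform(20 * np.sin(2 * np.pi * 0.25 * t))
        spec = hrv.ar_spectrum(tach)
        peak = spec.frequencies[np.argmax(spec.density)]
        assert hrv.HF_BAND[0] <= peak <= hrv.HF_BAND[1]


class TestBandPowers:
    def test_uniform_density_analytic_integral(self):
        freqs = np.linspace(0, 0.5, 501)
        spec = hrv.SpectrumEstimate(
            frequencies=freqs, density=np.ones_like(freqs), method="FFT"
        )
        bp = hrv.band_powers(spec)
        assert bp.vlf == pytest.approx(0.04, abs=1e-9)
        assert bp.lf == pytest.approx(0.11, abs=1e-9)
        assert bp.hf == pytest.approx(0.25, abs=1e-9)
        assert bp.total == pytest.approx(0.40, abs=1e-9)

    def test_all_lf_spectrum(self):
        freqs = np.linspace(0, 0.5, 501)
        density = np.where((freqs >= 0.05) & (freqs <= 0.12), 10.0, 0.0)
        bp = hrv.band_powers(
            hrv.SpectrumEstimate(frequencies=freqs, density=density, method="FFT")
        )
        assert bp.vlf == pytest.approx(0.0, abs=1e-6)
        assert bp.hf == pytest.approx(0.0, abs=1e-6)
        assert bp.lf == pytest.approx(bp.total)


class TestSpectralIndices:
    def test_symmetry(self):
        out = hrv.spectral_indices(hrv.BandPowers(vlf=0.1, lf=2.0, hf=2.0))
        assert out["lf_hf"] == pytest.approx(1.0)
        assert out["nlf"] == pytest.approx(0.5)
        assert out["nhf"] == pytest.approx(0.5)

    def test_hand_arithmetic(self):
        out = hrv.spectral_indices(hrv.BandPowers(vlf=0.04, lf=0.11, hf=0.25))
        assert out["lf_hf"] == pytest.approx(0.44)
        assert out["nlf"] == pytest.approx(0.11 / 0.36)
        assert out["rel_lf"] == pytest.approx(0.275)

    def test_normalized_powers_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vlf, lf, hf = rng.uniform(0.01, 5.0, size=3)
            out = hrv.spectral_indices(hrv.BandPowers(vlf=vlf, lf=lf, hf=hf))
            assert out["nlf"] + out["nhf"] == pytest.approx(1.0, abs=1e-9)

    def test_zero_hf_error(self):
        with pytest.raises(ZeroDivisionError):
            hrv.spectral_indices(hrv.BandPowers(vlf=0.1, lf=1.0, hf=0.0))


class TestTimeDomain:
    def test_constant_series(self):
        out = hrv.time_domain_indices(rr_from_list([1000.0] * 20))
        assert out["mean_rri"] == 1000.0
        assert out["mean_hr"] == pytest.approx(60.0)
        assert out["rmssd"] == 0.0
        assert out["pnn50"] == 0.0

    def test_rmssd_hand_value(self):
        out = hrv.time_domain_indices(rr_from_list([800, 810, 790, 805]))
        assert out["rmssd"] == pytest.approx(np.sqrt((100 + 400 + 225) / 3), abs=1e-6)
        assert out["rmssd"] == pytest.approx(15.546, abs=0.001)

    def test_pnn50_hand_count(self):
        out = hrv.time_domain_indices(rr_from_list([800, 860, 820, 880, 878]))
        assert out["pnn50"] == pytest.approx(0.5)

    def test_only_adjacent_kept_pairs_enter_diffs(self):
        rr = rr_from_list([800, 800, 2000, 900, 900])
        rr = pe.clean_rr(rr)  # 2000 dropped
        out = hrv.time_domain_indices(rr)
        # diffs: (800,800) and (900,900) only; the gap pair is excluded
        assert out["rmssd"] == 0.0
        assert out["pnn50"] == 0.0


class TestGeometric:
    def test_degenerate_single_bin(self):
        out = hrv.geometric_indices(rr_from_list([800.0] * 30))
        assert out["tri_index"] == 1.0
        assert out["tinn"] == pytest.approx(1000 / 128)

    def test_constructed_triangular_histogram(self):
        w = 6  # half-width in bins
        bw = hrv.HIST_BIN_MS
        values = []
        for k in range(-w + 1, w):
            values += [800.0 + k * bw] * (w - abs(k))
        out = hrv.geometric_indices(rr_from_list(values))
        assert abs(out["tinn"] - 2 * w * bw) <= bw

    def test_tri_index_at_least_one(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            values = rng.normal(850, 40, size=60).clip(400, 1400)
            out = hrv.geometric_indices(rr_from_list(values))
            assert out["tri_index"] >= 1.0


class TestPoincare:
    def test_constant_series_flags_undefined_ratio(self):
        out = hrv.poincare_indices(rr_from_list([900.0] * 20))
        assert out["sd1"] == 0.0 and out["sd2"] == 0.0
        assert np.isnan(out["sd1_sd2"])

    def test_alternating_series_hand_variance(self):
        out = hrv.poincare_indices(rr_from_list([800, 850] * 10 + [800]))
        assert out["sd1"] == pytest.approx(50 / np.sqrt(2), abs=0.01)
        assert out["sd2"] == pytest.approx(0.0, abs=1e-6)

    def test_sd1_equals_rmssd_over_sqrt2_for_balanced_diffs(self):
        # diffs sum to zero -> population identity is exact
        values = [800, 820, 790, 805, 800]
        rr = rr_from_list(values)
        sd1 = hrv.poincare_indices(rr)["sd1"]
        rmssd = hrv.time_domain_indices(rr)["rmssd"]
        assert sd1 == pytest.approx(rmssd / np.sqrt(2), abs=1e-9)


class TestIndexVector:
    def _vector(self, a_lf, a_hf, seed=0, duration=300.0):
        p = sc.IPFMParams(t0=0.85, a_lf=a_lf, f_lf=0.1, a_hf=a_hf, f_hf=0.25)
        beats = sc.generate_beat_train(p, duration, seed=seed)
        rr = pe.clean_rr(pe.beats_to_rr(beats))
        hb = sc.hb_pulse_train(beats, duration, 30.0, 0.11, 0.35)
        return hrv.compute_index_vector(rr, hb)

    def test_shape_and_order_contract(self):
        vec = self._vector(0.1, 0.1)
        arr = vec.as_array()
        assert arr.shape == (20,)
        assert list(vec.as_dict()) == list(hrv.INDEX_NAMES)
        assert not vec.short_segment

    def test_mean_hb_is_delegated_mean(self):
        vec = self._vector(0.1, 0.1, seed=3)
        p = sc.IPFMParams(t0=0.85, a_lf=0.1, f_lf=0.1, a_hf=0.1, f_hf=0.25)
        beats = sc.generate_beat_train(p, 300.0, seed=3)
        hb = sc.hb_pulse_train(beats, 300.0, 30.0, 0.11, 0.35)
        assert vec.mean_hb == pytest.approx(float(hb.mean()))

    def test_lf_dominant_vs_hf_dominant_ordering(self):
        lf_heavy = self._vector(0.25, 0.05, seed=1)
        hf_heavy = self._vector(0.05, 0.25, seed=1)
        assert lf_heavy.lf_hf_fft > hf_heavy.lf_hf_fft
        assert lf_heavy.lf_hf_ar > hf_heavy.lf_hf_ar

    def test_nlf_nhf_unit_sum_and_hr_consistency(self):
        for seed in range(5):
            vec = self._vector(0.1, 0.12, seed=seed)
            assert vec.nlf_fft + vec.nhf_fft == pytest.approx(1.0, abs=1e-9)
            assert vec.nlf_ar + vec.nhf_ar == pytest.approx(1.0, abs=1e-9)
            assert vec.mean_hr == pytest.approx(60000 / vec.mean_rri, rel=0.02)

    def test_fft_and_ar_lf_hf_agree_on_long_tachograms(self):
        """Sanity band: the two spectral methods should agree within 25%
        on long stationary synthetic tachograms."""
        agreements = []
        for seed in range(10):
            vec = self._vector(0.12, 0.12, seed=seed, duration=300.0)
            agreements.append(
                abs(vec.lf_hf_fft - vec.lf_hf_ar) / vec.lf_hf_fft
            )
        assert np.median(agreements) <= 0.25

    def test_short_segment_flag_on_baseline_length(self):
        vec = self._vector(0.1, 0.1, duration=30.0)
        assert vec.short_segment
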