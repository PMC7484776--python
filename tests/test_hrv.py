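"""HRV chain: filtering, detection, resampling, spectra, band and PDM indices."""
from __future__ import annotations

import numpy as np
import pytest

from fluidsense.datatypes import ECGRecord, InvalidInputError
from fluidsense.hrv import (
    band_powers,
    bandpass_ecg,
    build_rr,
    detect_r_peaks,
    ecg_to_rr,
    hrv_indices,
    hrv_spectrum,
    mean_heart_rate,
    pdm_indices,
    select_clean_window,
)
from fluidsense.synth import RRSpec, gen_ecg, gen_rr

FS = 256.0


def _sine_ecg(freq: float, duration: float = 40.0, fs: float = FS) -> ECGRecord:
    t = np.arange(int(duration * fs)) / fs
    return ECGRecord(samples=np.sin(2 * np.pi * freq * t), fs=fs)


class TestBandpass:
    def test_dc_rejected(self):
        ecg = ECGRecord(samples=np.ones(int(10 * FS)), fs=FS)
        out = bandpass_ecg(ecg)
        assert np.max(np.abs(out.samples)) < 1e-3

    def test_passband_preserved_within_1_db(self):
        out = bandpass_ecg(_sine_ecg(10.0))
        mid = out.samples[int(15 * FS) : int(25 * FS)]
        gain = np.max(np.abs(mid))
        assert 10 ** (-1 / 20) < gain < 10 ** (1 / 20)

    def test_60_hz_attenuated_20_db(self):
        out = bandpass_ecg(_sine_ecg(60.0))
        mid = out.samples[int(15 * FS) : int(25 * FS)]
        assert np.max(np.abs(mid)) < 10 ** (-20 / 20)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(InvalidInputError):
            bandpass_ecg(_sine_ecg(10.0), low=0.05, high=200.0)


class TestDetectRPeaks:
    def test_perfect_recovery_on_constant_rr(self):
        ecg = gen_ecg(RRSpec(mean_rr=1.0, a_lf=0, a_hf=0, noise_sd=0, duration=300), fs=FS)
        beats = detect_r_peaks(bandpass_ecg(ecg))
        truth = ecg.truth_beat_times
        assert beats.size == truth.size
        assert np.all(np.abs(beats - truth) * FS <= 1.0)  # within +-1 sample

    def test_modulated_rr_recovered_within_one_sample(self):
        ecg = gen_ecg(RRSpec(mean_rr=0.8, a_lf=0.04, a_hf=0.03, duration=300, seed=5), fs=FS)
        beats = detect_r_peaks(bandpass_ecg(ecg))
        truth = ecg.truth_beat_times
        assert beats.size == truth.size
        assert np.all(np.abs(beats - truth) * FS <= 1.0)

    def test_amplitude_scale_invariance(self):
        ecg = gen_ecg(RRSpec(mean_rr=0.9, duration=120, seed=2), fs=FS)
        filtered = bandpass_ecg(ecg)
        scaled = ECGRecord(samples=10.0 * filtered.samples, fs=FS)
        assert np.array_equal(detect_r_peaks(filtered), detect_r_peaks(scaled))

    def test_deleted_beat_gives_one_fewer_detection(self):
        ecg = gen_ecg(RRSpec(mean_rr=1.0, a_lf=0, a_hf=0, noise_sd=0, duration=120), fs=FS)
        base = detect_r_peaks(bandpass_ecg(ecg))
        # erase the QRS complex around the 30th truth beat
        samples = ecg.samples.copy()
        center = int(round(ecg.truth_beat_times[30] * FS))
        samples[center - 20 : center + 20] = 0.0
        edited = ECGRecord(samples=samples, fs=FS)
        assert detect_r_peaks(bandpass_ecg(edited)).size == base.size - 1

    def test_flat_signal_warns_and_returns_empty(self):
        ecg = ECGRecord(samples=np.zeros(int(10 * FS)), fs=FS)
        with pytest.warns(UserWarning):
            beats = detect_r_peaks(ecg)
        assert beats.size == 0


class TestBuildRR:
    def test_constant_intervals_resample_constant(self):
        beats = np.arange(0, 100, 0.8)
        rr = build_rr(beats)
        assert np.allclose(rr.resampled, 0.8, atol=1e-9)

    def test_spline_interpolates_knots_exactly(self):
        rng = np.random.default_rng(4)
        intervals = 0.8 + rng.normal(0, 0.05, 200)
        beats = np.concatenate([[0.0], np.cumsum(intervals)])
        rr = build_rr(beats)
        from scipy.interpolate import CubicSpline

        spline = CubicSpline(rr.beat_times[1:], rr.intervals)
        assert np.allclose(spline(beats[1:]), intervals, atol=1e-9)

    def test_resampled_length_matches_span(self):
        beats = np.arange(0, 60, 1.0)
        rr = build_rr(beats, resample_fs=4.0)
        assert rr.resampled.size == int(np.floor((beats[-1] - beats[0]) * 4.0)) + 1

    def test_too_few_beats_rejected(self):
        with pytest.raises(InvalidInputError):
            build_rr(np.array([0.0, 1.0, 2.0]))

    def test_modulation_frequency_survives_resampling(self):
        rr = gen_rr(RRSpec(a_lf=0.05, a_hf=0.0, noise_sd=0.0, duration=300, seed=0))
        freqs, psd = hrv_spectrum(rr)
        assert freqs[np.argmax(psd)] == pytest.approx(0.1, abs=4.0 / 256)


class TestMeanHeartRate:
    @pytest.mark.parametrize(
        "intervals, expected",
        [(np.full(100, 1.0), 60.0), (np.full(100, 0.8), 75.0),
         (np.tile([0.8, 1.2], 50), 60.0)],
    )
    def test_known_interval_patterns(self, intervals, expected):
        beats = np.concatenate([[0.0], np.cumsum(intervals)])
        assert mean_heart_rate(build_rr(beats)) == pytest.approx(expected)


def _uniform_rr(values: np.ndarray, fs: float = 4.0):
    """Wrap an already-even series as an RRSeries for spectrum tests."""
    from fluidsense.datatypes import RRSeries

    n = values.size
    beats = np.arange(n) / fs
    intervals = np.full(n - 1, 1.0 / fs)
    return RRSeries(
        beat_times=beats, intervals=intervals, resampled=values, resample_fs=fs
    )


class TestHrvSpectrum:
    def test_sinusoid_total_power_matches_parseval(self):
        t = np.arange(0, 300, 0.25)
        a = 0.04
        rr = _uniform_rr(0.8 + a * np.sin(2 * np.pi * 0.1 * t))
        freqs, psd = hrv_spectrum(rr)
        total = np.sum(psd) * (freqs[1] - freqs[0])
        assert total == pytest.approx(a**2 / 2, rel=0.05)
        assert freqs[np.argmax(psd)] == pytest.approx(0.1, abs=4.0 / 256)

    def test_white_noise_spectrum_flat_in_analysis_band(self):
        rng = np.random.default_rng(0)
        rr = _uniform_rr(0.8 + rng.normal(0, 0.01, 2688))  # ~20 half-overlap segments
        freqs, psd = hrv_spectrum(rr)
        band = psd[(freqs > 0) & (freqs <= 0.5)]
        assert band.max() / band.min() < 3.0

    def test_equal_amplitude_tones_give_equal_band_power(self):
        t = np.arange(0, 300, 0.25)
        x = 0.8 + 0.03 * np.sin(2 * np.pi * 0.1 * t) + 0.03 * np.sin(2 * np.pi * 0.25 * t)
        lf, hf, _, _ = band_powers(*hrv_spectrum(_uniform_rr(x)))
        assert lf == pytest.approx(hf, rel=0.10)

    def test_short_series_rejected_with_required_length(self):
        rr = _uniform_rr(np.full(100, 0.8))
        with pytest.raises(InvalidInputError, match="256"):
            hrv_spectrum(rr)


class TestBandPowers:
    def test_pure_lf_modulation(self):
        rr = gen_rr(RRSpec(a_lf=0.05, a_hf=0.0, noise_sd=0.0, duration=300, seed=0))
        _, _, nlf, nhf = band_powers(*hrv_spectrum(rr))
        assert nlf > 0.95 and nhf < 0.05

    def test_pure_hf_modulation(self):
        rr = gen_rr(RRSpec(a_lf=0.0, a_hf=0.05, noise_sd=0.0, duration=300, seed=0))
        _, _, nlf, nhf = band_powers(*hrv_spectrum(rr))
        assert nhf > 0.95 and nlf < 0.05

    def test_equal_amplitudes_split_evenly(self):
        rr = gen_rr(RRSpec(a_lf=0.04, a_hf=0.04, noise_sd=0.0, duration=300, seed=0))
        _, _, nlf, nhf = band_powers(*hrv_spectrum(rr))
        assert nlf == pytest.approx(0.5, abs=0.05)
        assert nlf + nhf == pytest.approx(1.0, abs=1e-12)

    def test_zero_band_power_rejected(self):
        freqs = np.linspace(0, 0.5, 65)
        with pytest.raises(InvalidInputError, match="normaliz"):
            band_powers(freqs, np.zeros_like(freqs))


class TestPdmIndices:
    def test_lf_dominance_orders_sympathetic_first(self):
        rr = gen_rr(RRSpec(a_lf=0.05, a_hf=0.0125, noise_sd=0.003, duration=300, seed=0))
        symp, para = pdm_indices(rr)
        assert symp > para >= 0

    def test_hf_dominance_orders_parasympathetic_first(self):
        rr = gen_rr(RRSpec(a_lf=0.0125, a_hf=0.05, noise_sd=0.003, duration=300, seed=0))
        symp, para = pdm_indices(rr)
        assert para > symp >= 0

    def test_sympathetic_index_monotone_in_lf_amplitude(self):
        means = []
        for a_lf in (0.01, 0.02, 0.04):
            vals = [
                pdm_indices(
                    gen_rr(RRSpec(a_lf=a_lf, a_hf=0.02, noise_sd=0.003,
                                  duration=300, seed=200 + k))
                )[0]
                for k in range(20)
            ]
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]

    def test_agrees_ordinally_with_band_powers_under_clear_dominance(self):
        agree = 0
        n = 20
        for k in range(n):
            lf_dom = k % 2 == 0
            rr = gen_rr(
                RRSpec(
                    a_lf=0.05 if lf_dom else 0.0125,
                    a_hf=0.0125 if lf_dom else 0.05,
                    noise_sd=0.003, duration=300, seed=300 + k,
                )
            )
            _, _, nlf, nhf = band_powers(*hrv_spectrum(rr))
            symp, para = pdm_indices(rr)
            agree += (nlf > nhf) == (symp > para)
        assert agree / n >= 0.9

    def test_short_series_rejected(self):
        rr = gen_rr(RRSpec(duration=120, seed=0))
        with pytest.raises(InvalidInputError, match="240"):
            pdm_indices(rr)


class TestEndToEnd:
    @pytest.mark.parametrize(
        "a_lf, a_hf",
        [(0.05, 0.0), (0.0, 0.05), (0.05, 0.0125), (0.0125, 0.05)],
    )
    def test_band_dominance_survives_the_full_chain(self, a_lf, a_hf):
        spec = RRSpec(a_lf=a_lf, a_hf=a_hf, noise_sd=0.003, duration=300, seed=17)
        rr = ecg_to_rr(gen_ecg(spec, fs=FS))
        idx = hrv_indices(rr)
        if a_lf > a_hf:
            assert idx.nlf > idx.nhf
            assert idx.pdmi_symp > idx.pdmi_para
        else:
            assert idx.nhf > idx.nlf
            assert idx.pdmi_para > idx.pdmi_symp
        assert idx.nlf + idx.nhf == pytest.approx(1.0, abs=1e-12)

    def test_clean_window_trims_to_about_four_minutes(self):
        ecg = gen_ecg(RRSpec(mean_rr=0.8, duration=300, seed=1), fs=FS)
        beats = detect_r_peaks(bandpass_ecg(ecg))
        window = select_clean_window(beats, duration=240.0)
        span = window[-1] - window[0]
        assert 240.0 <= span < 245.0

    def test_clean_window_avoids_artifact_region(self):
        # constant-RR beats with a burst of spurious short intervals at the end
        clean = np.arange(0, 290, 0.8)
        noisy = np.sort(np.concatenate([clean, np.arange(285, 289, 0.1)]))
        window = select_clean_window(noisy, duration=240.0)
        assert window[-1] < 285.0
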