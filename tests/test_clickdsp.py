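"""Feature-extraction tests: filtering, detection, spectra, bandwidths, ICI."""

import numpy as np
import pytest

from botoclick.audio_io import Waveform
from botoclick.clickdsp import (
    ClickEvent,
    ClickSpectrum,
    SpectroConfig,
    bandwidth_at,
    click_spectrum,
    compute_ici,
    detect_clicks,
    extract_train,
    highpass,
    peak_frequency,
)
from botoclick.synthgen import PulseSpec, gaussian_click, gaussian_sigma, render_train

RATE = 400_000.0
CFG = SpectroConfig()


def tone(freq, duration=0.05, amp=0.5, rate=RATE):
    t = np.arange(int(duration * rate)) / rate
    return Waveform(samples=amp * np.sin(2 * np.pi * freq * t), rate=rate)


def centered_snippet(pulse, nfft=256, noise=None, rng=None):
    x = np.zeros(nfft)
    c = len(pulse) // 2
    lo = nfft // 2 - c
    assert lo >= 0, "pulse longer than snippet"
    x[lo : lo + len(pulse)] = pulse
    if noise is not None:
        x = x + rng.normal(0, noise, size=nfft)
    return x


def rms_db(x):
    return 20 * np.log10(np.sqrt(np.mean(x**2)))


class TestHighpass:
    def test_stopband_and_passband_levels(self):
        # oracle: the filter's magnitude response at the tone frequencies
        lo, hi = tone(1e3), tone(50e3)
        out_lo, out_hi = highpass(lo), highpass(hi)
        assert rms_db(out_lo.samples) - rms_db(lo.samples) <= -40
        assert abs(rms_db(out_hi.samples) - rms_db(hi.samples)) <= 1
        assert out_lo.samples.size == lo.samples.size

    def test_zero_input_zero_output(self):
        w = Waveform(np.zeros(1000), RATE)
        assert np.allclose(highpass(w).samples, 0)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass(tone(1e3), cutoff_hz=250e3)


class TestDetect:
    def test_recovers_all_clicks_over_seeds(self, small_train_spec):
        for seed in range(20):
            w, truth = render_train(small_train_spec, RATE, seed=seed)
            events = detect_clicks(highpass(w), CFG)
            assert len(events) == len(truth)

    def test_pure_noise_no_events(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            w = Waveform(rng.normal(0, 0.01, size=120_000), RATE)
            assert detect_clicks(w, CFG) == []

    def test_refractory_merges_close_pulses(self):
        rng = np.random.default_rng(0)
        pulse = gaussian_click(PulseSpec(50e3, 60e3, 10.0, 0.5), RATE)
        x = rng.normal(0, 1e-3, size=4000)
        for start in (1800, 1800 + 120):  # 0.3 ms apart < 0.5 ms refractory
            x[start : start + pulse.size] += pulse
        events = detect_clicks(Waveform(x, RATE), CFG)
        assert len(events) == 1

    def test_short_train_rejected(self):
        with pytest.raises(ValueError, match="nfft"):
            detect_clicks(Waveform(np.zeros(100), RATE), CFG)

    def test_amplitude_scaling_invariance(self, small_train_spec):
        w, _ = render_train(small_train_spec, RATE, seed=4)
        hp = highpass(w)
        scaled = Waveform(hp.samples * 0.05, RATE)
        e1 = detect_clicks(hp, CFG)
        e2 = detect_clicks(scaled, CFG)
        assert len(e1) == len(e2)
        f1 = [peak_frequency(click_spectrum(e, CFG, RATE)) for e in e1]
        f2 = [peak_frequency(click_spectrum(e, CFG, RATE)) for e in e2]
        assert np.allclose(f1, f2, atol=1e-9)


class TestSpectrum:
    def test_tone_single_dominant_lobe(self):
        t = np.arange(256) / RATE
        snip = 0.5 * np.cos(2 * np.pi * 50e3 * t)
        s = click_spectrum(ClickEvent(0, 0.5, snip, 30), CFG, RATE)
        assert peak_frequency(s) == pytest.approx(50.0, abs=0.2)
        far = np.isfinite(s.power_db) & (np.abs(s.freqs - 50e3) > 10e3)
        assert np.nanmax(s.power_db[far]) < -20

    def test_gaussian_matches_analytic_within_half_db(self):
        f0, bw3 = 50e3, 26.5e3
        pulse = gaussian_click(PulseSpec(f0, bw3, 3.0, 0.5), RATE)
        snip = centered_snippet(pulse)
        s = click_spectrum(ClickEvent(0, 0.5, snip, 30), CFG, RATE)
        sigma_t = gaussian_sigma(bw3, 3.0)
        sigma_f = 1 / (2 * np.pi * sigma_t)
        analytic_db = -10 * np.log10(np.e) * ((s.freqs - f0) / sigma_f) ** 2
        top = np.isfinite(s.power_db) & (analytic_db >= -10)
        assert np.max(np.abs(s.power_db[top] - analytic_db[top])) < 0.5

    def test_all_zero_snippet_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            click_spectrum(ClickEvent(0, 0, np.zeros(256), 0), CFG, RATE)

    def test_max_is_zero_db(self, small_train_spec):
        w, _ = render_train(small_train_spec, RATE, seed=0)
        e = detect_clicks(highpass(w), CFG)[0]
        s = click_spectrum(e, CFG, RATE)
        assert np.nanmax(s.power_db) == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.isnan(s.power_db[s.freqs < CFG.highpass_hz]))


def synthetic_spectrum(values_db, df=1000.0):
    """Hand-built spectrum; resolution = grid spacing (guard of 4 bins)."""
    values = np.asarray(values_db, dtype=float)
    return ClickSpectrum(
        freqs=np.arange(values.size) * df + 20e3,
        power_db=values,
        resolution_hz=df,
    )


class TestPeakFrequency:
    def test_gaussian_peak_recovered(self):
        pulse = gaussian_click(PulseSpec(60e3, 40e3, 10.0, 0.5), RATE)
        s = click_spectrum(ClickEvent(0, 0.5, centered_snippet(pulse), 30), CFG, RATE)
        assert peak_frequency(s) == pytest.approx(60.0, abs=0.4)

    def test_tie_breaks_to_lowest_frequency(self):
        db = np.full(100, -30.0)
        db[20] = 0.0  # 40 kHz
        db[60] = 0.0  # 80 kHz
        s = synthetic_spectrum(db)
        assert peak_frequency(s) == pytest.approx(40.0)


class TestBandwidth:
    def test_gaussian_bandwidths_match_closed_form(self):
        # sigma = 10 us -> BW3 = 26.5 kHz, BW10 = 48.3 kHz
        pulse = gaussian_click(PulseSpec(60e3, 26.5e3, 3.0, 0.5), RATE)
        s = click_spectrum(ClickEvent(0, 0.5, centered_snippet(pulse), 30), CFG, RATE)
        bw3, c3 = bandwidth_at(s, 3)
        bw10, c10 = bandwidth_at(s, 10)
        assert not c3 and not c10
        assert bw3 == pytest.approx(26.5, rel=0.05)
        assert bw10 == pytest.approx(48.3, rel=0.05)
        assert 1.80 <= bw10 / bw3 <= 1.85

    def test_windowed_tone_width_matches_window_oracle(self):
        # a long tone's click-spectrum width is set by the Hamming window:
        # oracle = the same measurement on the window transform itself
        t = np.arange(256) / RATE
        snip = 0.5 * np.cos(2 * np.pi * 100e3 * t)
        s = click_spectrum(ClickEvent(0, 0.5, snip, 30), CFG, RATE)
        bw3, _ = bandwidth_at(s, 3)

        n = 256 * CFG.zero_pad_factor
        w = np.abs(np.fft.rfft(np.hamming(256), n)) ** 2
        with np.errstate(divide="ignore"):
            wdb = 10 * np.log10(w / w.max())
        freqs = np.fft.rfftfreq(n, 1 / RATE)
        above = wdb >= -3
        hi = int(np.argmax(~above))  # first bin below -3 dB
        # linear interpolation, then double for the two-sided width
        frac = (wdb[hi - 1] + 3) / (wdb[hi - 1] - wdb[hi])
        half = freqs[hi - 1] + frac * (freqs[hi] - freqs[hi - 1])
        assert bw3 * 1e3 == pytest.approx(2 * half, abs=RATE / 256)

    def test_shoulder_above_level_ignored(self):
        # -8 dB shoulder between peak and the -10 dB point must not stop
        # the walk; the first genuine crossing defines the bandwidth
        db = np.array([-30.0] * 5 + [-12, -4, 0, -4, -8, -8, -8, -12, -30, -30, -30])
        s = synthetic_spectrum(db)
        bw10, clipped = bandwidth_at(s, 10, guard_bins=1)
        assert not clipped
        lo = 20e3 + 1000 * (5 + (12 - 10) / (12 - 4))
        hi = 20e3 + 1000 * (11 + (10 - 8) / (12 - 8))
        assert bw10 * 1e3 == pytest.approx(hi - lo)

    def test_subresolution_dip_walked_through(self):
        # one-bin noise dip below the level is narrower than the window
        # main lobe and is ignored; the sustained crossing counts
        db = np.array(
            [-30.0] * 4 + [-15, -5, 0, -5, -10.5, -5, -6, -8, -11, -12, -13, -30, -30]
        )
        s = synthetic_spectrum(db)
        bw_guarded, _ = bandwidth_at(s, 10)  # default guard = 4 bins
        bw_naive, _ = bandwidth_at(s, 10, guard_bins=1)
        assert bw_naive < bw_guarded  # naive rule stops at the dip
        hi = 11 + (10 - 8) / (11 - 8)  # sustained crossing into bin 12
        assert bw_guarded > bw_naive

    def test_clipped_at_highpass_mask(self):
        db = np.concatenate([[np.nan] * 3, np.linspace(-2, 0, 8), np.linspace(-1, -40, 20)])
        s = synthetic_spectrum(db)
        bw10, clipped = bandwidth_at(s, 10)
        assert clipped

    def test_bw10_geq_bw3_property(self, small_train_spec):
        w, _ = render_train(small_train_spec, RATE, seed=9)
        for e in detect_clicks(highpass(w), CFG):
            s = click_spectrum(e, CFG, RATE)
            bw3, c3 = bandwidth_at(s, 3)
            bw10, c10 = bandwidth_at(s, 10)
            if not (c3 or c10):
                assert bw10 >= bw3


class TestICI:
    def _events(self, times_s):
        return [ClickEvent(t, 1.0, np.zeros(256), 30.0) for t in times_s]

    def test_successive_differences_ms(self):
        icis = compute_ici(self._events([0.0, 0.010, 0.020]))
        assert np.allclose(icis, [10.0, 10.0])

    def test_overlapped_always_empty(self):
        assert compute_ici(self._events([0.0, 0.01, 0.02]), overlapped=True).size == 0

    def test_single_event_empty(self):
        assert compute_ici(self._events([0.5])).size == 0


class TestExtractTrain:
    def test_recovers_ground_truth_features(self, small_train_spec):
        # mean absolute Fp error <= 1 kHz at +30 dB SNR, pooled over trains
        errs = []
        for seed in range(12):
            w, truth = render_train(small_train_spec, RATE, seed=seed)
            tf = extract_train(w, train_id="t", lineage="Ia")
            assert len(tf.clicks) == len(truth)
            errs.append(
                np.abs(
                    np.array([c.fp_khz for c in tf.clicks])
                    - truth["f0_hz"].to_numpy() / 1e3
                )
            )
            if seed == 0:
                true_ici = np.diff(truth["time_s"]) * 1e3
                assert np.allclose(tf.icis_ms, true_ici, atol=0.05)
        assert np.concatenate(errs).mean() <= 1.0

    def test_overlapped_selection_suppresses_ici(self, small_train_spec):
        from botoclick.audio_io import TrainSelection

        w, _ = render_train(small_train_spec, RATE, seed=12)
        sel = TrainSelection("x", 0.0, w.duration, overlapped=True)
        tf = extract_train(w, selection=sel)
        assert len(tf.clicks) > 0
        assert tf.icis_ms.size == 0

    def test_silence_gives_empty_result_with_warning(self, caplog):
        w = Waveform(np.zeros(80_000), RATE)
        with caplog.at_level("WARNING"):
            tf = extract_train(w, train_id="quiet")
        assert tf.clicks == []
        assert any("no clicks" in r.message for r in caplog.records)
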