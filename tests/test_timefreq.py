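"""Morlet transform, baseline normalization, resampling and phase."""
import numpy as np
import pytest
from scipy import signal as sp_signal
from scipy import stats

import thetareplay as tr
from thetareplay import timefreq


@pytest.fixture(scope="module")
def spec():
    return tr.WaveletSpec()


class TestFrequencyGrid:
    def test_grid_counts(self, spec):
        g = spec.freqs
        assert len(g) == 49
        assert ((g >= 2) & (g <= 20)).sum() == 19
        assert ((g >= 21) & (g <= 79)).sum() == 30
        assert timefreq.feature_band_mask(g).sum() == 38

    def test_sigma_relations_at_7hz(self, spec):
        assert spec.sigma_f(7.0) == pytest.approx(1.0)
        assert spec.sigma_t(7.0) == pytest.approx(1.0 / (2 * np.pi), rel=1e-12)

    def test_grid_monotone_required(self):
        with pytest.raises(ValueError):
            tr.WaveletSpec(freqs=np.array([10.0, 5.0]))


class TestCWTAmplitude:
    def test_zero_signal_zero_amplitude(self, spec, make_epochs, std_times):
        ep = make_epochs(np.zeros_like(std_times))
        out = tr.cwt_amplitude(ep, spec, freqs=np.array([10.0]), times=np.array([3000.0]))
        assert np.all(out.amplitude == 0)

    @pytest.mark.parametrize("norm", ["energy", "peak"])
    def test_sinusoid_gaussian_response(self, norm, make_epochs, std_times):
        """A pure sinusoid's response across bins follows the analytic
        Morlet frequency response (a Gaussian in frequency, with a
        1/sqrt(f) prefactor under unit-energy normalization)."""
        f0 = 10.0
        ep = make_epochs(np.sin(2 * np.pi * f0 * std_times / 1000.0))
        freqs = np.arange(5.0, 16.0)
        s = tr.WaveletSpec(normalization=norm)
        amp = tr.cwt_amplitude(ep, s, freqs=freqs, times=np.array([3000.0])).amplitude[0, 0, :, 0]
        sf = freqs / 7.0
        pred = np.exp(-((freqs - f0) ** 2) / (2 * sf**2))
        if norm == "energy":
            pred = pred * freqs**-0.5
        assert freqs[np.argmax(amp)] == f0
        assert np.max(np.abs(amp / amp.max() - pred / pred.max())) < 0.01

    def test_amplitude_linearity(self, spec, make_epochs, std_times):
        wave = np.sin(2 * np.pi * 15.0 * std_times / 1000.0) + 0.3 * np.random.default_rng(0).standard_normal(len(std_times))
        t_out = np.array([2000.0, 3000.0, 4000.0])
        a1 = tr.cwt_amplitude(make_epochs(wave), spec, freqs=np.array([15.0]), times=t_out).amplitude
        a2 = tr.cwt_amplitude(make_epochs(2 * wave), spec, freqs=np.array([15.0]), times=t_out).amplitude
        np.testing.assert_allclose(a2, 2 * a1, rtol=1e-5)

    def test_windowed_matches_fft_path(self, spec, make_epochs, std_times):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.standard_normal(len(std_times)))
        idx = np.arange(800, 1150)  # 350 output samples -> FFT path
        t_many = std_times[idx]
        a_fft = tr.cwt_amplitude(ep, spec, freqs=np.array([10.0, 40.0]), times=t_many).amplitude
        a_win = tr.cwt_amplitude(ep, spec, freqs=np.array([10.0, 40.0]), times=t_many[:100]).amplitude
        np.testing.assert_allclose(a_fft[..., :100], a_win, atol=1e-5)

    def test_agrees_with_mne_morlet(self, make_epochs, std_times):
        """Independent oracle: mne's Morlet transform with n_cycles = 7
        matches our amplitude (up to per-frequency scale) and phase."""
        mne_tf = pytest.importorskip("mne.time_frequency")
        rng = np.random.default_rng(2)
        wave = rng.standard_normal(len(std_times))
        ep = make_epochs(wave)
        freqs = np.array([8.0, 20.0, 40.0])
        out = mne_tf.tfr_array_morlet(
            wave[None, None, :], sfreq=480.0, freqs=freqs, n_cycles=7.0, output="complex"
        )[0, 0]
        mid = slice(1000, 3300)
        ours = tr.cwt_amplitude(ep, tr.WaveletSpec(), freqs=freqs, times=std_times[mid])
        ph = [
            tr.instantaneous_phase(ep, f, tr.WaveletSpec(freqs=freqs), times=std_times[mid])
            for f in freqs
        ]
        for i in range(len(freqs)):
            a_mne = np.abs(out[i, mid])
            a_ours = ours.amplitude[0, 0, i]
            ratio = a_ours / a_mne
            assert np.ptp(ratio) / np.mean(ratio) < 1e-3  # same shape, fixed scale
            dphi = np.angle(np.exp(1j * (np.angle(out[i, mid]) - ph[i].phase[0, 0])))
            assert np.max(np.abs(dphi)) < 1e-3

    def test_edge_effect_error_on_short_epoch(self, spec, make_epochs):
        short = np.zeros(480)  # 1 s epoch < 7-cycle support at 2 Hz
        ep = make_epochs(short)
        with pytest.raises(ValueError, match="support"):
            tr.cwt_amplitude(ep, spec, freqs=np.array([2.0]), times=np.array([-500.0]))


class TestBaselineNormalize:
    def _const_tfr(self, value, times):
        amp = np.full((1, 1, 1, len(times)), float(value))
        return tr.TFRepresentation(amp, np.array([10.0]), times)

    def test_constant_becomes_zero(self):
        times = np.arange(-900.0, 8000.0, 4.0)
        out = tr.baseline_normalize(self._const_tfr(3.0, times))
        assert np.all(out.amplitude == 0)

    def test_step_example(self):
        times = np.arange(-900.0, 8000.0, 4.0)
        tfr = self._const_tfr(5.0, times)
        inside = (times >= -500) & (times <= -100)
        tfr.amplitude[..., inside] = 3.0
        out = tr.baseline_normalize(tfr)
        assert np.all(out.amplitude[..., inside] == 0)
        assert np.all(out.amplitude[..., ~inside] == 2.0)

    def test_idempotent(self):
        times = np.arange(-900.0, 8000.0, 4.0)
        tfr = self._const_tfr(1.0, times)
        tfr.amplitude += np.random.default_rng(0).random(tfr.amplitude.shape)
        once = tr.baseline_normalize(tfr)
        twice = tr.baseline_normalize(once)
        np.testing.assert_allclose(once.amplitude, twice.amplitude, atol=1e-12)
        base = (once.times >= -500) & (once.times <= -100)
        assert abs(once.amplitude[..., base].mean()) < 1e-12

    def test_window_outside_epoch_errors(self):
        times = np.arange(3000.0, 8000.0, 4.0)
        with pytest.raises(ValueError):
            tr.baseline_normalize(self._const_tfr(1.0, times))


class TestDownsample:
    def test_9s_epoch_sample_count(self):
        times = -1000.0 + 1000.0 * np.arange(4320) / 480.0
        tfr = tr.TFRepresentation(np.ones((1, 1, 1, 4320)), np.array([10.0]), times)
        out = tr.downsample_tf(tfr, 250.0)
        assert len(out.times) == 2250  # 9 s x 250 Hz
        assert np.allclose(np.diff(out.times), 4.0)

    def test_constant_preserved(self):
        times = -1000.0 + 1000.0 * np.arange(4320) / 480.0
        tfr = tr.TFRepresentation(np.full((1, 1, 1, 4320), 7.5), np.array([10.0]), times)
        out = tr.downsample_tf(tfr, 250.0)
        np.testing.assert_allclose(out.amplitude, 7.5, rtol=1e-3)

    def test_bandlimited_interp_error_below_1pct(self):
        times = -1000.0 + 1000.0 * np.arange(4320) / 480.0
        wave = np.sin(2 * np.pi * 60.0 * times / 1000.0)
        tfr = tr.TFRepresentation(wave[None, None, None, :], np.array([10.0]), times)
        out = tr.downsample_tf(tfr, 250.0)
        truth = np.sin(2 * np.pi * 60.0 * out.times / 1000.0)
        # edges carry the resampling-filter transient; they lie inside the
        # 1 s pad margins of the analysis epoch
        assert np.max(np.abs(out.amplitude[0, 0, 0, 60:-60] - truth[60:-60])) < 0.01

    def test_upsampling_refused(self):
        times = np.arange(0.0, 1000.0, 4.0)
        tfr = tr.TFRepresentation(np.ones((1, 1, 1, len(times))), np.array([10.0]), times)
        with pytest.raises(ValueError):
            tr.downsample_tf(tfr, 480.0)


class TestHighpass:
    def test_6hz_phase_preserved(self, make_epochs, std_times):
        wave = np.cos(2 * np.pi * 6.0 * std_times / 1000.0)
        out = tr.zero_phase_highpass(make_epochs(wave), 3.0)
        mid = slice(1500, 2800)
        analytic_in = sp_signal.hilbert(wave)[mid]
        analytic_out = sp_signal.hilbert(out.signal[0, 0])[mid]
        dphi = np.angle(analytic_out / analytic_in)
        assert np.max(np.abs(dphi)) < 0.05

    def test_dc_rejected(self, make_epochs, std_times):
        out = tr.zero_phase_highpass(make_epochs(np.full_like(std_times, 4.0)), 3.0)
        assert np.max(np.abs(out.signal[0, 0, 500:-500])) < 1e-6

    def test_1hz_attenuated(self, make_epochs, std_times):
        wave = np.sin(2 * np.pi * 1.0 * std_times / 1000.0)
        out = tr.zero_phase_highpass(make_epochs(wave), 3.0)
        assert np.max(np.abs(out.signal[0, 0, 1000:-1000])) < 0.1

    def test_cutoff_at_nyquist_errors(self, make_epochs, std_times):
        with pytest.raises(ValueError):
            tr.zero_phase_highpass(make_epochs(np.zeros_like(std_times)), 240.0)


class TestInstantaneousPhase:
    def test_cosine_peak_phase_zero(self, make_epochs, std_times):
        ep = make_epochs(np.cos(2 * np.pi * 6.0 * std_times / 1000.0))
        # 6 Hz cosine peaks at integer multiples of its period
        out = tr.instantaneous_phase(ep, 6.0, times=np.array([3000.0, 4000.0]))
        assert np.max(np.abs(out.phase)) < 0.01

    def test_phase_slope_matches_frequency(self, make_epochs, std_times):
        f = 5.0
        ep = make_epochs(np.cos(2 * np.pi * f * std_times / 1000.0))
        grid = np.arange(3000.0, 5000.0, 4.0)
        out = tr.instantaneous_phase(ep, f, times=grid)
        unwrapped = np.unwrap(out.phase[0, 0])
        slope = stats.linregress(out.times / 1000.0, unwrapped).slope
        assert slope == pytest.approx(2 * np.pi * f, rel=0.01)

    def test_sin_cos_quarter_cycle_offset(self, make_epochs, std_times):
        f = 6.0
        arg = 2 * np.pi * f * std_times / 1000.0
        grid = np.arange(3000.0, 3500.0, 4.0)
        ph_cos = tr.instantaneous_phase(make_epochs(np.cos(arg)), f, times=grid)
        ph_sin = tr.instantaneous_phase(make_epochs(np.sin(arg)), f, times=grid)
        d = np.angle(np.exp(1j * (ph_cos.phase - ph_sin.phase)))
        np.testing.assert_allclose(d, np.pi / 2, atol=0.01)

    def test_off_grid_frequency_rejected(self, make_epochs, std_times):
        ep = make_epochs(np.zeros_like(std_times))
        with pytest.raises(ValueError, match="grid"):
            tr.instantaneous_phase(ep, 6.3)

    def test_wrapped_range(self, make_epochs, std_times):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.standard_normal(len(std_times)))
        out = tr.instantaneous_phase(ep, 6.0, times=np.arange(3000.0, 4000.0, 4.0))
        assert np.all(out.phase > -np.pi) and np.all(out.phase <= np.pi)


def test_phase_recovery_from_generator():
    """Estimated theta phase at coupled sensors tracks the planted phase
    within 0.15 rad RMS over the mid-maintenance window (theta SNR 2)."""
    params = tr.GeneratorParams(
        n_subjects=1, n_sensors=16, replay_rate=0.0, theta_amplitude=2.0,
        rng_seed=11,
    )
    ep, gt = tr.generate_subject(params, 0)
    hp = tr.zero_phase_highpass(ep, 3.0)
    grid = np.arange(4000.0, 7000.0, 4.0)
    ph = tr.instantaneous_phase(hp, 6.0, times=grid)
    sens = np.flatnonzero(gt.cluster_of_sensor == gt.coupling_clusters["configural"])
    trials = [j for j in range(len(ep.metadata)) if ep.metadata.iloc[j]["condition"] == "configural"]
    errs = []
    for j in trials[:10]:
        planted = 2 * np.pi * gt.theta_freq * ph.times / 1000.0 + gt.theta_offset[j, gt.coupling_clusters["configural"]]
        for s in sens[:3]:
            d = np.angle(np.exp(1j * (ph.phase[j, s] - planted)))
            errs.append(d)
    rms = float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))
    assert rms < 0.15
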