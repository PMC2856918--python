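"""Morlet wavelet time-frequency analysis.

The single-trial transform uses a complex Morlet wavelet

    w(f, t) = (2 pi sigma_t^2)^(-1/2) exp(-t^2 / (2 sigma_t^2)) exp(2 pi i f t)

with a fixed ratio f / sigma_f = 7 (sigma_f = 1 / (2 pi sigma_t)), i.e. a
constant-Q bank of ~7-cycle wavelets.  Spectral amplitude is the modulus of
the complex convolution coefficient; instantaneous phase at a theta
frequency is its argument.  Amplitude is baseline-normalized by subtracting
the per-trial, per-sensor, per-frequency mean over a pre-stimulus window,
and the amplitude time axis is brought to a uniform 250 Hz (4 ms) grid.

Two evaluation paths produce identical coefficients up to round-off: a full
FFT convolution over the epoch, and a windowed direct evaluation at a
selected set of output times (used when only classifier training/test
points are needed).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import signal as sp_signal

from .containers import EpochSet, PhaseSeries, TFRepresentation


def default_frequency_grid() -> np.ndarray:
    """Analysis grid: 1 Hz steps over 2-20 Hz, 2 Hz steps over 21-79 Hz."""
    return np.r_[np.arange(2.0, 21.0, 1.0), np.arange(21.0, 80.0, 2.0)]


def feature_band_mask(freqs: np.ndarray, band: tuple[float, float] = (13.0, 79.0)) -> np.ndarray:
    """Boolean mask of grid frequencies inside the classifier feature band."""
    freqs = np.asarray(freqs, dtype=float)
    return (freqs >= band[0]) & (freqs <= band[1])


@dataclass
class WaveletSpec:
    """Constant-ratio Morlet bank; ``ratio`` is f0 / sigma_f (cycles)."""

    ratio: float = 7.0
    freqs: np.ndarray = field(default_factory=default_frequency_grid)
    trunc_sd: float = 5.0  # kernel support, in units of sigma_t
    normalization: str = "energy"  # "energy" or "peak"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")

    def sigma_f(self, f: float) -> float:
        return f / self.ratio

    def sigma_t(self, f: float) -> float:
        return 1.0 / (2.0 * np.pi * self.sigma_f(f))

    def kernel(self, f: float, sfreq: float) -> np.ndarray:
        """Complex Morlet kernel sampled at ``sfreq``, truncated at
        ``trunc_sd`` standard deviations of the Gaussian envelope."""
        st = self.sigma_t(f)
        half = int(np.ceil(self.trunc_sd * st * sfreq))
        t = np.arange(-half, half + 1) / sfreq
        w = np.exp(-(t ** 2) / (2 * st ** 2)) * np.exp(2j * np.pi * f * t)
        w *= (2 * np.pi * st ** 2) ** -0.5
        if self.normalization == "energy":
            w /= np.sqrt(np.sum(np.abs(w) ** 2) / sfreq)
        elif self.normalization == "peak":
            # unit gain for a unit-amplitude sinusoid at the centre frequency
            w /= 0.5 * np.abs(np.sum(np.conj(w) * np.exp(2j * np.pi * f * t))) / sfreq
        else:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        return w / sfreq  # absorb dt so convolution approximates the integral


def _cwt_coeffs(
    signal: np.ndarray,
    sfreq: float,
    spec: WaveletSpec,
    freqs: np.ndarray,
    out_idx: np.ndarray,
) -> np.ndarray:
    """Complex CWT coefficients at sample indices ``out_idx``.

    ``signal`` is (rows, n_times); returns (rows, n_freqs, len(out_idx)).
    Chooses between full FFT convolution and windowed direct evaluation
    based on the number of requested output samples.
    """
    rows, n_times = signal.shape
    out = np.empty((rows, len(freqs), len(out_idx)), dtype=np.complex64)
    use_fft = len(out_idx) > 300
    if use_fft:
        max_half = int(np.ceil(spec.trunc_sd * spec.sigma_t(freqs.min()) * sfreq))
        nfft = sp_fft.next_fast_len(n_times + 2 * max_half + 1)
        sig_f = sp_fft.fft(signal.astype(np.float64), n=nfft, axis=1)
        for fi, f in enumerate(freqs):
            w = spec.kernel(f, sfreq)
            half = (len(w) - 1) // 2
            wf = sp_fft.fft(w, n=nfft)
            conv = sp_fft.ifft(sig_f * wf[None, :], axis=1)
            # 'same' alignment: coefficient at sample k sits at k + half
            out[:, fi, :] = conv[:, out_idx + half]
        return out
    # windowed path: dot products with the kernel centred on each output sample
    for fi, f in enumerate(freqs):
        w = spec.kernel(f, sfreq)[::-1]  # convolution flips the kernel
        half = (len(w) - 1) // 2
        pad = np.zeros((rows, n_times + 2 * half), dtype=signal.dtype)
        pad[:, half : half + n_times] = signal
        wri = np.stack([w.real, w.imag], axis=1).astype(signal.dtype)
        for j, k in enumerate(out_idx):
            seg = pad[:, k : k + len(w)]
            ri = seg @ wri
            out[:, fi, j] = ri[:, 0] + 1j * ri[:, 1]
    return out


def _resolve_out_idx(epochs: EpochSet, times: np.ndarray | None) -> np.ndarray:
    if times is None:
        return np.arange(len(epochs.times))
    times = np.asarray(times, dtype=float)
    idx = np.round((times - epochs.times[0]) * epochs.sfreq / 1000.0).astype(int)
    if np.any(idx < 0) or np.any(idx >= len(epochs.times)):
        raise ValueError("requested output times fall outside the epoch")
    return idx


def cwt_amplitude(
    epochs: EpochSet,
    spec: WaveletSpec | None = None,
    freqs: np.ndarray | None = None,
    times: np.ndarray | None = None,
) -> TFRepresentation:
    """Pre-normalization spectral amplitude (modulus of the CWT coefficient).

    ``freqs`` restricts the bank to a subset of ``spec.freqs``; ``times``
    (ms) restricts the output time axis, otherwise the full epoch axis at
    the recording rate is returned.  Amplitude is linear in the input.
    """
    spec = spec or WaveletSpec()
    freqs = spec.freqs if freqs is None else np.asarray(freqs, dtype=float)
    support = 2 * spec.trunc_sd * spec.sigma_t(freqs.min()) * 1000.0
    duration = epochs.times[-1] - epochs.times[0]
    if duration < support:
        raise ValueError(
            f"epoch ({duration:.0f} ms) shorter than wavelet support "
            f"({support:.0f} ms) at {freqs.min():g} Hz"
        )
    out_idx = _resolve_out_idx(epochs, times)
    n_trials, n_sensors, n_times = epochs.signal.shape
    flat = epochs.signal.reshape(n_trials * n_sensors, n_times).astype(np.float32)
    amp = np.empty((flat.shape[0], len(freqs), len(out_idx)), dtype=np.float32)
    # chunk rows to bound FFT memory
    chunk = max(1, int(2e8 // (16 * n_times)))
    for a in range(0, flat.shape[0], chunk):
        coeffs = _cwt_coeffs(flat[a : a + chunk], epochs.sfreq, spec, freqs, out_idx)
        amp[a : a + chunk] = np.abs(coeffs)
    amp = amp.reshape(n_trials, n_sensors, len(freqs), len(out_idx))
    return TFRepresentation(amp, freqs, epochs.times[out_idx])


def baseline_normalize(
    tf: TFRepresentation, window: tuple[float, float] = (-500.0, -100.0)
) -> TFRepresentation:
    """Subtract the per-trial/sensor/frequency mean amplitude over ``window``.

    The window defaults to 500 to 100 ms before sample onset.  Idempotent:
    a normalized representation has zero baseline mean.
    """
    lo, hi = window
    mask = (tf.times >= lo) & (tf.times <= hi)
    if not mask.any():
        raise ValueError("baseline window outside the represented time axis")
    base = tf.amplitude[..., mask].mean(axis=-1, keepdims=True)
    return TFRepresentation(tf.amplitude - base, tf.freqs, tf.times, baseline=window)


def downsample_tf(tf: TFRepresentation, target: float = 250.0) -> TFRepresentation:
    """Band-limited resampling of the amplitude onto a uniform grid at
    ``target`` Hz (polyphase filtering; 480 -> 250 is the rational factor
    25/48).  The output axis starts at the first represented time and
    steps by ``1000 / target`` ms (4 ms at the 250 Hz output rate).
    Values of series band-limited below the new Nyquist are preserved
    within the resampling filter tolerance.
    """
    from fractions import Fraction

    src_dt = np.diff(tf.times)
    if len(src_dt) == 0 or np.ptp(src_dt) > 1e-6:
        raise ValueError("downsampling requires a uniform source time axis")
    src_rate = 1000.0 / src_dt[0]
    if target > src_rate:
        raise ValueError("target rate exceeds source rate")
    frac = Fraction(target / src_rate).limit_denominator(1000)
    out = sp_signal.resample_poly(
        tf.amplitude.astype(np.float64), frac.numerator, frac.denominator,
        axis=-1, padtype="edge",
    ).astype(tf.amplitude.dtype)
    step = 1000.0 / target
    new_times = tf.times[0] + step * np.arange(out.shape[-1])
    keep = new_times <= tf.times[-1] + 1e-9
    return TFRepresentation(out[..., keep], tf.freqs, new_times[keep], baseline=tf.baseline)


def zero_phase_highpass(epochs: EpochSet, cutoff: float = 3.0, order: int = 4) -> EpochSet:
    """Forward-backward (zero net phase shift) Butterworth high-pass."""
    if cutoff >= epochs.sfreq / 2:
        raise ValueError("cutoff at or above Nyquist")
    sos = sp_signal.butter(order, cutoff, btype="highpass", fs=epochs.sfreq, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, epochs.signal, axis=-1)
    return EpochSet(
        filtered.astype(epochs.signal.dtype),
        epochs.times,
        epochs.sfreq,
        epochs.metadata,
        epochs.layout,
    )


def instantaneous_phase(
    epochs: EpochSet,
    theta_freq: float = 6.0,
    spec: WaveletSpec | None = None,
    times: np.ndarray | None = None,
    out_rate: float = 250.0,
) -> PhaseSeries:
    """Instantaneous phase of the Morlet coefficient at ``theta_freq``.

    Phase is scale-invariant, so the wavelet normalization is irrelevant
    here.  ``times`` defaults to the full epoch on the ``out_rate`` grid.
    Epochs are expected to be high-pass filtered beforehand (3 Hz default
    in the pipeline).
    """
    spec = spec or WaveletSpec()
    if not np.any(np.isclose(spec.freqs, theta_freq)):
        raise ValueError(f"{theta_freq} Hz is not on the analysis grid")
    if times is None:
        step = 1000.0 / out_rate
        n_out = int(np.floor((epochs.times[-1] - epochs.times[0]) / step)) + 1
        times = epochs.times[0] + step * np.arange(n_out)
    out_idx = _resolve_out_idx(epochs, times)
    n_trials, n_sensors, n_times = epochs.signal.shape
    flat = epochs.signal.reshape(n_trials * n_sensors, n_times).astype(np.float32)
    ph = np.empty((flat.shape[0], len(out_idx)), dtype=np.float32)
    chunk = max(1, int(2e8 // (16 * n_times)))
    freqs = np.array([theta_freq])
    for a in range(0, flat.shape[0], chunk):
        coeffs = _cwt_coeffs(flat[a : a + chunk], epochs.sfreq, spec, freqs, out_idx)
        ph[a : a + chunk] = np.angle(coeffs[:, 0, :])
    # wrap convention (-pi, pi]
    ph[ph <= -np.pi] += 2 * np.pi
    return PhaseSeries(
        ph.reshape(n_trials, n_sensors, len(out_idx)),
        theta_freq,
        epochs.times[out_idx],
        sfreq=out_rate,
    )
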