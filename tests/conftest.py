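import numpy as np
import pandas as pd
import pytest

from thetareplay.containers import EpochSet, TFRepresentation, grid_layout


@pytest.fixture(scope="session")
def make_epochs():
    """Factory: wrap waveforms into a minimal EpochSet.

    ``waves`` is (trials, sensors, time) or a 1-D waveform; the epoch uses
    the standard -1000..8000 ms window at 480 Hz unless overridden.
    """

    def _make(waves, sfreq=480.0, t0=-1000.0):
        waves = np.asarray(waves, dtype=float)
        if waves.ndim == 1:
            waves = waves[None, None, :]
        n_trials, n_sensors, n_times = waves.shape
        times = t0 + 1000.0 * np.arange(n_times) / sfreq
        cats = ["indoor" if i % 2 == 0 else "outdoor" for i in range(n_trials)]
        md = pd.DataFrame(
            {
                "category": cats,
                "condition": ["control"] * n_trials,
                "pair_index": [i // 2 for i in range(n_trials)],
                "subject": [0] * n_trials,
            }
        )
        return EpochSet(waves, times, sfreq, md, grid_layout(n_sensors))

    return _make


@pytest.fixture(scope="session")
def std_times():
    """Standard 9 s epoch time axis at 480 Hz (ms)."""
    return -1000.0 + 1000.0 * np.arange(4320) / 480.0


@pytest.fixture(scope="session")
def make_feature_tfr():
    """Factory: a TFRepresentation holding a given feature matrix at one
    time point (plus a zero baseline time point), for decoder tests that
    do not need a wavelet transform."""

    def _make(x, n_sensors, freqs, time_point=364.0):
        x = np.asarray(x, dtype=float)
        n_trials, n_feat = x.shape
        n_freqs = len(freqs)
        assert n_feat == n_sensors * n_freqs
        amp = np.zeros((n_trials, n_sensors, n_freqs, 2), dtype=np.float64)
        amp[..., 1] = x.reshape(n_trials, n_sensors, n_freqs)
        times = np.array([-36.0, time_point])
        return TFRepresentation(amp, np.asarray(freqs, float), times)

    return _make


@pytest.fixture(scope="session")
def labels_20_20():
    """40-trial metadata: 20 indoor / 20 outdoor, paired by index."""
    rows = []
    for pair in range(20):
        for cat in ("indoor", "outdoor"):
            rows.append(
                {"category": cat, "condition": "configural", "pair_index": pair, "subject": 0}
            )
    return pd.DataFrame(rows)
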