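"""Synthetic multichannel cohorts with planted category patterns and replay.

The generator emulates the structure of a delayed match-to-sample MEG
study: 9 s epochs (1 s pre-stimulus margin, 3 s sample presentation, 5 s
maintenance), two scene categories (indoor/outdoor), three task conditions
(control / nonconfigural / configural), 20 trials per category per
condition, and 8 subjects.  Every epoch is built from

* 1/f background noise (spectrally shaped white noise, unit variance),
* an ongoing theta oscillation, coherent within spatial sensor clusters,
* a (category, condition)-specific oscillatory pattern with carriers in
  the classifier feature band, active during the sample window, and
* maintenance "replay" bursts that re-inject the same pattern.

Replay events are drawn once per theta cycle (Bernoulli with probability
``replay_rate / theta_freq``, so the mean rate is ``replay_rate`` events/s)
and placed at the time where the trial's planted theta attains a phase
drawn from a von Mises law with concentration ``coupling_kappa`` and
preferred phase ``coupling_mu``.  The planted phase of each event is
recorded in the ground truth, making the generator's coupling parameters
exactly the quantities the phase-locking stage estimates.

Sensors outside the condition's coupled cluster receive per-trial random
theta detuning and phase offsets, so their theta decoheres from the event
train within a trial: phase-locking topography is therefore recoverable at
the cluster level.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    CATEGORIES,
    CONDITIONS,
    MAINTENANCE_WINDOW,
    EpochSet,
    SensorLayout,
    ctf275_like_layout,
    grid_layout,
)


class ParameterError(ValueError):
    """Nonphysical or inconsistent generator parameters."""


def _per_condition(value, name: str, *, force_control_zero: bool = False) -> dict:
    if isinstance(value, dict):
        out = {c: float(value.get(c, 0.0)) for c in CONDITIONS}
    else:
        out = {c: float(value) for c in CONDITIONS}
    if force_control_zero:
        out["control"] = 0.0
    for c, v in out.items():
        if v < 0:
            raise ParameterError(f"{name}[{c}] must be >= 0, got {v}")
    return out


@dataclass
class GeneratorParams:
    """All knobs of the synthetic cohort generator.

    ``replay_rate`` / ``coupling_kappa`` / ``coupling_mu`` accept either a
    scalar (applied to both DMS conditions) or a per-condition mapping.
    Control trials never contain replay events regardless of the rate.
    """

    n_subjects: int = 8
    n_trials_per_category: int = 20
    n_sensors: int = 64
    sampling_rate: float = 480.0
    epoch_window: tuple[float, float] = (-1000.0, 8000.0)
    theta_freq: float = 6.0
    replay_rate: dict | float = field(
        default_factory=lambda: {"control": 0.0, "nonconfigural": 4.2, "configural": 5.7}
    )
    coupling_kappa: dict | float = 8.0
    coupling_mu: dict | float = 0.0
    burst_duration: float = 150.0
    pattern_snr: float = 0.8
    burst_gain: float = 3.0
    noise_exponent: float = 1.0
    band_activity: float = 1.0
    band_gain_sd: float = 0.25
    theta_amplitude: float = 2.0
    theta_phase_jitter: float = 0.2
    theta_detune: float = 0.5
    n_theta_clusters: int = 4
    coupling_clusters: dict = field(
        default_factory=lambda: {"control": 0, "nonconfigural": 0, "configural": 1}
    )
    layout_kind: str = "grid"
    carrier_band: tuple[float, float] = (33.0, 79.0)
    n_carriers: int = 4
    kappa_subject_range: tuple[float, float] = (1.0, 1.0)
    behavior_base: dict = field(
        default_factory=lambda: {"control": 0.83, "nonconfigural": 0.97, "configural": 0.79}
    )
    behavior_slope: float = 0.0
    behavior_noise_sd: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.replay_rate = _per_condition(self.replay_rate, "replay_rate", force_control_zero=True)
        self.coupling_kappa = _per_condition(self.coupling_kappa, "coupling_kappa")
        if not isinstance(self.coupling_mu, dict):
            self.coupling_mu = {c: float(self.coupling_mu) for c in CONDITIONS}
        if self.n_trials_per_category < 2:
            raise ParameterError("n_trials_per_category must be >= 2")
        if self.n_subjects < 1:
            raise ParameterError("n_subjects must be >= 1")
        if self.theta_freq <= 0 or self.sampling_rate <= 0:
            raise ParameterError("frequencies must be positive")
        for c, lam in self.replay_rate.items():
            if lam > self.theta_freq:
                raise ParameterError(
                    f"replay_rate[{c}]={lam} exceeds theta_freq={self.theta_freq}; "
                    "the cycle-landmark construction caps the rate at one event "
                    "per theta cycle"
                )
        lo, hi = self.epoch_window
        if lo > -1000.0 or hi < 8000.0:
            raise ParameterError(
                "epoch_window must span the -1000..8000 ms baseline/sample/"
                "maintenance structure"
            )
        if self.burst_duration <= 0:
            raise ParameterError("burst_duration must be positive")


@dataclass
class CategoryPattern:
    """Spectral-spatial signature of one (category, condition) pair."""

    category: str
    condition: str
    sensor_weights: np.ndarray  # per-sensor gain, canonical sensor order
    carrier_frequencies: np.ndarray  # Hz, within the classifier feature band
    carrier_amplitudes: np.ndarray


@dataclass
class GroundTruth:
    """Planted truth for one subject: replay events and theta structure.

    ``event_times``/``event_phases`` hold, per trial, the replay onset
    times (ms) and the planted theta phase of each event.  The theta
    bookkeeping (cluster assignment, per-trial detune and offsets) allows
    the planted phase at any sensor to be reconstructed analytically via
    :meth:`event_phases_at_sensor` without re-estimating it from signal.
    """

    subject: int
    event_times: list[np.ndarray]
    event_phases: list[np.ndarray]
    metadata: pd.DataFrame
    theta_freq: float
    cluster_of_sensor: np.ndarray
    coupling_clusters: dict
    theta_offset: np.ndarray  # trials x clusters, rad
    theta_detune: np.ndarray  # trials x clusters, Hz
    kappa_used: dict
    behavioral_accuracy: dict

    def event_phase_matrix(self, trial: int, n_sensors: int | None = None) -> np.ndarray:
        """Planted theta phase at every sensor for this trial's events,
        shape (n_sensors, n_events); vectorized counterpart of
        :meth:`event_phases_at_sensor`."""
        if n_sensors is None:
            n_sensors = len(self.cluster_of_sensor)
        cond = self.metadata.iloc[trial]["condition"]
        c_of_s = self.cluster_of_sensor[:n_sensors]
        t = self.event_times[trial] / 1000.0
        ph = (
            2 * np.pi * (self.theta_freq + self.theta_detune[trial, c_of_s])[:, None] * t[None, :]
            + self.theta_offset[trial, c_of_s][:, None]
        )
        coupled = c_of_s == self.coupling_clusters[cond]
        ph[coupled] = self.event_phases[trial][None, :]
        return np.angle(np.exp(1j * ph))

    def event_phases_at_sensor(self, trial: int, sensor: int) -> np.ndarray:
        """Planted theta phase at ``sensor`` at this trial's event times."""
        cond = self.metadata.iloc[trial]["condition"]
        c = int(self.cluster_of_sensor[sensor])
        t = self.event_times[trial] / 1000.0
        if c == self.coupling_clusters[cond]:
            ph = self.event_phases[trial].copy()
        else:
            ph = (
                2 * np.pi * (self.theta_freq + self.theta_detune[trial, c]) * t
                + self.theta_offset[trial, c]
            )
        return np.angle(np.exp(1j * ph))


def make_patterns(params: GeneratorParams, rng: np.random.Generator) -> dict:
    """Distinct patterns per (category, condition): disjoint carrier sets
    on the 2 Hz analysis grid within ``carrier_band`` and random
    sensor-weight maps over roughly 40% of the sensors.

    Carriers are assigned by stratified draw — the band is split into
    ``n_carriers`` frequency strata and every pattern receives exactly one
    carrier per stratum — so the six patterns are equated in detectability
    (wavelet bandwidth, and hence in-bin noise, grows with frequency).
    This mirrors the counterbalancing of stimulus material across task
    conditions in the study design the generator emulates.
    """
    lo, hi = params.carrier_band
    band = np.arange(lo, hi + 1e-9, 2.0)
    n_patterns = len(CATEGORIES) * len(CONDITIONS)
    need = params.n_carriers * n_patterns
    if need > len(band):
        raise ParameterError(
            f"{need} carriers requested but only {len(band)} grid frequencies "
            f"in {params.carrier_band}"
        )
    strata = np.array_split(band, params.n_carriers)
    assignment = np.empty((n_patterns, params.n_carriers))
    for k, stratum in enumerate(strata):
        picks = rng.permutation(len(stratum))[:n_patterns]
        if len(picks) < n_patterns:
            raise ParameterError("carrier band too narrow for stratified assignment")
        assignment[:, k] = stratum[picks]
    patterns = {}
    for i, (cond, cat) in enumerate(
        [(cond, cat) for cond in CONDITIONS for cat in CATEGORIES]
    ):
        carriers = np.sort(assignment[i])
        n_active = max(2, int(round(0.4 * params.n_sensors)))
        active = rng.choice(params.n_sensors, size=n_active, replace=False)
        weights = np.zeros(params.n_sensors)
        weights[active] = rng.uniform(0.7, 1.0, size=n_active)
        amps = np.ones(params.n_carriers)
        patterns[(cat, cond)] = CategoryPattern(cat, cond, weights, carriers, amps)
    return patterns


def draw_replay_events(
    rng: np.random.Generator,
    params: GeneratorParams,
    condition: str,
    theta_offset: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Replay events for a single maintenance period.

    Returns ``(times_ms, phases)``.  One Bernoulli draw per theta cycle
    with success probability ``replay_rate / theta_freq``; each event's
    phase is drawn from von Mises(mu, kappa) and converted to the time at
    which the trial's planted theta (phase ``2 pi f t + theta_offset``)
    attains it within that cycle.
    """
    lam = params.replay_rate[condition]
    if lam == 0.0:
        return np.empty(0), np.empty(0)
    f = params.theta_freq
    t_lo, t_hi = np.asarray(MAINTENANCE_WINDOW) / 1000.0
    period = 1.0 / f
    # first cycle whose zero-phase landmark (offset included) is >= t_lo
    n0 = int(np.ceil((t_lo * f) + theta_offset / (2 * np.pi)))
    starts = (n0 + np.arange(int(np.floor((t_hi - t_lo) * f)) + 1) - theta_offset / (2 * np.pi)) * period
    starts = starts[(starts >= t_lo) & (starts + period <= t_hi)]
    hit = rng.random(len(starts)) < lam / f
    kappa = params.coupling_kappa[condition]
    mu = params.coupling_mu[condition]
    phases = rng.vonmises(mu, kappa, size=int(hit.sum()))
    # cycle landmarks already include theta_offset (phase 0 at each start),
    # so the within-cycle position is just the sampled phase itself
    frac = np.mod(phases, 2 * np.pi) / (2 * np.pi)
    times = (starts[hit] + frac * period) * 1000.0
    keep = (times >= MAINTENANCE_WINDOW[0]) & (times < MAINTENANCE_WINDOW[1])
    return times[keep], phases[keep]


def _shaped_noise(rng: np.random.Generator, n_trials: int, n_times: int, sfreq: float, exponent: float) -> np.ndarray:
    """1/f noise: white noise spectrally shaped to power ~ f^-exponent,
    normalized to unit variance per series."""
    white = rng.standard_normal((n_trials, n_times))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_times, d=1.0 / sfreq)
    shape = np.maximum(f, 1.0) ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    out = np.fft.irfft(spec * shape, n=n_times, axis=-1)
    out /= out.std(axis=-1, keepdims=True)
    return out


def _band_noise(
    rng: np.random.Generator,
    n_trials: int,
    n_times: int,
    sfreq: float,
    band: tuple[float, float] = (13.0, 79.0),
    gain_sd: float = 0.25,
) -> np.ndarray:
    """Ongoing band-limited oscillatory activity, unit variance, with a
    per-trial lognormal amplitude gain (trial-to-trial excitability).

    This is what makes maintenance-period spectral features fluctuate
    across trials in the classifier band: without it, pattern-free delay
    activity would present the network with a nearly constant input whose
    arbitrary extrapolated output can exceed the correctness threshold
    for every trial at once."""
    white = rng.standard_normal((n_trials, n_times))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_times, d=1.0 / sfreq)
    spec[:, (f < band[0]) | (f > band[1])] = 0.0
    out = np.fft.irfft(spec, n=n_times, axis=-1)
    out /= out.std(axis=-1, keepdims=True)
    # within-trial waxing/waning of band power (~300 ms timescale): keeps
    # moment-to-moment spectral features fluctuating so no trial stays on
    # one side of the classifier threshold for the whole delay
    width = max(1, int(0.3 * sfreq))
    kernel = np.ones(width) / width
    slow = np.apply_along_axis(
        lambda r: np.convolve(r, kernel, mode="same"), -1, rng.standard_normal((n_trials, n_times))
    )
    slow /= slow.std(axis=-1, keepdims=True)
    out = out * (1.0 + 0.6 * np.abs(slow))
    out /= out.std(axis=-1, keepdims=True)
    gains = np.exp(gain_sd * rng.standard_normal(n_trials))
    return out * gains[:, None]


def _spatial_clusters(layout: SensorLayout, n_clusters: int) -> np.ndarray:
    """Position-based cluster labels (quadrant-style median splits)."""
    x, y = layout.pos[:, 0], layout.pos[:, 1]
    labels = (x > np.median(x)).astype(int) + 2 * (y > np.median(y)).astype(int)
    return labels % n_clusters


def _build_layout(params: GeneratorParams) -> SensorLayout:
    if params.layout_kind == "ctf275":
        return ctf275_like_layout()
    return grid_layout(params.n_sensors)


def generate_subject(
    params: GeneratorParams,
    subject_index: int,
    layout: SensorLayout | None = None,
    kappa_factor: float = 1.0,
    behavior_rng: np.random.Generator | None = None,
) -> tuple[EpochSet, GroundTruth]:
    """One subject's full recording (all conditions and categories).

    Deterministic given ``params.rng_seed`` and ``subject_index``.  The
    per-sensor noise streams are keyed by the canonical (sorted-id) sensor
    order, so permuting the layout permutes the output identically.
    """
    if layout is None:
        layout = _build_layout(params)
    if layout.n_sensors != params.n_sensors:
        raise ParameterError("layout size does not match n_sensors")
    ss = np.random.SeedSequence([int(params.rng_seed) % (2**31), int(subject_index)])
    pattern_seed, trial_seed, sensor_root, behavior_seed = ss.spawn(4)
    rng = np.random.default_rng(trial_seed)
    params_eff = params
    if kappa_factor != 1.0:
        params_eff = replace(
            params,
            coupling_kappa={c: v * kappa_factor for c, v in params.coupling_kappa.items()},
        )

    sfreq = params.sampling_rate
    t_ms = params.epoch_window[0] + 1000.0 * np.arange(
        int(round((params.epoch_window[1] - params.epoch_window[0]) * sfreq / 1000.0))
    ) / sfreq
    t_s = t_ms / 1000.0
    n_times = len(t_ms)
    n_per = params.n_trials_per_category
    n_trials = n_per * len(CATEGORIES) * len(CONDITIONS)

    canonical = np.argsort(layout.ids)  # canonical sensor order for RNG keying
    patterns = make_patterns(params, np.random.default_rng(pattern_seed))

    rows = []
    for cond in CONDITIONS:
        for pair in range(n_per):
            for cat in CATEGORIES:
                rows.append({"category": cat, "condition": cond, "pair_index": pair, "subject": subject_index})
    metadata = pd.DataFrame(rows)

    clusters = _spatial_clusters(layout, params.n_theta_clusters)
    n_clusters = params.n_theta_clusters
    theta_offset = np.zeros((n_trials, n_clusters))
    theta_detune = np.zeros((n_trials, n_clusters))

    signal = np.zeros((n_trials, params.n_sensors, n_times), dtype=np.float32)

    # per-sensor 1/f noise, keyed by canonical sensor identity
    sensor_seeds = sensor_root.spawn(params.n_sensors)
    for k, seed in enumerate(sensor_seeds):
        s = canonical[k]
        s_rng = np.random.default_rng(seed)
        noise = _shaped_noise(s_rng, n_trials, n_times, sfreq, params.noise_exponent)
        if params.band_activity > 0:
            noise = noise + params.band_activity * _band_noise(
                s_rng, n_trials, n_times, sfreq,
                band=(13.0, 79.0), gain_sd=params.band_gain_sd,
            )
        signal[:, s, :] = noise

    def to_rows(v: np.ndarray) -> np.ndarray:
        # canonical (sorted-id) sensor space -> layout row order
        out = np.empty_like(v)
        out[canonical] = v
        return out

    theta_gain = to_rows(1.0 + 0.2 * (rng.random(params.n_sensors) - 0.5))
    pattern_weights = {key: to_rows(pat.sensor_weights) for key, pat in patterns.items()}
    event_times: list[np.ndarray] = []
    event_phases: list[np.ndarray] = []
    f_th = params.theta_freq
    half_burst = params.burst_duration / 2000.0  # s

    for j in range(n_trials):
        cond = metadata.iloc[j]["condition"]
        cat = metadata.iloc[j]["category"]
        couple_c = params.coupling_clusters.get(cond, 0)
        delta_couple = params.theta_phase_jitter * rng.standard_normal()
        for c in range(n_clusters):
            if c == couple_c:
                theta_offset[j, c] = delta_couple
                theta_detune[j, c] = 0.0
            else:
                theta_offset[j, c] = rng.uniform(-np.pi, np.pi)
                theta_detune[j, c] = rng.uniform(-params.theta_detune, params.theta_detune)
            in_c = clusters == c
            wave = np.cos(2 * np.pi * (f_th + theta_detune[j, c]) * t_s + theta_offset[j, c])
            signal[j, in_c, :] += (
                params.theta_amplitude * theta_gain[in_c, None] * wave[None, :]
            ).astype(np.float32)

        pat = patterns[(cat, cond)]
        # sample-period pattern with 100 ms raised-cosine ramps
        env = np.zeros(n_times)
        in_sample = (t_ms >= 0) & (t_ms < 3000)
        env[in_sample] = 1.0
        ramp = (t_ms >= 0) & (t_ms < 100)
        env[ramp] = 0.5 * (1 - np.cos(np.pi * t_ms[ramp] / 100.0))
        ramp = (t_ms >= 2900) & (t_ms < 3000)
        env[ramp] = 0.5 * (1 - np.cos(np.pi * (3000.0 - t_ms[ramp]) / 100.0))
        wavesum = np.zeros(n_times)
        for fc, ac in zip(pat.carrier_frequencies, pat.carrier_amplitudes):
            wavesum += ac * np.sin(2 * np.pi * fc * t_s + rng.uniform(0, 2 * np.pi))
        w_rows = pattern_weights[(cat, cond)]
        signal[j] += (
            params.pattern_snr * w_rows[:, None] * (env * wavesum)[None, :]
        ).astype(np.float32)

        # maintenance replay bursts
        times, phases = draw_replay_events(rng, params_eff, cond, theta_offset=delta_couple)
        event_times.append(times)
        event_phases.append(phases)
        if len(times):
            burst_total = np.zeros(n_times)
            for te in times / 1000.0:
                lo, hi = te - half_burst, te + half_burst
                m = (t_s >= lo) & (t_s <= hi)
                if not m.any():
                    continue
                benv = 0.5 * (1 + np.cos(np.pi * (t_s[m] - te) / half_burst))
                bw = np.zeros(m.sum())
                for fc, ac in zip(pat.carrier_frequencies, pat.carrier_amplitudes):
                    bw += ac * np.sin(2 * np.pi * fc * (t_s[m] - te) + rng.uniform(0, 2 * np.pi))
                burst_total[m] += benv * bw
            signal[j] += (
                params.pattern_snr * params.burst_gain
                * w_rows[:, None] * burst_total[None, :]
            ).astype(np.float32)

    if behavior_rng is None:
        behavior_rng = np.random.default_rng(behavior_seed)
    kappa_used = {c: v * kappa_factor for c, v in params.coupling_kappa.items()}
    behavior = {}
    for cond in CONDITIONS:
        acc = (
            params.behavior_base[cond]
            + params.behavior_slope * (kappa_used[cond] - params.coupling_kappa[cond])
            + params.behavior_noise_sd * behavior_rng.standard_normal()
        )
        behavior[cond] = float(np.clip(acc, 0.0, 1.0))

    epochs = EpochSet(signal, t_ms, sfreq, metadata, layout)
    gt = GroundTruth(
        subject=subject_index,
        event_times=event_times,
        event_phases=event_phases,
        metadata=metadata,
        theta_freq=f_th,
        cluster_of_sensor=clusters,
        coupling_clusters=dict(params.coupling_clusters),
        theta_offset=theta_offset,
        theta_detune=theta_detune,
        kappa_used=kappa_used,
        behavioral_accuracy=behavior,
    )
    return epochs, gt


def generate_ground_truth(
    params: GeneratorParams,
    subject_index: int,
    kappa_factor: float = 1.0,
) -> GroundTruth:
    """Events-only generation: the full ground-truth bookkeeping (trial
    structure, theta clusters/offsets/detunes, replay events, behavior)
    without synthesizing any signal.

    Used by statistical-calibration studies that operate on planted
    phases; draws are deterministic given the seed but use a separate
    stream from :func:`generate_subject`.
    """
    layout = _build_layout(params)
    ss = np.random.SeedSequence(
        [int(params.rng_seed) % (2**31), int(subject_index), 99]
    )
    rng = np.random.default_rng(ss)
    params_eff = params
    if kappa_factor != 1.0:
        params_eff = replace(
            params,
            coupling_kappa={c: v * kappa_factor for c, v in params.coupling_kappa.items()},
        )
    n_per = params.n_trials_per_category
    rows = []
    for cond in CONDITIONS:
        for pair in range(n_per):
            for cat in CATEGORIES:
                rows.append(
                    {"category": cat, "condition": cond, "pair_index": pair, "subject": subject_index}
                )
    metadata = pd.DataFrame(rows)
    n_trials = len(metadata)
    clusters = _spatial_clusters(layout, params.n_theta_clusters)
    n_clusters = params.n_theta_clusters
    theta_offset = np.zeros((n_trials, n_clusters))
    theta_detune = np.zeros((n_trials, n_clusters))
    event_times, event_phases = [], []
    for j in range(n_trials):
        cond = metadata.iloc[j]["condition"]
        couple_c = params.coupling_clusters.get(cond, 0)
        delta_couple = params.theta_phase_jitter * rng.standard_normal()
        for c in range(n_clusters):
            if c == couple_c:
                theta_offset[j, c] = delta_couple
            else:
                theta_offset[j, c] = rng.uniform(-np.pi, np.pi)
                theta_detune[j, c] = rng.uniform(-params.theta_detune, params.theta_detune)
        t, ph = draw_replay_events(rng, params_eff, cond, theta_offset=delta_couple)
        event_times.append(t)
        event_phases.append(ph)
    kappa_used = {c: v * kappa_factor for c, v in params.coupling_kappa.items()}
    behavior = {
        cond: float(
            np.clip(
                params.behavior_base[cond]
                + params.behavior_slope * (kappa_used[cond] - params.coupling_kappa[cond])
                + params.behavior_noise_sd * rng.standard_normal(),
                0.0,
                1.0,
            )
        )
        for cond in CONDITIONS
    }
    return GroundTruth(
        subject=subject_index,
        event_times=event_times,
        event_phases=event_phases,
        metadata=metadata,
        theta_freq=params.theta_freq,
        cluster_of_sensor=clusters,
        coupling_clusters=dict(params.coupling_clusters),
        theta_offset=theta_offset,
        theta_detune=theta_detune,
        kappa_used=kappa_used,
        behavioral_accuracy=behavior,
    )


def subject_kappa_factors(params: GeneratorParams) -> np.ndarray:
    """Per-subject multiplicative spread of the coupling concentration."""
    lo, hi = params.kappa_subject_range
    rng = np.random.default_rng(np.random.SeedSequence([int(params.rng_seed) % (2**31), 777]))
    return rng.uniform(lo, hi, size=params.n_subjects)


def generate_cohort(params: GeneratorParams) -> list[tuple[EpochSet, GroundTruth]]:
    """Full cohort; per-subject seeds derive deterministically from
    ``rng_seed`` and subject κ spread from ``kappa_subject_range``."""
    factors = subject_kappa_factors(params)
    return [
        generate_subject(params, i, kappa_factor=float(factors[i]))
        for i in range(params.n_subjects)
    ]


def cohort_behavior(cohort: list[tuple[EpochSet, GroundTruth]], condition: str = "configural") -> np.ndarray:
    """Subject-level behavioral accuracies for the correlation analysis."""
    return np.array([gt.behavioral_accuracy[condition] for _, gt in cohort])
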