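"""Phase locking of reactivation events to theta, and its statistics.

For trial j with N_j reactivation events at theta phases phi_nj, the
phase-locking value is the modulus of the mean unit phasor

    PLV_j = | sum_n exp(i phi_nj) | / N_j,

1 for perfect alignment and ~sqrt(pi)/(2 sqrt(N)) in expectation for
uniform phases.  PLVs are variance-stabilized with the arcsine transform
z = arcsin(2 PLV - 1) before parametric contrasts.  Trials with fewer than
``min_events`` events (default 2; a single event gives PLV = 1 trivially)
are excluded.

Condition contrasts are paired t-tests over subjects on trial-mean z per
sensor; multiplicity over sensors is controlled with a cluster-based
permutation test (clusters of >= 8 adjacent significant sensors, null from
within-subject condition-label sign flips).  A within-subject permutation
based on circular shifts of each trial's event vector — which preserves
the events' temporal correlation structure — gives per-sensor significance
of the phase locking itself, and a Pearson map links coupling to
behavioral accuracy across subjects.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .containers import PhaseSeries, SensorLayout
from .synth import GroundTruth

MIN_CLUSTER_SIZE = 8


def plv(phases: np.ndarray, min_events: int = 2) -> float:
    """Modulus of the mean unit phasor of ``phases`` (radians)."""
    phases = np.asarray(phases, dtype=float)
    if len(phases) < min_events:
        raise ValueError(
            f"{len(phases)} events < min_events={min_events}: trial excluded"
        )
    return float(np.abs(np.exp(1j * phases).mean()))


def arcsine_z(p: float | np.ndarray) -> float | np.ndarray:
    """Variance-stabilizing transform z = arcsin(2 PLV - 1), in
    [-pi/2, pi/2] and strictly increasing on [0, 1]."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("PLV outside [0, 1]")
    out = np.arcsin(2 * p - 1)
    return float(out) if out.ndim == 0 else out


def circular_mean(phases: np.ndarray) -> float:
    """Direction of the mean phasor (preferred phase estimate)."""
    return float(np.angle(np.exp(1j * np.asarray(phases, dtype=float)).mean()))


def build_plv_table(
    events: pd.DataFrame,
    phase: PhaseSeries,
    metadata: pd.DataFrame,
    subject: int,
    min_events: int = 2,
) -> pd.DataFrame:
    """Per (trial, sensor) PLV table from a merged event list.

    ``events`` needs ``trial`` and ``time`` columns (ms); the phase at
    each event is read from the phase series at the nearest sample.
    Trials with fewer than ``min_events`` events are excluded.
    """
    rows = []
    n_sensors = phase.phase.shape[1]
    for trial, grp in events.groupby("trial", observed=True):
        times = grp["time"].to_numpy(dtype=float)
        if len(times) < min_events:
            continue
        idx = np.array([phase.time_index(t) for t in times])
        ph = phase.phase[int(trial), :, idx]  # (events, sensors)
        vec = np.abs(np.exp(1j * ph).mean(axis=0))
        z = arcsine_z(np.clip(vec, 0.0, 1.0))
        cond = metadata.iloc[int(trial)]["condition"]
        for s in range(n_sensors):
            rows.append((subject, cond, int(trial), s, phase.freq, len(times), float(vec[s]), float(z[s])))
    return pd.DataFrame(
        rows,
        columns=["subject", "condition", "trial", "sensor", "freq", "n_events", "plv", "z"],
    )


def plv_table_from_ground_truth(
    gt: GroundTruth, n_sensors: int, min_events: int = 2
) -> pd.DataFrame:
    """PLV table from the generator's analytically planted phases.

    Bypasses signal synthesis and phase estimation: the planted theta
    phase at each sensor and event is reconstructed from the ground-truth
    bookkeeping.  Used for statistical-calibration studies where the
    estimation noise of the measured-phase path is irrelevant.
    """
    rows = []
    for trial in range(len(gt.event_times)):
        n_ev = len(gt.event_times[trial])
        if n_ev < min_events:
            continue
        cond = gt.metadata.iloc[trial]["condition"]
        ph = gt.event_phase_matrix(trial, n_sensors)  # (sensors, events)
        vec = np.abs(np.exp(1j * ph).mean(axis=1))
        zs = arcsine_z(np.clip(vec, 0.0, 1.0))
        for s in range(n_sensors):
            rows.append(
                (gt.subject, cond, trial, s, gt.theta_freq, n_ev, float(vec[s]), float(zs[s]))
            )
    return pd.DataFrame(
        rows,
        columns=["subject", "condition", "trial", "sensor", "freq", "n_events", "plv", "z"],
    )


def subject_sensor_z(table: pd.DataFrame) -> pd.DataFrame:
    """Trial-mean z per (subject, condition, sensor) — the paired unit of
    the condition contrast."""
    return (
        table.groupby(["subject", "condition", "sensor"], observed=True)["z"]
        .mean()
        .reset_index()
    )


def coupling_contrast(
    table: pd.DataFrame, condition_a: str, condition_b: str
) -> pd.DataFrame:
    """Per-sensor paired t-test over subjects on trial-mean z (A vs B).

    Returns a frame with sensor, t, p (two-sided) and the mean paired
    difference.  Raises on fewer than 2 complete subjects or zero
    variance (e.g. contrasting a condition with itself).
    """
    means = subject_sensor_z(table)
    a = means[means["condition"] == condition_a].pivot(index="subject", columns="sensor", values="z")
    b = means[means["condition"] == condition_b].pivot(index="subject", columns="sensor", values="z")
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise ValueError("need both conditions for at least 2 subjects")
    d = (a.loc[common] - b.loc[common]).to_numpy()
    if np.allclose(d.std(axis=0, ddof=1), 0.0):
        raise ValueError("zero variance of paired differences")
    t, p = stats.ttest_rel(a.loc[common].to_numpy(), b.loc[common].to_numpy(), axis=0)
    return pd.DataFrame(
        {"sensor": a.columns.to_numpy(), "t": t, "p": p, "mean_diff": d.mean(axis=0)}
    )


@dataclass
class ClusterResult:
    sensors: np.ndarray
    stat: float  # summed |t| (cluster mass)
    p_value: float
    direction: int  # +1: A > B, -1: A < B


def _find_clusters(
    t: np.ndarray, p: np.ndarray, adjacency: sparse.spmatrix, alpha: float, min_size: int
) -> list[tuple[np.ndarray, float, int]]:
    out = []
    for direction in (+1, -1):
        sig = np.flatnonzero((p < alpha) & (np.sign(t) == direction))
        if len(sig) == 0:
            continue
        sub = adjacency[np.ix_(sig, sig)]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = sig[labels == c]
            if len(members) >= min_size:
                out.append((members, float(np.abs(t[members]).sum()), direction))
    return out


def cluster_permutation(
    diffs: np.ndarray,
    adjacency: sparse.spmatrix,
    n_perm: int = 1000,
    min_size: int = MIN_CLUSTER_SIZE,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[ClusterResult]:
    """Cluster-based nonparametric permutation test over sensors.

    ``diffs`` is the (subjects x sensors) matrix of paired z differences.
    Sensors with two-sided p < ``alpha`` are grouped into clusters of
    mutually adjacent sensors; candidates need at least ``min_size``
    members.  The null flips each subject's condition labels (sign of its
    difference map) and records the maximal cluster mass; each observed
    cluster's p-value is the fraction of permutation maxima at or above
    its mass.
    """
    if n_perm < 500:
        raise ValueError("n_perm must be >= 500 for stable cluster p-values")
    diffs = np.asarray(diffs, dtype=float)
    n_sub, n_sens = diffs.shape

    def tmap(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t, p = stats.ttest_1samp(d, 0.0, axis=0)
        return np.nan_to_num(t), np.nan_to_num(p, nan=1.0)

    t_obs, p_obs = tmap(diffs)
    observed = _find_clusters(t_obs, p_obs, adjacency, alpha, min_size)
    if not observed:
        return []
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n_sub)
        t_p, p_p = tmap(diffs * flips[:, None])
        cl = _find_clusters(t_p, p_p, adjacency, alpha, min_size)
        null_max[i] = max((mass for _, mass, _ in cl), default=0.0)
    return [
        ClusterResult(members, mass, float(np.mean(null_max >= mass)), direction)
        for members, mass, direction in observed
    ]


def within_subject_permutation(
    event_indices: list[np.ndarray],
    phase: np.ndarray,
    n_perm: int = 500,
    seed: int = 0,
    min_events: int = 2,
) -> np.ndarray:
    """Per-sensor p for phase locking, preserving event autocorrelation.

    ``event_indices[j]`` holds trial j's event positions as sample indices
    into ``phase`` (trials x sensors x time).  The null circularly shifts
    each trial's whole event vector by a uniform random offset (the same
    shift for all sensors of that trial), preserving inter-event
    structure.  p per sensor is the fraction of null mean-z values at or
    above the observed mean z.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable p-value")
    n_trials, n_sensors, n_times = phase.shape
    bearing = [j for j in range(n_trials) if len(event_indices[j]) >= min_events]
    if not bearing:
        raise ValueError("no event-bearing trials: nothing to test")

    def mean_z(shifts: np.ndarray) -> np.ndarray:
        zs = np.zeros((len(bearing), n_sensors))
        for row, j in enumerate(bearing):
            idx = (event_indices[j] + shifts[row]) % n_times
            ph = phase[j, :, idx]  # (events, sensors)
            vec = np.abs(np.exp(1j * ph).mean(axis=0))
            zs[row] = arcsine_z(np.clip(vec, 0.0, 1.0))
        return zs.mean(axis=0)

    observed = mean_z(np.zeros(len(bearing), dtype=int))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_sensors)
    for _ in range(n_perm):
        shifts = rng.integers(0, n_times, size=len(bearing))
        exceed += mean_z(shifts) >= observed
    return exceed / n_perm


def behavior_correlation(
    subject_z: np.ndarray,
    accuracy: np.ndarray,
    adjacency: sparse.spmatrix | None = None,
    r_threshold: float = 0.7,
    alpha: float = 0.05,
    min_cluster: int = MIN_CLUSTER_SIZE,
) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Pearson correlation between per-sensor coupling and behavior.

    ``subject_z`` is (subjects x sensors) trial-mean z; ``accuracy`` the
    per-subject behavioral accuracy.  Sensors are flagged when r exceeds
    ``r_threshold`` with two-sided p < ``alpha``; flagged sensor sets are
    reported only when at least ``min_cluster`` are mutually adjacent.
    """
    subject_z = np.asarray(subject_z, dtype=float)
    accuracy = np.asarray(accuracy, dtype=float)
    if len(accuracy) < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    if np.allclose(accuracy.std(), 0.0):
        raise ValueError("behavioral accuracy is constant: r undefined")
    n_sens = subject_z.shape[1]
    r = np.zeros(n_sens)
    p = np.ones(n_sens)
    for s in range(n_sens):
        if np.allclose(subject_z[:, s].std(), 0.0):
            r[s], p[s] = 0.0, 1.0
        else:
            r[s], p[s] = stats.pearsonr(subject_z[:, s], accuracy)
    flagged = (r > r_threshold) & (p < alpha)
    table = pd.DataFrame({"sensor": np.arange(n_sens), "r": r, "p": p, "flagged": flagged})
    clusters: list[np.ndarray] = []
    if adjacency is not None and flagged.any():
        sig = np.flatnonzero(flagged)
        sub = adjacency[np.ix_(sig, sig)]
        n_comp, labels = connected_components(sub, directed=False)
        for c in range(n_comp):
            members = sig[labels == c]
            if len(members) >= min_cluster:
                clusters.append(members)
    return table, clusters
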