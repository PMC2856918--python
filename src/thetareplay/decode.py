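"""Time-point-wise multivariate pattern classification of stimulus category.

Features are baseline-normalized spectral amplitudes at a single training
time point, restricted to the 13-79 Hz band (38 grid frequencies; the
2-12 Hz components are excluded).  Feature selection keeps the
(sensor, frequency) bins whose paired two-tailed t statistic over the
20 indoor / 20 outdoor exemplar pairs has p < 0.05, independently per
training time point.

The classifier is a feedforward network: selected features -> 20 logistic
hidden units -> 2 logistic output units, targets (1 0) for indoor and
(0 1) for outdoor, trained by minimizing the summed squared error with a
conjugate-gradient optimizer stopped after 20 iterations.  During
maintenance the network is applied at 250 evenly spaced test points
spanning the delay minus 250 ms margins; an output is counted correct when
the unit matching the trial's true category exceeds 0.95.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import CATEGORIES, MAINTENANCE_WINDOW, TFRepresentation
from .timefreq import feature_band_mask

#: classifier training time points, ms relative to sample onset
TRAINING_TIMES = tuple(float(t) for t in range(-36, 765, 80))
N_HIDDEN = 20
N_ITER = 20
OUTPUT_THRESHOLD = 0.95


class EmptyMaskError(ValueError):
    """No features survived selection; training is refused."""


@dataclass
class FeatureMask:
    """Selected (sensor, frequency) bins at one training time point."""

    time_point: float
    condition: str
    sensor_idx: np.ndarray
    freq_idx: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.sensor_idx)


@dataclass
class TrainedClassifier:
    mask: FeatureMask
    w1: np.ndarray  # (n_features, 20)
    b1: np.ndarray
    w2: np.ndarray  # (20, 2)
    b2: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    time_point: float
    condition: str
    seed: int
    n_iterations: int = N_ITER


def _category_pairs(labels: pd.DataFrame | np.ndarray):
    """Indoor/outdoor trial indices paired by presentation index."""
    if isinstance(labels, pd.DataFrame):
        cats = labels["category"].to_numpy()
        pair = labels["pair_index"].to_numpy() if "pair_index" in labels else None
    else:
        cats = np.asarray(labels)
        pair = None
    indoor = np.flatnonzero(cats == "indoor")
    outdoor = np.flatnonzero(cats == "outdoor")
    if pair is not None:
        indoor = indoor[np.argsort(pair[indoor])]
        outdoor = outdoor[np.argsort(pair[outdoor])]
    return indoor, outdoor


def features_at(tf: TFRepresentation, time_point: float, band=(13.0, 79.0)) -> tuple[np.ndarray, np.ndarray]:
    """Flattened (trials, sensor x band-frequency) feature matrix at one
    time point, plus the (sensor_idx, freq_idx) coordinates of each column."""
    ti = tf.time_index(time_point)
    fmask = feature_band_mask(tf.freqs, band)
    amp = tf.amplitude[:, :, fmask, ti]
    n_trials, n_sensors, n_freqs = amp.shape
    sensor_idx, freq_idx = np.meshgrid(
        np.arange(n_sensors), np.flatnonzero(fmask), indexing="ij"
    )
    return (
        amp.reshape(n_trials, n_sensors * n_freqs).astype(np.float64),
        np.c_[sensor_idx.ravel(), freq_idx.ravel()],
    )


def select_features(
    tf: TFRepresentation,
    time_point: float,
    labels: pd.DataFrame,
    alpha: float = 0.05,
    condition: str = "",
    band: tuple[float, float] = (13.0, 79.0),
) -> FeatureMask:
    """Paired two-tailed t-test per (sensor, frequency) bin; keep p < alpha.

    Raises :class:`EmptyMaskError` when nothing is selected (including the
    degenerate ``alpha = 0``).
    """
    x, coords = features_at(tf, time_point, band)
    indoor, outdoor = _category_pairs(labels)
    n = min(len(indoor), len(outdoor))
    t, p = stats.ttest_rel(x[indoor[:n]], x[outdoor[:n]], axis=0)
    keep = np.flatnonzero(p < alpha)
    if len(keep) == 0:
        raise EmptyMaskError(
            f"no features below alpha={alpha} at t={time_point} ms"
        )
    return FeatureMask(
        time_point,
        condition,
        coords[keep, 0],
        coords[keep, 1],
        t[keep],
        p[keep],
    )


def _extract(tf: TFRepresentation, mask: FeatureMask, time_point: float | None = None) -> np.ndarray:
    tp = mask.time_point if time_point is None else time_point
    ti = tf.time_index(tp)
    if mask.freq_idx.max() >= len(tf.freqs) or mask.sensor_idx.max() >= tf.amplitude.shape[1]:
        raise ValueError("feature mask references bins absent from this representation")
    return tf.amplitude[:, mask.sensor_idx, mask.freq_idx, ti].astype(np.float64)


def _targets(cats: np.ndarray) -> np.ndarray:
    # (1 0) indoor, (0 1) outdoor
    t = np.zeros((len(cats), 2))
    t[np.asarray(cats) == "indoor", 0] = 1.0
    t[np.asarray(cats) == "outdoor", 1] = 1.0
    return t


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _unpack(theta: np.ndarray, nf: int):
    i = 0
    w1 = theta[i : i + nf * N_HIDDEN].reshape(nf, N_HIDDEN); i += nf * N_HIDDEN
    b1 = theta[i : i + N_HIDDEN]; i += N_HIDDEN
    w2 = theta[i : i + N_HIDDEN * 2].reshape(N_HIDDEN, 2); i += N_HIDDEN * 2
    b2 = theta[i : i + 2]
    return w1, b1, w2, b2


def _loss_grad(theta: np.ndarray, x: np.ndarray, t: np.ndarray, nf: int):
    w1, b1, w2, b2 = _unpack(theta, nf)
    h = _sigmoid(x @ w1 + b1)
    y = _sigmoid(h @ w2 + b2)
    err = y - t
    loss = float(np.sum(err ** 2))
    dy = 2.0 * err * y * (1 - y)
    dh = (dy @ w2.T) * h * (1 - h)
    grad = np.concatenate(
        [
            (x.T @ dh).ravel(),
            dh.sum(axis=0),
            (h.T @ dy).ravel(),
            dy.sum(axis=0),
        ]
    )
    return loss, grad


def train_classifier(
    tf: TFRepresentation,
    mask: FeatureMask,
    labels: pd.DataFrame,
    seed: int = 0,
    trial_subset: np.ndarray | None = None,
) -> TrainedClassifier:
    """Train the 20-hidden-unit network for (at most) 20 CG iterations.

    Features are z-scored with training-set statistics.  Reproducible
    given ``seed`` (small uniform weight initialization).
    """
    x = _extract(tf, mask)
    cats = labels["category"].to_numpy()
    if trial_subset is not None:
        x = x[trial_subset]
        cats = cats[trial_subset]
    for cat in CATEGORIES:
        if np.sum(cats == cat) < 2:
            raise ValueError(f"fewer than 2 exemplars of {cat}")
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - mean) / sd
    t = _targets(cats)
    nf = x.shape[1]
    rng = np.random.default_rng(seed)
    r1, r2 = 1.0 / np.sqrt(nf), 1.0 / np.sqrt(N_HIDDEN)
    theta0 = np.concatenate(
        [
            rng.uniform(-r1, r1, nf * N_HIDDEN),
            rng.uniform(-r1, r1, N_HIDDEN),
            rng.uniform(-r2, r2, N_HIDDEN * 2),
            rng.uniform(-r2, r2, 2),
        ]
    )
    res = optimize.minimize(
        _loss_grad,
        theta0,
        args=(xs, t, nf),
        jac=True,
        method="CG",
        options={"maxiter": N_ITER, "gtol": 1e-12},
    )
    w1, b1, w2, b2 = _unpack(res.x, nf)
    return TrainedClassifier(
        mask, w1, b1, w2, b2, mean, sd, mask.time_point, mask.condition, seed
    )


def predict(clf: TrainedClassifier, x: np.ndarray) -> np.ndarray:
    """Raw network outputs in [0, 1]^2 for a (trials, features) matrix."""
    xs = (x - clf.feature_mean) / clf.feature_sd
    h = _sigmoid(xs @ clf.w1 + clf.b1)
    return _sigmoid(h @ clf.w2 + clf.b2)


def loocv_folds(
    tf: TFRepresentation,
    time_point: float,
    labels: pd.DataFrame,
    alpha: float = 0.05,
    seed: int = 0,
    condition: str = "",
):
    """Yield (classifier, held_out_index) per leave-one-out fold.

    Feature selection is re-run inside each fold on the training trials
    only.  Folds are balanced: the held-out trial's category partner (same
    presentation index) is excluded from that fold's training set, so the
    network always trains on equally many indoor and outdoor exemplars and
    the held-out trial never influences selection or weights.
    """
    indoor, outdoor = _category_pairs(labels)
    n = min(len(indoor), len(outdoor))
    if n < 2:
        raise ValueError("need at least 2 trials per category")
    pairs = np.c_[indoor[:n], outdoor[:n]]
    all_idx = np.sort(pairs.ravel())
    for pi in range(n):
        train_idx = np.setdiff1d(all_idx, pairs[pi])
        sub_labels = labels.iloc[train_idx].reset_index(drop=True)
        sub_tf = TFRepresentation(
            tf.amplitude[train_idx], tf.freqs, tf.times, baseline=tf.baseline
        )
        mask = select_features(sub_tf, time_point, sub_labels, alpha, condition)
        clf = train_classifier(sub_tf, mask, sub_labels, seed=seed + pi)
        for held in pairs[pi]:
            yield clf, int(held)


def loocv_accuracy(
    tf: TFRepresentation,
    time_point: float,
    labels: pd.DataFrame,
    alpha: float = 0.05,
    seed: int = 0,
    condition: str = "",
) -> float:
    """Mean held-out accuracy (winning output unit vs true category)."""
    cats = labels["category"].to_numpy()
    n_correct = 0
    n_total = 0
    for clf, held in loocv_folds(tf, time_point, labels, alpha, seed, condition):
        x = _extract(tf, clf.mask)[held : held + 1]
        y = predict(clf, x)[0]
        pred = CATEGORIES[int(np.argmax(y))]
        n_correct += int(pred == cats[held])
        n_total += 1
    if n_total == 0:
        raise ValueError("no folds evaluated")
    return n_correct / n_total


def maintenance_test_points(n_points: int = 250, margin: float = 250.0, grid_ms: float = 4.0) -> np.ndarray:
    """Evenly spaced maintenance test points, snapped to the 250 Hz grid."""
    lo = np.ceil((MAINTENANCE_WINDOW[0] + margin) / grid_ms) * grid_ms
    hi = np.floor((MAINTENANCE_WINDOW[1] - margin) / grid_ms) * grid_ms
    pts = np.linspace(lo, hi, n_points)
    return np.unique(np.round(pts / grid_ms) * grid_ms)


def classify_maintenance(
    clf: TrainedClassifier,
    tf: TFRepresentation,
    labels: pd.DataFrame,
    test_points: np.ndarray | None = None,
    threshold: float = OUTPUT_THRESHOLD,
) -> pd.DataFrame:
    """Thresholded single-trial classification along the delay.

    Returns one record per trial x test point with the raw outputs, the
    correctness under the >0.95 rule, and a diagnostic ``ambiguous`` flag
    for outputs exceeding the threshold on both units (flagged trials are
    never counted correct).
    """
    if test_points is None:
        test_points = maintenance_test_points()
    cats = labels["category"].to_numpy()
    true_col = np.where(cats == "indoor", 0, 1)
    records = []
    for tp in test_points:
        x = _extract(tf, clf.mask, time_point=tp)
        y = predict(clf, x)
        both = (y[:, 0] > threshold) & (y[:, 1] > threshold)
        correct = (y[np.arange(len(y)), true_col] > threshold) & ~both
        for j in range(len(y)):
            records.append(
                (j, cats[j], float(tp), float(y[j, 0]), float(y[j, 1]), bool(correct[j]), bool(both[j]))
            )
    return pd.DataFrame.from_records(
        records,
        columns=["trial", "category", "time", "out_indoor", "out_outdoor", "correct", "ambiguous"],
    )


def thresholded_correct(outputs: np.ndarray, true_category: str, threshold: float = OUTPUT_THRESHOLD) -> bool:
    """The >0.95 correctness rule for a single output pair."""
    o = np.asarray(outputs, dtype=float)
    col = 0 if true_category == "indoor" else 1
    if o[0] > threshold and o[1] > threshold:
        return False
    return bool(o[col] > threshold)
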