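"""Core in-memory containers shared across the pipeline.

Conventions: all times are in milliseconds relative to sample (stimulus)
onset; the epoch spans a 1 s pre-stimulus margin, 3 s of sample
presentation and a 5 s maintenance (delay) period.  Signals are stored as
``trials x sensors x time`` float arrays.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import sparse

CATEGORIES = ("indoor", "outdoor")
CONDITIONS = ("control", "nonconfigural", "configural")

#: maintenance (delay) window, ms relative to sample onset, half-open
MAINTENANCE_WINDOW = (3000.0, 8000.0)
SAMPLE_WINDOW = (0.0, 3000.0)


class SchemaError(ValueError):
    """Raised when a persisted artifact or container is malformed."""


@dataclass
class SensorLayout:
    """2D sensor layout with an adjacency notion for cluster statistics.

    ``ids`` are unique sensor names; ``pos`` is an ``(n, 2)`` array of
    planar coordinates (arbitrary units).
    """

    ids: list[str]
    pos: np.ndarray
    adjacency_kind: str = "grid"  # "grid" (rook+bishop) or "knn"
    knn_k: int = 6

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if len(self.ids) != len(set(self.ids)):
            raise SchemaError("duplicate sensor ids in layout")
        if self.pos.shape != (len(self.ids), 2):
            raise SchemaError("layout pos must be (n_sensors, 2)")

    @property
    def n_sensors(self) -> int:
        return len(self.ids)

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric boolean sensor adjacency.

        Grid layouts connect the 8 surrounding grid cells (rook + bishop
        moves); irregular layouts use symmetrized k-nearest neighbours.
        """
        n = self.n_sensors
        if self.adjacency_kind == "grid":
            # nearest grid step defines the lattice constant
            tree = cKDTree(self.pos)
            d, _ = tree.query(self.pos, k=2)
            step = float(np.median(d[:, 1]))
            pairs = tree.query_pairs(r=step * np.sqrt(2) * 1.01)
        elif self.adjacency_kind == "knn":
            tree = cKDTree(self.pos)
            k = min(self.knn_k + 1, n)
            _, idx = tree.query(self.pos, k=k)
            pairs = {(i, j) for i, row in enumerate(idx) for j in row[1:]}
            pairs = {(min(i, j), max(i, j)) for i, j in pairs}
        else:  # pragma: no cover - guarded by construction
            raise ValueError(f"unknown adjacency kind {self.adjacency_kind!r}")
        if pairs:
            rows, cols = np.array(sorted(pairs)).T
        else:
            rows = cols = np.array([], dtype=int)
        a = sparse.coo_matrix(
            (np.ones(len(rows), bool), (rows, cols)), shape=(n, n)
        )
        a = a + a.T
        return a.tocsr()


def grid_layout(n_sensors: int) -> SensorLayout:
    """Square-ish grid layout used for desk-scale synthetic cohorts."""
    side = int(np.ceil(np.sqrt(n_sensors)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    pos = np.c_[xs.ravel(), ys.ravel()][:n_sensors].astype(float)
    ids = [f"S{i:03d}" for i in range(n_sensors)]
    return SensorLayout(ids, pos, adjacency_kind="grid")


def ctf275_like_layout() -> SensorLayout:
    """A 275-sensor whole-head-like layout (concentric rings), synthetic.

    This is a synthetic stand-in for a CTF gradiometer layout: 275 sensors
    on concentric rings of a disc, with k-nearest-neighbour adjacency.
    """
    n = 275
    pos = []
    n_rings = 10
    counts = np.linspace(6, 50, n_rings).astype(int)
    counts = (counts * n / counts.sum()).astype(int)
    counts[-1] += n - counts.sum()
    for ring, cnt in enumerate(counts):
        r = (ring + 1) / n_rings
        ang = 2 * np.pi * (np.arange(cnt) + 0.5 * (ring % 2)) / cnt
        pos.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    ids = [f"M{i:03d}" for i in range(n)]
    return SensorLayout(ids, np.array(pos), adjacency_kind="knn", knn_k=6)


@dataclass
class EpochSet:
    """Multichannel epoched recordings: ``trials x sensors x time``.

    ``times`` is in ms relative to sample onset with uniform spacing
    ``1000 / sfreq``; ``metadata`` has one row per trial with at least
    ``category``, ``condition`` and ``subject`` columns.
    """

    signal: np.ndarray
    times: np.ndarray
    sfreq: float
    metadata: pd.DataFrame
    layout: SensorLayout

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        self.times = np.asarray(self.times, dtype=float)
        if self.signal.ndim != 3:
            raise SchemaError("signal must be trials x sensors x time")
        n_trials, n_sensors, n_times = self.signal.shape
        if len(self.times) != n_times:
            raise SchemaError("time axis length mismatch")
        dt = np.diff(self.times)
        if n_times > 1 and not np.allclose(dt, 1000.0 / self.sfreq, rtol=1e-6):
            raise SchemaError("time axis must be uniform at 1/sfreq")
        if len(self.metadata) != n_trials:
            raise SchemaError("metadata length must equal trial count")
        if self.layout.n_sensors != n_sensors:
            raise SchemaError("layout does not match sensor dimension")

    @property
    def n_trials(self) -> int:
        return self.signal.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.signal.shape[1]

    def time_index(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times - t_ms)))

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            self.signal[mask],
            self.times,
            self.sfreq,
            self.metadata.iloc[mask].reset_index(drop=True)
            if mask.dtype == bool
            else self.metadata.iloc[mask].reset_index(drop=True),
            self.layout,
        )


@dataclass
class TFRepresentation:
    """Spectral amplitude, ``trials x sensors x frequencies x time``.

    ``times`` need not be the full epoch axis: the transform may be
    evaluated at a selected set of output times (e.g. classifier training
    and test points plus the baseline window).  ``baseline`` records the
    window subtracted by :func:`thetareplay.timefreq.baseline_normalize`
    (``None`` before normalization).
    """

    amplitude: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    baseline: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.amplitude.ndim != 4:
            raise SchemaError("amplitude must be trials x sensors x freqs x time")
        if self.amplitude.shape[2] != len(self.freqs):
            raise SchemaError("frequency axis mismatch")
        if self.amplitude.shape[3] != len(self.times):
            raise SchemaError("time axis mismatch")
        if not np.all(np.isfinite(self.amplitude)):
            raise SchemaError("amplitude must be finite everywhere")

    def freq_index(self, f: float) -> int:
        i = int(np.argmin(np.abs(self.freqs - f)))
        if abs(self.freqs[i] - f) > 1e-9:
            raise ValueError(f"frequency {f} Hz not on grid")
        return i

    def time_index(self, t_ms: float, atol: float = 2.0) -> int:
        i = int(np.argmin(np.abs(self.times - t_ms)))
        if abs(self.times[i] - t_ms) > atol:
            raise ValueError(f"time {t_ms} ms not in representation")
        return i


@dataclass
class PhaseSeries:
    """Instantaneous phase at one analysis frequency, wrapped to (-pi, pi].

    ``phase`` is ``trials x sensors x time``.
    """

    phase: np.ndarray
    freq: float
    times: np.ndarray
    sfreq: float = 250.0

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase)
        self.times = np.asarray(self.times, dtype=float)
        if self.phase.ndim != 3:
            raise SchemaError("phase must be trials x sensors x time")
        if self.phase.shape[2] != len(self.times):
            raise SchemaError("time axis mismatch")

    def time_index(self, t_ms: float) -> int:
        """Nearest-sample lookup (events live on the 250 Hz grid)."""
        return int(np.argmin(np.abs(self.times - t_ms)))
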