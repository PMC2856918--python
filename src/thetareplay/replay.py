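"""Reactivation (replay) detection from thresholded classifier outputs.

At each maintenance test point the number C of correctly classified trials
out of n = 20 per category is referred to a one-tailed binomial test
against chance r = 0.5, using the normal approximation to the binomial
density (an exact binomial is provided as the testing oracle).  The
per-comparison threshold is Bonferroni-corrected over the 250 test points
x 11 classifiers family: 0.05 / 2750 = 1.8e-5, which with n = 20 is passed
only by perfect 20/20 classification.  Time points passing the threshold
are reactivation times; the correct trials at those times are the
reactivation events carried forward to the theta-coupling stage, merged
over the classifiers trained from 44 to 764 ms (duplicate (trial, time)
detections collapse to one event).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: classifiers whose detections enter the merged event list (ms)
MERGE_CLASSIFIER_WINDOW = (44.0, 764.0)


@dataclass
class BinomialTestSpec:
    """Family-corrected binomial significance spec for accuracy counts."""

    n: int = 20
    r: float = 0.5
    family_size: int = 250 * 11
    family_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.r < 1.0):
            raise ValueError("chance probability must lie in (0, 1)")
        if self.family_size <= 0:
            raise ValueError("family size must be positive")

    @property
    def corrected_alpha(self) -> float:
        return self.family_alpha / self.family_size


def binomial_pvalue(C: int, spec: BinomialTestSpec, method: str = "normal") -> float:
    """One-tailed upper p-value for >= C correct of n at chance r.

    ``method="normal"`` is the normal approximation without continuity
    correction; ``method="exact"`` is the exact binomial tail used as the
    referee in tests.
    """
    if C < 0 or C > spec.n:
        raise ValueError(f"count {C} outside 0..{spec.n}")
    if method == "normal":
        mu = spec.n * spec.r
        sd = np.sqrt(spec.n * spec.r * (1 - spec.r))
        return float(stats.norm.sf((C - mu) / sd))
    if method == "exact":
        return float(stats.binom.sf(C - 1, spec.n, spec.r))
    raise ValueError(f"unknown method {method!r}")


def corrected_threshold(spec: BinomialTestSpec) -> float:
    """Bonferroni per-comparison alpha: family alpha / family size."""
    return spec.corrected_alpha


def min_significant_count(spec: BinomialTestSpec, method: str = "normal") -> int:
    """Smallest correct-count whose p-value falls below the corrected
    threshold (n + 1 if none does)."""
    thr = spec.corrected_alpha
    for c in range(spec.n + 1):
        if binomial_pvalue(c, spec, method) < thr:
            return c
    return spec.n + 1


@dataclass
class ReactivationSet:
    """Detected reactivation times and their per-trial events.

    ``times`` has one row per (condition_trained, condition_tested,
    category, classifier_time, time) that passed the corrected threshold;
    ``events`` lists the correct trials at those times.  ``merged_events``
    collapses duplicate (trial, time) detections across the 44-764 ms
    classifiers for the coupling stage.
    """

    times: pd.DataFrame
    events: pd.DataFrame
    spec: BinomialTestSpec = field(default_factory=BinomialTestSpec)

    def merged_events(self) -> pd.DataFrame:
        lo, hi = MERGE_CLASSIFIER_WINDOW
        ev = self.events
        keep = (ev["classifier_time"] >= lo) & (ev["classifier_time"] <= hi)
        cols = ["condition_trained", "condition_tested", "category", "trial", "time"]
        return ev.loc[keep, cols].drop_duplicates().reset_index(drop=True)


def detect_reactivations(
    records: pd.DataFrame,
    spec: BinomialTestSpec | None = None,
    method: str = "normal",
    classifier_time: float = np.nan,
    condition_trained: str = "",
    condition_tested: str = "",
) -> ReactivationSet:
    """Apply the corrected binomial rule to one classifier's record table.

    ``records`` is the output of
    :func:`thetareplay.decode.classify_maintenance` for all trials of one
    (subject, condition, classifier); counts are formed per category and
    test point.
    """
    spec = spec or BinomialTestSpec()
    times_rows, event_rows = [], []
    for cat, grp in records.groupby("category", observed=True):
        counts = grp.groupby("time", observed=True)["correct"].agg(["sum", "size"])
        if counts["size"].nunique() > 1:
            raise ValueError("inconsistent trial counts across time points")
        if int(counts["size"].iloc[0]) != spec.n:
            raise ValueError(
                f"records contain {int(counts['size'].iloc[0])} trials per "
                f"time point, spec expects n={spec.n}"
            )
        for t, row in counts.iterrows():
            C = int(row["sum"])
            p = binomial_pvalue(C, spec, method)
            if p < spec.corrected_alpha:
                times_rows.append(
                    (condition_trained, condition_tested, cat, classifier_time, float(t), C, p)
                )
                hit = grp[(grp["time"] == t) & grp["correct"]]
                for trial in hit["trial"].to_numpy():
                    event_rows.append(
                        (condition_trained, condition_tested, cat, classifier_time, int(trial), float(t))
                    )
    times = pd.DataFrame(
        times_rows,
        columns=[
            "condition_trained", "condition_tested", "category",
            "classifier_time", "time", "n_correct", "p_value",
        ],
    )
    events = pd.DataFrame(
        event_rows,
        columns=["condition_trained", "condition_tested", "category", "classifier_time", "trial", "time"],
    )
    return ReactivationSet(times, events, spec)


def combine(sets: list[ReactivationSet]) -> ReactivationSet:
    """Union of reactivation sets (e.g. across classifiers or categories)."""
    if not sets:
        return ReactivationSet(
            pd.DataFrame(
                columns=[
                    "condition_trained", "condition_tested", "category",
                    "classifier_time", "time", "n_correct", "p_value",
                ]
            ),
            pd.DataFrame(
                columns=["condition_trained", "condition_tested", "category", "classifier_time", "trial", "time"]
            ),
        )
    times = [s.times for s in sets if not s.times.empty]
    events = [s.events for s in sets if not s.events.empty]
    empty = combine([])
    return ReactivationSet(
        pd.concat(times, ignore_index=True) if times else empty.times,
        pd.concat(events, ignore_index=True) if events else empty.events,
        sets[0].spec,
    )


def count_reactivations(rs: ReactivationSet, grouping: list[str] | None = None) -> pd.Series:
    """Number of reactivation times per group (a grand total when
    ``grouping`` is None).  Totals collapse consistently: summing counts
    over a finer grouping reproduces the coarser totals."""
    if grouping is None:
        return pd.Series({"total": len(rs.times)})
    valid = {"condition_trained", "condition_tested", "category", "classifier_time"}
    bad = set(grouping) - valid
    if bad:
        raise KeyError(f"invalid grouping keys {sorted(bad)}")
    if rs.times.empty:
        return pd.Series(dtype=int)
    return rs.times.groupby(grouping, observed=True).size()


def compare_counts(counts_a: np.ndarray, counts_b: np.ndarray) -> tuple[float, float]:
    """Paired one-tailed t-test (A > B) on per-subject reactivation totals."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need paired totals for at least 2 subjects")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences")
    t, p = stats.ttest_rel(a, b, alternative="greater")
    return float(t), float(p)
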