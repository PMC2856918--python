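"""Reusable study computations over the synthetic cohorts.

Each function runs one self-contained validation study end to end —
generation, analysis, and the summary quantity — so that the analysis
drivers, the test suite and the acceptance script all execute the same
code paths.  Problem sizes default to desk scale; the rationale for each
is given in docs/methods.md.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import coupling as cp
from . import decode, replay, synth, timefreq
from .containers import CONDITIONS, grid_layout


def _band_times(extra: np.ndarray) -> np.ndarray:
    """Baseline-window grid (250 Hz) plus the requested analysis times."""
    base = np.arange(-500.0, -99.0, 4.0)
    return np.unique(np.r_[base, np.asarray(extra, dtype=float)])


def _condition_tfr(epochs, spec, band, times):
    """Per-condition baseline-normalized TF amplitude at selected times."""
    out = {}
    for cond in CONDITIONS:
        idx = np.flatnonzero(epochs.metadata["condition"] == cond)
        sub = epochs.select_trials(idx)
        tf = timefreq.cwt_amplitude(sub, spec, freqs=band, times=times)
        out[cond] = (timefreq.baseline_normalize(tf), sub.metadata, idx)
    return out


def baseline_loocv_study(
    seed: int,
    n_subjects: int = 8,
    n_sensors: int = 64,
    time_point: float = -36.0,
) -> tuple[float, pd.DataFrame]:
    """LOOCV accuracy of the pre-stimulus baseline classifier.

    The generator plants no category information before sample onset, so
    held-out accuracy should sit at chance (0.5).  Returns the grand mean
    over subjects x conditions and the per-cell table.
    """
    params = synth.GeneratorParams(n_subjects=n_subjects, n_sensors=n_sensors, rng_seed=seed)
    spec = timefreq.WaveletSpec()
    band = spec.freqs[timefreq.feature_band_mask(spec.freqs)]
    times = _band_times(np.array([time_point]))
    rows = []
    for si in range(n_subjects):
        epochs, _ = synth.generate_subject(params, si)
        for cond, (tf, labels, _) in _condition_tfr(epochs, spec, band, times).items():
            acc = decode.loocv_accuracy(tf, time_point, labels, seed=seed + si, condition=cond)
            rows.append((si, cond, acc))
    table = pd.DataFrame(rows, columns=["subject", "condition", "accuracy"])
    return float(table["accuracy"].mean()), table


def reactivation_count_study(
    seed: int,
    n_subjects: int = 8,
    n_sensors: int = 24,
    training_times: tuple[float, ...] = (364.0, 444.0),
    n_test_points: int = 100,
    params: synth.GeneratorParams | None = None,
) -> pd.DataFrame:
    """Within- and cross-condition reactivation counts per subject.

    Classifiers trained on each condition's sample period are applied to
    every condition's maintenance period; counts are totals of detected
    reactivation times (corrected 20/20 rule) over classifiers and
    categories.  Returns a long table
    (subject, condition_trained, condition_tested, count).
    """
    if params is None:
        params = synth.GeneratorParams(n_subjects=n_subjects, n_sensors=n_sensors, rng_seed=seed)
    spec = timefreq.WaveletSpec()
    band = spec.freqs[timefreq.feature_band_mask(spec.freqs)]
    test_pts = decode.maintenance_test_points(n_test_points)
    times = _band_times(np.r_[np.asarray(training_times), test_pts])
    bspec = replay.BinomialTestSpec(n=params.n_trials_per_category)
    rows = []
    for si in range(params.n_subjects):
        epochs, _ = synth.generate_subject(params, si)
        tfrs = _condition_tfr(epochs, spec, band, times)
        counts = {(a, b): 0 for a in CONDITIONS for b in CONDITIONS}
        for cond in CONDITIONS:
            tf_train, labels_train, _ = tfrs[cond]
            for tp in training_times:
                try:
                    mask = decode.select_features(tf_train, tp, labels_train, condition=cond)
                except decode.EmptyMaskError:
                    continue
                clf = decode.train_classifier(tf_train, mask, labels_train, seed=seed + si)
                for tested in CONDITIONS:
                    tf_test, labels_test, _ = tfrs[tested]
                    rec = decode.classify_maintenance(clf, tf_test, labels_test, test_pts)
                    rs = replay.detect_reactivations(
                        rec, bspec, classifier_time=tp,
                        condition_trained=cond, condition_tested=tested,
                    )
                    counts[(cond, tested)] += len(rs.times)
        for (a, b), n in counts.items():
            rows.append((si, a, b, n))
    return pd.DataFrame(rows, columns=["subject", "condition_trained", "condition_tested", "count"])


def ordering_contrasts(counts: pd.DataFrame) -> dict:
    """Paired one-tailed tests on within-condition totals: the replay-rate
    ordering configural > nonconfigural > control."""
    within = counts[counts["condition_trained"] == counts["condition_tested"]]
    pivot = within.pivot(index="subject", columns="condition_trained", values="count")
    out = {}
    for a, b in [("configural", "nonconfigural"), ("nonconfigural", "control"), ("configural", "control")]:
        t, p = replay.compare_counts(pivot[a].to_numpy(), pivot[b].to_numpy())
        out[f"{a}_gt_{b}"] = {"t": t, "p": p, "mean_a": float(pivot[a].mean()), "mean_b": float(pivot[b].mean())}
    return out


def specificity_contrast(counts: pd.DataFrame) -> dict:
    """Within- vs cross-condition counts (paired one-tailed over subjects),
    for the memory conditions where the generator plants replay."""
    rows = counts[counts["condition_trained"].isin(["configural", "nonconfigural"])]
    within = (
        rows[rows["condition_trained"] == rows["condition_tested"]]
        .groupby("subject")["count"].sum()
    )
    cross = (
        rows[rows["condition_trained"] != rows["condition_tested"]]
        .groupby("subject")["count"].sum()
    )
    t, p = replay.compare_counts(within.to_numpy(), cross.to_numpy())
    return {
        "t": t, "p": p,
        "mean_within": float(within.mean()), "mean_cross": float(cross.mean()),
    }


def kappa_recovery_study(
    seed: int,
    kappas: tuple[float, ...] = (0.0, 1.0, 4.0, 20.0),
    mu: float = 1.0,
    n_sensors: int = 16,
) -> dict:
    """Parameter recovery of the von Mises coupling through the measured
    phase path: trial-mean PLV at the coupled sensors per kappa, and the
    estimated preferred phase at the largest kappa.
    """
    spec = timefreq.WaveletSpec()
    grid = np.arange(3000.0, 8000.0, 4.0)
    plv_by_kappa = {}
    mu_est = None
    for kappa in kappas:
        params = synth.GeneratorParams(
            n_subjects=1, n_sensors=n_sensors,
            coupling_kappa=float(kappa), coupling_mu=float(mu), rng_seed=seed,
        )
        epochs, gt = synth.generate_subject(params, 0)
        hp = timefreq.zero_phase_highpass(epochs, 3.0)
        ph = timefreq.instantaneous_phase(hp, 6.0, spec, times=grid)
        couple = gt.coupling_clusters["configural"]
        sens = np.flatnonzero(gt.cluster_of_sensor == couple)
        plvs, phases = [], []
        for j in range(len(epochs.metadata)):
            if epochs.metadata.iloc[j]["condition"] != "configural":
                continue
            if len(gt.event_times[j]) < 2:
                continue
            idx = np.array([ph.time_index(t) for t in gt.event_times[j]])
            mat = ph.phase[j][:, idx]  # (sensors, events)
            plvs.extend(np.abs(np.exp(1j * mat[sens]).mean(axis=1)))
            phases.append(mat[sens[0]])
        plv_by_kappa[kappa] = float(np.mean(plvs))
        if kappa == max(kappas):
            mu_est = cp.circular_mean(np.concatenate(phases))
    return {"plv_by_kappa": plv_by_kappa, "mu_true": float(mu), "mu_est": float(mu_est)}


def cluster_fwer_study(
    seed: int,
    n_reps: int = 40,
    n_subjects: int = 8,
    n_sensors: int = 36,
    n_perm: int = 500,
) -> float:
    """Family-wise error of the cluster permutation test under the null
    generator (equal rates, kappa = 0 in both memory conditions), using
    the planted-phase path.  Returns the fraction of replicate cohorts
    with any cluster at p < 0.05.
    """
    layout = grid_layout(n_sensors)
    adjacency = layout.adjacency()
    false_positives = 0
    for rep in range(n_reps):
        params = synth.GeneratorParams(
            n_subjects=n_subjects, n_sensors=n_sensors,
            replay_rate={"nonconfigural": 4.0, "configural": 4.0},
            coupling_kappa=0.0, rng_seed=seed + 1000 * rep,
        )
        tables = [
            cp.plv_table_from_ground_truth(synth.generate_ground_truth(params, i), n_sensors)
            for i in range(n_subjects)
        ]
        table = pd.concat(tables, ignore_index=True)
        means = cp.subject_sensor_z(table)
        a = means[means["condition"] == "configural"].pivot(index="subject", columns="sensor", values="z")
        b = means[means["condition"] == "nonconfigural"].pivot(index="subject", columns="sensor", values="z")
        diffs = (a - b).reindex(columns=range(n_sensors)).fillna(0.0).to_numpy()
        clusters = cp.cluster_permutation(diffs, adjacency, n_perm=n_perm, seed=seed + rep)
        false_positives += any(c.p_value < 0.05 for c in clusters)
    return false_positives / n_reps


def feature_selection_type1_study(
    seed: int,
    n_reps: int = 200,
    n_sensors: int = 64,
) -> float:
    """Type-I rate of the paired-t feature selection on pure-noise
    features with identical class distributions (nominal alpha 0.05)."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    n_bins = n_sensors * 38
    selected, total = 0, 0
    for _ in range(n_reps):
        indoor = rng.standard_normal((20, n_bins))
        outdoor = rng.standard_normal((20, n_bins))
        _, p = stats.ttest_rel(indoor, outdoor, axis=0)
        selected += int((p < 0.05).sum())
        total += n_bins
    return selected / total


def behavior_recovery_study(
    seed: int,
    n_subjects: int = 8,
    slope: float = 0.03,
) -> dict:
    """Correlation between subject coupling concentration and behavioral
    accuracy when the generator ties them linearly (events-only path)."""
    from scipy import stats

    params = synth.GeneratorParams(
        n_subjects=n_subjects, kappa_subject_range=(0.3, 1.7),
        behavior_slope=slope, behavior_noise_sd=0.02, rng_seed=seed,
    )
    factors = synth.subject_kappa_factors(params)
    kappas, accs = [], []
    for i in range(n_subjects):
        gt = synth.generate_ground_truth(params, i, kappa_factor=float(factors[i]))
        kappas.append(gt.kappa_used["configural"])
        accs.append(gt.behavioral_accuracy["configural"])
    r, p = stats.pearsonr(kappas, accs)
    return {"r": float(r), "p": float(p), "slope": slope}
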