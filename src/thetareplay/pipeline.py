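"""End-to-end orchestration: simulate -> time-frequency -> decode ->
reactivation detection -> theta coupling, with per-stage persisted
artifacts so any stage can be re-run from the previous checkpoint.

Stage artifacts live under ``<outdir>/``:

* ``subjects/epochs_<i>.h5`` (+ JSON/TSV sidecars), ``subjects/gt_<i>.json``
* ``tfr/tfr_<i>_<condition>.h5``, ``tfr/phase_<i>_<freq>.h5``
* ``decode/records_<i>.csv``, ``decode/loocv.csv``
* ``replay/times.csv``, ``replay/events.csv``, ``replay/counts.csv``,
  ``replay/contrasts.json``
* ``coupling/plv.csv``, ``coupling/contrast_<freq>.csv``,
  ``coupling/clusters.json``, ``coupling/behavior.json``
* ``report.json``

All randomness derives from the run seed; regenerating with the same
config yields identical tables.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as cp
from . import decode, io, replay, synth, timefreq
from .config import PipelineConfig, _plain
from .containers import CONDITIONS, MAINTENANCE_WINDOW

log = logging.getLogger("thetareplay")


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def _needed_times(cfg: PipelineConfig) -> np.ndarray:
    base = np.arange(cfg.wavelet.baseline[0], cfg.wavelet.baseline[1] + 1e-9, 4.0)
    test = decode.maintenance_test_points(cfg.classifier.n_test_points)
    return np.unique(np.r_[base, np.asarray(cfg.classifier.training_times), test])


def _maintenance_grid() -> np.ndarray:
    return np.arange(MAINTENANCE_WINDOW[0], MAINTENANCE_WINDOW[1] - 1e-9, 4.0)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    gen = replace(cfg.generator, rng_seed=cfg.seed)
    sub = outdir / "subjects"
    sub.mkdir(parents=True, exist_ok=True)
    factors = synth.subject_kappa_factors(gen)
    n_events = 0
    for i in range(gen.n_subjects):
        epochs, gt = synth.generate_subject(gen, i, kappa_factor=float(factors[i]))
        io.write_epochs(epochs, sub / f"epochs_{i}.h5")
        io.write_ground_truth(gt, sub / f"gt_{i}.json")
        n_events += int(sum(len(t) for t in gt.event_times))
    return {"n_subjects": gen.n_subjects, "planted_events": n_events}


def stage_tfr(cfg: PipelineConfig, outdir: Path) -> dict:
    tdir = outdir / "tfr"
    tdir.mkdir(parents=True, exist_ok=True)
    spec = timefreq.WaveletSpec(ratio=cfg.wavelet.ratio)
    band = spec.freqs[timefreq.feature_band_mask(spec.freqs)]
    times = _needed_times(cfg)
    n_files = 0
    for i in range(cfg.generator.n_subjects):
        epochs = io.read_epochs(outdir / "subjects" / f"epochs_{i}.h5")
        for cond in CONDITIONS:
            idx = np.flatnonzero(epochs.metadata["condition"] == cond)
            sub = epochs.select_trials(idx)
            tf = timefreq.cwt_amplitude(sub, spec, freqs=band, times=times)
            tf = timefreq.baseline_normalize(tf, cfg.wavelet.baseline)
            io.write_tfr(tf, tdir / f"tfr_{i}_{cond}.h5")
            n_files += 1
        hp = timefreq.zero_phase_highpass(epochs, cfg.coupling.highpass_hz)
        for f in cfg.coupling.theta_freqs:
            ph = timefreq.instantaneous_phase(hp, f, spec, times=_maintenance_grid())
            io.write_phase(ph, tdir / f"phase_{i}_{int(f)}.h5")
    return {"tfr_files": n_files, "feature_freqs": len(band)}


def stage_decode(cfg: PipelineConfig, outdir: Path) -> dict:
    ddir = outdir / "decode"
    ddir.mkdir(parents=True, exist_ok=True)
    test_points = decode.maintenance_test_points(cfg.classifier.n_test_points)
    loocv_rows = []
    for i in range(cfg.generator.n_subjects):
        epochs_meta = io.read_epochs(outdir / "subjects" / f"epochs_{i}.h5").metadata
        tfs, labels, gidx = {}, {}, {}
        for cond in CONDITIONS:
            idx = np.flatnonzero(epochs_meta["condition"] == cond)
            tfs[cond] = io.read_tfr(outdir / "tfr" / f"tfr_{i}_{cond}.h5")
            labels[cond] = epochs_meta.iloc[idx].reset_index(drop=True)
            gidx[cond] = idx
        rec_frames = []
        for cond in CONDITIONS:
            for tp in cfg.classifier.loocv_times:
                acc = decode.loocv_accuracy(
                    tfs[cond], tp, labels[cond], cfg.classifier.alpha,
                    seed=cfg.seed + i, condition=cond,
                )
                loocv_rows.append((i, cond, tp, acc))
            for tp in cfg.classifier.training_times:
                try:
                    mask = decode.select_features(
                        tfs[cond], tp, labels[cond], cfg.classifier.alpha, cond
                    )
                except decode.EmptyMaskError:
                    log.warning("subject %d cond %s t=%s: empty mask", i, cond, tp)
                    continue
                clf = decode.train_classifier(tfs[cond], mask, labels[cond], seed=cfg.seed + i)
                tested = CONDITIONS if cfg.classifier.cross_condition else (cond,)
                for test_cond in tested:
                    rec = decode.classify_maintenance(
                        clf, tfs[test_cond], labels[test_cond], test_points,
                        threshold=cfg.classifier.output_threshold,
                    )
                    rec["trial"] = gidx[test_cond][rec["trial"].to_numpy()]
                    rec.insert(0, "subject", i)
                    rec.insert(1, "condition_trained", cond)
                    rec.insert(2, "condition_tested", test_cond)
                    rec.insert(3, "classifier_time", tp)
                    rec_frames.append(rec)
        pd.concat(rec_frames, ignore_index=True).to_csv(ddir / f"records_{i}.csv", index=False)
    loocv = pd.DataFrame(loocv_rows, columns=["subject", "condition", "time_point", "accuracy"])
    loocv.to_csv(ddir / "loocv.csv", index=False)
    return {
        "loocv_mean": {
            f"{tp:g}ms": float(loocv[loocv["time_point"] == tp]["accuracy"].mean())
            for tp in cfg.classifier.loocv_times
        }
    }


def stage_replay(cfg: PipelineConfig, outdir: Path) -> dict:
    rdir = outdir / "replay"
    rdir.mkdir(parents=True, exist_ok=True)
    spec = replay.BinomialTestSpec(
        cfg.replay.n, cfg.replay.chance, cfg.replay.family_size, cfg.replay.family_alpha
    )
    all_times, all_events, count_rows = [], [], []
    for i in range(cfg.generator.n_subjects):
        rec = pd.read_csv(outdir / "decode" / f"records_{i}.csv")
        sets = []
        for (ct, cx, tp), grp in rec.groupby(
            ["condition_trained", "condition_tested", "classifier_time"], observed=True
        ):
            rs = replay.detect_reactivations(
                grp, spec, classifier_time=float(tp),
                condition_trained=ct, condition_tested=cx,
            )
            sets.append(rs)
        combined = replay.combine(sets)
        combined.times.insert(0, "subject", i)
        combined.events.insert(0, "subject", i)
        all_times.append(combined.times)
        all_events.append(combined.events)
        for ct in CONDITIONS:
            for cx in CONDITIONS:
                n = int(
                    (
                        (combined.times["condition_trained"] == ct)
                        & (combined.times["condition_tested"] == cx)
                    ).sum()
                )
                count_rows.append((i, ct, cx, n))
    times = pd.concat(all_times, ignore_index=True)
    events = pd.concat(all_events, ignore_index=True)
    counts = pd.DataFrame(
        count_rows, columns=["subject", "condition_trained", "condition_tested", "count"]
    )
    times.to_csv(rdir / "times.csv", index=False)
    events.to_csv(rdir / "events.csv", index=False)
    counts.to_csv(rdir / "counts.csv", index=False)

    within = counts[counts["condition_trained"] == counts["condition_tested"]]
    pivot = within.pivot(index="subject", columns="condition_trained", values="count")
    contrasts = {}
    for a, b in [
        ("configural", "nonconfigural"),
        ("configural", "control"),
        ("nonconfigural", "control"),
    ]:
        try:
            t, p = replay.compare_counts(pivot[a].to_numpy(), pivot[b].to_numpy())
            contrasts[f"{a}_gt_{b}"] = {"t": t, "p": p}
        except ValueError as e:
            contrasts[f"{a}_gt_{b}"] = {"error": str(e)}
    (rdir / "contrasts.json").write_text(json.dumps(contrasts, indent=2))
    return {
        "total_reactivation_times": int(len(times)),
        "within_condition_counts": {
            c: float(pivot[c].mean()) for c in pivot.columns
        },
        "contrasts": contrasts,
    }


def stage_coupling(cfg: PipelineConfig, outdir: Path) -> dict:
    cdir = outdir / "coupling"
    cdir.mkdir(parents=True, exist_ok=True)
    events = pd.read_csv(outdir / "replay" / "events.csv")
    lo, hi = replay.MERGE_CLASSIFIER_WINDOW
    merged = events[
        (events["condition_trained"] == events["condition_tested"])
        & (events["classifier_time"] >= lo)
        & (events["classifier_time"] <= hi)
    ][["subject", "condition_tested", "trial", "time"]].drop_duplicates()

    tables = []
    behaviors = []
    for i in range(cfg.generator.n_subjects):
        meta = io.read_epochs(outdir / "subjects" / f"epochs_{i}.h5").metadata
        gt = io.read_ground_truth(outdir / "subjects" / f"gt_{i}.json")
        behaviors.append(gt.behavioral_accuracy["configural"])
        ev_i = merged[merged["subject"] == i]
        if ev_i.empty:
            continue
        for f in cfg.coupling.theta_freqs:
            ph = io.read_phase(outdir / "tfr" / f"phase_{i}_{int(f)}.h5")
            tab = cp.build_plv_table(ev_i, ph, meta, i, cfg.coupling.min_events)
            tables.append(tab)
    tables = [t for t in tables if not t.empty]
    summary: dict = {"contrast": {}, "clusters": {}}
    if tables:
        plv_table = pd.concat(tables, ignore_index=True)
        plv_table.to_csv(cdir / "plv.csv", index=False)
        a, b = cfg.coupling.contrast
        layout = io.read_epochs(outdir / "subjects" / "epochs_0.h5").layout
        adjacency = layout.adjacency()
        for f in cfg.coupling.theta_freqs:
            tab_f = plv_table[plv_table["freq"] == f]
            try:
                contrast = cp.coupling_contrast(tab_f, a, b)
            except ValueError as e:
                summary["contrast"][f"{f:g}Hz"] = {"error": str(e)}
                continue
            contrast.to_csv(cdir / f"contrast_{int(f)}.csv", index=False)
            summary["contrast"][f"{f:g}Hz"] = {
                "max_t": float(contrast["t"].max()),
                "n_sig_sensors": int((contrast["p"] < 0.05).sum()),
            }
            if f == cfg.coupling.headline_freq:
                means = cp.subject_sensor_z(tab_f)
                pa = means[means["condition"] == a].pivot(index="subject", columns="sensor", values="z")
                pb = means[means["condition"] == b].pivot(index="subject", columns="sensor", values="z")
                common = pa.index.intersection(pb.index)
                full = np.zeros((len(common), layout.n_sensors))
                da = pa.loc[common].reindex(columns=range(layout.n_sensors)).to_numpy()
                db = pb.loc[common].reindex(columns=range(layout.n_sensors)).to_numpy()
                diffs = np.nan_to_num(da) - np.nan_to_num(db) + full
                if len(common) >= 2:
                    clusters = cp.cluster_permutation(
                        diffs, adjacency, cfg.coupling.n_perm_cluster,
                        cfg.coupling.min_cluster_size, seed=cfg.seed,
                    )
                    summary["clusters"][f"{f:g}Hz"] = [
                        {"n_sensors": int(len(c.sensors)), "mass": c.stat, "p": c.p_value, "direction": c.direction}
                        for c in clusters
                    ]
                    (cdir / "clusters.json").write_text(
                        json.dumps(summary["clusters"], indent=2)
                    )
        # behavior correlation at the headline frequency, contrast condition A
        tab_h = plv_table[plv_table["freq"] == cfg.coupling.headline_freq]
        means = cp.subject_sensor_z(tab_h)
        za = means[means["condition"] == a].pivot(index="subject", columns="sensor", values="z")
        za = za.reindex(columns=range(layout.n_sensors))
        acc = np.asarray([behaviors[int(s)] for s in za.index])
        try:
            rtab, rclusters = cp.behavior_correlation(
                np.nan_to_num(za.to_numpy()), acc, adjacency,
                min_cluster=cfg.coupling.min_cluster_size,
            )
            rtab.to_csv(cdir / "behavior_r.csv", index=False)
            summary["behavior"] = {
                "max_r": float(rtab["r"].max()),
                "n_flagged": int(rtab["flagged"].sum()),
                "n_clusters": len(rclusters),
            }
        except ValueError as e:
            summary["behavior"] = {"error": str(e)}
    else:
        summary["note"] = "no trials with enough reactivation events for PLV"
    return summary


STAGES = [
    ("simulate", stage_simulate),
    ("tfr", stage_tfr),
    ("decode", stage_decode),
    ("replay", stage_replay),
    ("coupling", stage_coupling),
]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run report."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.verbosity, logging.INFO))
    report: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": _plain(cfg.to_dict()),
        "stages": {},
    }
    for name, fn in STAGES:
        t0 = time.perf_counter()
        try:
            summary = fn(cfg, outdir)
        except Exception as e:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, type(e).__name__, str(e)) from e
        wall = time.perf_counter() - t0
        log.info("stage %s done in %.1f s", name, wall)
        report["stages"][name] = {"summary": summary, "wall_s": round(wall, 2)}
    report["artifacts"] = {
        str(p.relative_to(outdir)): _checksum(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "report.json"
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report
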