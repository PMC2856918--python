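"""Persistence: chunked HDF5 array containers with JSON sidecars.

Epochs, TF amplitude and phase stores are HDF5 files with chunked
datasets; trial metadata and scalar attributes travel in a JSON sidecar
(`<file>.json`), and sensor layouts are tab-separated text
(sensor id, x, y).  Round trips are lossless for signal, time axis,
metadata and layout.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet, PhaseSeries, SchemaError, SensorLayout, TFRepresentation
from .synth import GroundTruth


def write_layout(layout: SensorLayout, path: str | Path) -> None:
    df = pd.DataFrame(
        {"sensor": layout.ids, "x": layout.pos[:, 0], "y": layout.pos[:, 1]}
    )
    with open(path, "w") as fh:
        fh.write(f"# adjacency={layout.adjacency_kind} knn_k={layout.knn_k}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_layout(path: str | Path) -> SensorLayout:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh, sep="\t")
    kind, k = "grid", 6
    if header.startswith("#"):
        for tok in header[1:].split():
            key, _, val = tok.partition("=")
            if key == "adjacency":
                kind = val
            elif key == "knn_k":
                k = int(val)
    for col in ("sensor", "x", "y"):
        if col not in df.columns:
            raise SchemaError(f"layout file missing column {col!r}")
    return SensorLayout(
        [str(s) for s in df["sensor"]], df[["x", "y"]].to_numpy(float),
        adjacency_kind=kind, knn_k=k,
    )


def _sidecar(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "signal", data=epochs.signal,
            chunks=(1, epochs.n_sensors, epochs.signal.shape[2]),
        )
        f.create_dataset("times", data=epochs.times)
    meta = {
        "sfreq": epochs.sfreq,
        "metadata": epochs.metadata.to_dict(orient="list"),
        "layout_file": path.stem + ".layout.tsv",
    }
    _sidecar(path).write_text(json.dumps(meta))
    write_layout(epochs.layout, path.with_name(meta["layout_file"]))


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise SchemaError(f"missing sidecar {side.name}")
    meta = json.loads(side.read_text())
    for field in ("sfreq", "metadata", "layout_file"):
        if field not in meta:
            raise SchemaError(f"sidecar missing field {field!r}")
    try:
        with h5py.File(path, "r") as f:
            if "signal" not in f or "times" not in f:
                raise SchemaError("epoch container missing signal/times datasets")
            signal = f["signal"][()]
            times = f["times"][()]
    except OSError as e:
        raise SchemaError(f"unreadable epoch container: {e}") from e
    layout = read_layout(path.with_name(meta["layout_file"]))
    return EpochSet(signal, times, float(meta["sfreq"]), pd.DataFrame(meta["metadata"]), layout)


def write_tfr(tf: TFRepresentation, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "amplitude", data=tf.amplitude,
            chunks=(1,) + tf.amplitude.shape[1:],
        )
        f.create_dataset("freqs", data=tf.freqs)
        f.create_dataset("times", data=tf.times)
        if tf.baseline is not None:
            f.attrs["baseline"] = tf.baseline


def read_tfr(path: str | Path) -> TFRepresentation:
    try:
        with h5py.File(path, "r") as f:
            baseline = tuple(f.attrs["baseline"]) if "baseline" in f.attrs else None
            return TFRepresentation(f["amplitude"][()], f["freqs"][()], f["times"][()], baseline=baseline)
    except OSError as e:
        raise SchemaError(f"unreadable TF container: {e}") from e


def write_phase(ph: PhaseSeries, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("phase", data=ph.phase, chunks=(1,) + ph.phase.shape[1:])
        f.create_dataset("times", data=ph.times)
        f.attrs["freq"] = ph.freq
        f.attrs["sfreq"] = ph.sfreq


def read_phase(path: str | Path) -> PhaseSeries:
    try:
        with h5py.File(path, "r") as f:
            return PhaseSeries(
                f["phase"][()], float(f.attrs["freq"]), f["times"][()], float(f.attrs["sfreq"])
            )
    except OSError as e:
        raise SchemaError(f"unreadable phase container: {e}") from e


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    doc = {
        "subject": gt.subject,
        "event_times": [t.tolist() for t in gt.event_times],
        "event_phases": [p.tolist() for p in gt.event_phases],
        "metadata": gt.metadata.to_dict(orient="list"),
        "theta_freq": gt.theta_freq,
        "cluster_of_sensor": gt.cluster_of_sensor.tolist(),
        "coupling_clusters": gt.coupling_clusters,
        "theta_offset": gt.theta_offset.tolist(),
        "theta_detune": gt.theta_detune.tolist(),
        "kappa_used": gt.kappa_used,
        "behavioral_accuracy": gt.behavioral_accuracy,
    }
    Path(path).write_text(json.dumps(doc))


def read_ground_truth(path: str | Path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    return GroundTruth(
        subject=int(doc["subject"]),
        event_times=[np.asarray(t, dtype=float) for t in doc["event_times"]],
        event_phases=[np.asarray(p, dtype=float) for p in doc["event_phases"]],
        metadata=pd.DataFrame(doc["metadata"]),
        theta_freq=float(doc["theta_freq"]),
        cluster_of_sensor=np.asarray(doc["cluster_of_sensor"], dtype=int),
        coupling_clusters={k: int(v) for k, v in doc["coupling_clusters"].items()},
        theta_offset=np.asarray(doc["theta_offset"], dtype=float),
        theta_detune=np.asarray(doc["theta_detune"], dtype=float),
        kappa_used={k: float(v) for k, v in doc["kappa_used"].items()},
        behavioral_accuracy={k: float(v) for k, v in doc["behavioral_accuracy"].items()},
    )
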