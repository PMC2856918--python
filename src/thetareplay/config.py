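"""Pipeline configuration: schema-validated blocks with the analysis
constants as defaults (7-cycle wavelets, 0.95 output threshold, 20 hidden
units, 20 training iterations, 0.05/(250 x 11) corrected threshold, 3 Hz
zero-phase high-pass, 4/5/6 Hz theta, minimum 8 adjacent sensors)."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synth import GeneratorParams


@dataclass
class WaveletConfig:
    ratio: float = 7.0
    baseline: tuple[float, float] = (-500.0, -100.0)
    downsample_to: float = 250.0


@dataclass
class ClassifierConfig:
    alpha: float = 0.05
    n_hidden: int = 20
    n_iterations: int = 20
    output_threshold: float = 0.95
    training_times: tuple[float, ...] = tuple(float(t) for t in range(-36, 765, 80))
    n_test_points: int = 250
    loocv_times: tuple[float, ...] = (-36.0,)
    cross_condition: bool = True


@dataclass
class ReplayConfig:
    n: int = 20
    chance: float = 0.5
    family_size: int = 250 * 11
    family_alpha: float = 0.05


@dataclass
class CouplingConfig:
    highpass_hz: float = 3.0
    theta_freqs: tuple[float, ...] = (4.0, 5.0, 6.0)
    headline_freq: float = 6.0
    min_events: int = 2
    min_cluster_size: int = 8
    n_perm_cluster: int = 1000
    n_perm_within: int = 500
    contrast: tuple[str, str] = ("configural", "nonconfigural")


@dataclass
class PipelineConfig:
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    replay: ReplayConfig = field(default_factory=ReplayConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    seed: int = 0
    outdir: str = "results/pipeline"
    verbosity: str = "INFO"

    def validate(self) -> None:
        if self.classifier.n_hidden != 20 or self.classifier.n_iterations != 20:
            raise ValueError("classifier topology/iterations are fixed by design")
        if self.replay.family_size <= 0 or not 0 < self.replay.chance < 1:
            raise ValueError("invalid replay test spec")
        if self.coupling.headline_freq not in self.coupling.theta_freqs:
            raise ValueError("headline theta frequency missing from theta_freqs")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        cfg = cls(
            generator=GeneratorParams(**doc.get("generator", {})),
            wavelet=WaveletConfig(**_tup(doc.get("wavelet", {}), ["baseline"])),
            classifier=ClassifierConfig(
                **_tup(doc.get("classifier", {}), ["training_times", "loocv_times"])
            ),
            replay=ReplayConfig(**doc.get("replay", {})),
            coupling=CouplingConfig(
                **_tup(doc.get("coupling", {}), ["theta_freqs", "contrast"])
            ),
            seed=int(doc.get("seed", 0)),
            outdir=str(doc.get("outdir", "results/pipeline")),
            verbosity=str(doc.get("verbosity", "INFO")),
        )
        cfg.validate()
        return cfg

    @classmethod
    def desk_scale(cls, seed: int = 0, outdir: str = "results/analysis") -> "PipelineConfig":
        """Desk-scale study configuration used by the analysis drivers:
        the full 8-subject, 20+20-trial cohort on a 24-sensor grid, five
        classifier training times and 100 maintenance test points.  All
        statistical constants keep their reference values."""
        cfg = cls(
            generator=GeneratorParams(n_subjects=8, n_sensors=24, rng_seed=seed),
            seed=seed,
            outdir=outdir,
        )
        import dataclasses

        cfg.classifier = dataclasses.replace(
            cfg.classifier,
            training_times=(-36.0, 204.0, 364.0, 444.0, 604.0),
            loocv_times=(-36.0, 204.0, 364.0, 604.0),
            n_test_points=100,
        )
        cfg.coupling = dataclasses.replace(cfg.coupling, n_perm_cluster=1000)
        return cfg

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and
        logging verbosity excluded)."""
        doc = _plain(self.to_dict())
        doc.pop("outdir", None)
        doc.pop("verbosity", None)
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _tup(block: dict, keys: list[str]) -> dict:
    out = dict(block)
    for k in keys:
        if k in out and isinstance(out[k], list):
            out[k] = tuple(out[k])
    return out


def _plain(obj):
    """JSON/YAML-safe copy (tuples -> lists, numpy scalars -> python)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
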