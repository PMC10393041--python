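"""Run configuration: defaults, YAML loading, validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .model import HETERConfig
from .synthetic import CohortSpec
from .training import TrainSpec

__all__ = ["RunConfig", "load_config", "validate_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs, resolvable from a single YAML."""

    workdir: str = "runs/default"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    cohort_csv: str | None = None  # pre-existing cohort; skips simulation
    alignment_method: str = "ssr"
    horizon_minutes: int = 15
    resolution_minutes: int = 15
    test_points: int = 144
    stride: int = 1
    model: HETERConfig = field(default_factory=HETERConfig)
    train: TrainSpec = field(default_factory=TrainSpec)
    dtw_band: int | None = None
    seed: int = 0

    # -- derived paths ------------------------------------------------------

    @property
    def paths(self) -> dict[str, Path]:
        base = Path(self.workdir)
        return {
            "cohort": Path(self.cohort_csv) if self.cohort_csv else base / "cohort.csv",
            "aligned": base / "aligned",
            "graph": base / "graph",
            "checkpoint": base / "model.npz",
            "results": base / "results.csv",
        }

    @property
    def horizon_steps(self) -> int:
        return self.horizon_minutes // self.resolution_minutes

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of invariant violations (empty means valid)."""
    errors: list[str] = []
    if config.horizon_minutes % config.resolution_minutes != 0:
        errors.append(
            f"horizon {config.horizon_minutes} min not divisible by "
            f"resolution {config.resolution_minutes} min"
        )
    elif config.horizon_minutes // config.resolution_minutes < 1:
        errors.append("horizon must be at least one resolution step")
    if config.alignment_method not in ("ssr", "pad", "tra"):
        errors.append(f"unknown alignment method {config.alignment_method!r}")
    if config.test_points < 0:
        errors.append("test_points must be >= 0")
    if config.stride < 1:
        errors.append("stride must be >= 1")
    if config.cohort_csv is not None and not Path(config.cohort_csv).exists():
        errors.append(f"cohort_csv does not exist: {config.cohort_csv}")
    n_records = config.cohort.n_t1dm + config.cohort.n_t2dm
    if config.cohort_csv is None and config.model.k >= n_records:
        errors.append(f"K={config.model.k} must be < cohort size {n_records}")
    return errors


def _build(section_cls, data: dict):
    try:
        return section_cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid {section_cls.__name__} section: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run configuration, filling defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    kwargs = dict(raw)
    if "cohort" in kwargs:
        kwargs["cohort"] = _build(CohortSpec, kwargs["cohort"])
    if "model" in kwargs:
        model = dict(kwargs["model"])
        if "length_range" in model:  # defensive: common copy/paste slip
            raise ValueError("length_range belongs in the cohort section")
        kwargs["model"] = _build(HETERConfig, model)
    if "train" in kwargs:
        kwargs["train"] = _build(TrainSpec, kwargs["train"])
    config = RunConfig(**kwargs)
    return config


def save_config(config: RunConfig, path) -> None:
    data = config.to_dict()
    # YAML round-trips tuples as lists; normalize for equality on reload
    data["cohort"]["length_range"] = list(data["cohort"]["length_range"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Hash of the scientific configuration; artifact paths are excluded so
    the same run in two workdirs produces identical artifacts."""
    data = config.to_dict()
    data.pop("workdir", None)
    data.pop("cohort_csv", None)
    payload = json.dumps(data, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
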