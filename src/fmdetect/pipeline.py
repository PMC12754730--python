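"""Configuration loading, run manifests and experiment orchestration.

A single YAML/JSON document configures every stage, one section per config
type (``session``, ``noise``, ``filter``, ``spectral``, ``experiment``),
plus top-level ``n_scans`` and ``seed``.  Missing fields fall back to the
documented defaults (logged); unknown fields raise a configuration error
naming the offending path.  Every output directory receives a manifest
(config snapshot, seed, input hashes, software version) sufficient to
reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .errors import ConfigurationError
from .evaluate import ExperimentConfig
from .features import SpectralConfig
from .preprocess import FilterConfig, NoiseCancelConfig
from .synthgen import SessionConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Top-level configuration for simulate/run/search commands."""

    session: SessionConfig = field(default_factory=SessionConfig)
    noise: NoiseCancelConfig = field(default_factory=NoiseCancelConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    model_inputs: list[int] = field(default_factory=lambda: [1, 2, 3])
    n_scans: int = 3
    seed: int = 0

    def experiment_for(self, model_input: int, classifier: str | None = None,
                       seed: int | None = None) -> ExperimentConfig:
        exp = dataclasses.replace(
            self.experiment,
            model_input=model_input,
            noise_cfg=self.noise,
            filter_cfg=self.filter,
            spectral_cfg=self.spectral,
        )
        if classifier:
            exp = dataclasses.replace(exp, classifier=classifier)
        if seed is not None:
            exp = dataclasses.replace(exp, seed=seed)
        return exp


def _build_section(cls, data: dict, path: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in valid:
            raise ConfigurationError(f"{path}.{key}: unknown field")
    missing = valid - set(data)
    if missing:
        logger.info("%s: using defaults for %s", path, ", ".join(sorted(missing)))
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value) if key not in ("mpm_press_s",) else value
        coerced[key] = value
    return cls(**coerced)


_SECTIONS = {
    "session": SessionConfig,
    "noise": NoiseCancelConfig,
    "filter": FilterConfig,
    "spectral": SpectralConfig,
    "experiment": ExperimentConfig,
}


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON config file; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    kwargs: dict[str, Any] = {}
    for name, value in raw.items():
        if name in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigurationError(f"{name}: expected a mapping")
            if name == "experiment" and "classifier_params" in value:
                value = dict(value)
                value["classifier_params"] = dict(value["classifier_params"] or {})
            kwargs[name] = _build_section(_SECTIONS[name], value, name)
        elif name in ("n_scans", "seed"):
            kwargs[name] = int(value)
        elif name == "model_inputs":
            kwargs[name] = [int(v) for v in value]
        else:
            raise ConfigurationError(f"{name}: unknown config section")
    return RunConfig(**kwargs)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce an output directory exactly."""

    command: str
    seed: int
    config: dict
    version: str = __version__
    created_utc: str = ""
    input_hashes: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def save(self, directory: str | Path) -> Path:
        path = Path(directory) / "manifest.json"
        payload = dataclasses.asdict(self)
        path.write_text(json.dumps(payload, indent=1, default=str))
        return path


def build_manifest(command: str, config: RunConfig, seed: int,
                   inputs: list[Path] = (), outputs: list[Path] = ()) -> RunManifest:
    return RunManifest(
        command=command,
        seed=seed,
        config=_jsonable(config),
        created_utc=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        input_hashes={str(p): sha256_of(p) for p in inputs},
        outputs=[str(p) for p in outputs],
    )


def scan_seed(base_seed: int, index: int) -> int:
    """Per-scan seed derived from the run seed; stable across runs."""
    import numpy as np

    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2 ** 31))
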