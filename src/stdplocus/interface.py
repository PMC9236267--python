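"""Configuration files, result tables and run manifests.

Configurations are plain YAML (or JSON, a YAML subset) mapping directly onto
:class:`~stdplocus.experiments.ExperimentConfig` fields; unknown keys are
rejected and out-of-range values raise a validation error naming the field.
Results are written as headered CSV tables (long format for trajectories,
full float precision) plus a ``manifest.json`` recording the config echo,
package version, seeds and the emitted file inventory — enough to reproduce
the run bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .experiments import ExperimentConfig, ExperimentResult

__all__ = ["load_config", "save_config", "write_results", "RunManifest"]

log = logging.getLogger("stdplocus")

_FIELDS = {f.name for f in dataclasses.fields(ExperimentConfig)}
_TUPLE_FIELDS = {"c_grid", "rate_grid"}


def load_config(path) -> ExperimentConfig:
    """Read and validate an experiment configuration from YAML/JSON."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    for key in _TUPLE_FIELDS & set(raw):
        raw[key] = tuple(raw[key])
    try:
        return ExperimentConfig(**raw)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: {exc}") from exc


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


@dataclasses.dataclass
class RunManifest:
    config: dict
    version: str
    base_seed: object
    files: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def write_results(result: ExperimentResult, out_dir) -> RunManifest:
    """Emit metrics.csv, weights.csv, post_spikes.csv, config_used.yaml and
    manifest.json into ``out_dir`` (created if needed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    _write_csv(result.metrics, out / "metrics.csv")
    files.append("metrics.csv")
    weights = result.weights if not result.weights.empty else pd.DataFrame(
        columns=["time_ms", "synapse", "P", "q", "W"])
    _write_csv(weights, out / "weights.csv")
    files.append("weights.csv")

    rows = []
    for trial, train in enumerate(result.post_spikes):
        for t in np.asarray(train.times):
            rows.append((trial, t))
    _write_csv(pd.DataFrame(rows, columns=["trial", "time_ms"]),
               out / "post_spikes.csv")
    files.append("post_spikes.csv")

    save_config(result.config, out / "config_used.yaml")
    files.append("config_used.yaml")

    manifest = RunManifest(config=result.config.to_dict(), version=__version__,
                           base_seed=result.seed, files=sorted(files))
    (out / "manifest.json").write_text(manifest.to_json())
    log.info("wrote %d result files to %s (seed=%s)",
             len(files) + 1, out, result.seed)
    return manifest
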