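"""Run configuration, validation and result output.

A run config is a YAML/JSON mapping with blocks::

    model: mass | ei | network | field1d | field2d
    params: {...}        # typed per model (MassParams, EIParams, ...)
    experiment: {...}    # stimulus / initial condition / sweep spec
    numerics: {dt, T, save_every, ...}
    seed: 0
    outdir: runs/example

Unknown keys are rejected with a nearest-key suggestion; the fully resolved
config (defaults filled) is echoed next to every run's outputs, and the
manifest records a hash of it for provenance.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .params import EIParams, FieldParams, MassParams, NetworkParams

__all__ = ["RunConfig", "load_config", "resolve_config", "write_results", "ConfigError"]


class ConfigError(ValueError):
    """Raised on schema violations, naming the offending key."""


_MODEL_PARAMS = {
    "mass": MassParams,
    "ei": EIParams,
    "network": NetworkParams,
    "field1d": FieldParams,
    "field2d": FieldParams,
}


@dataclass
class RunConfig:
    model: str
    params: object
    experiment: dict = field(default_factory=dict)
    numerics: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "runs/out"

    def resolved(self) -> dict:
        """Plain-dict form with all parameter defaults filled in."""
        pdict = dataclasses.asdict(self.params)
        if self.model in ("field1d", "field2d"):
            mass = pdict.pop("mass")
            pdict = {**mass, **pdict}
        return {
            "model": self.model,
            "params": pdict,
            "experiment": dict(self.experiment),
            "numerics": dict(self.numerics),
            "seed": self.seed,
            "outdir": str(self.outdir),
        }

    def hash(self) -> str:
        canon = json.dumps(self.resolved(), sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _check_keys(given: dict, allowed, context: str) -> None:
    for key in given:
        if key not in allowed:
            hint = difflib.get_close_matches(key, list(allowed), n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown key {key!r} in {context}{suffix}")


def _build_params(model: str, raw: dict):
    cls = _MODEL_PARAMS[model]
    if model in ("field1d", "field2d"):
        mass_fields = {f.name for f in dataclasses.fields(MassParams)}
        field_fields = {f.name for f in dataclasses.fields(FieldParams)} - {"mass", "dim"}
        _check_keys(raw, mass_fields | field_fields, "params")
        mass = MassParams(**{k: v for k, v in raw.items() if k in mass_fields})
        extra = {k: v for k, v in raw.items() if k in field_fields}
        return FieldParams(mass=mass, dim=1 if model == "field1d" else 2, **extra)
    names = {f.name for f in dataclasses.fields(cls)}
    _check_keys(raw, names, "params")
    return cls(**raw)


def resolve_config(data: dict, overrides: dict | None = None) -> RunConfig:
    """Validate a raw mapping (defaults < file < overrides) into a RunConfig."""
    _check_keys(data, {"model", "params", "experiment", "numerics", "seed", "outdir"},
                "config")
    merged = dict(data)
    for k, v in (overrides or {}).items():
        if k in ("model", "seed", "outdir"):
            merged[k] = v
        else:
            merged.setdefault("params", {})
            merged["params"] = {**merged.get("params", {}), k: v}
    model = merged.get("model")
    if model not in _MODEL_PARAMS:
        raise ConfigError(
            f"model must be one of {sorted(_MODEL_PARAMS)}, got {model!r}")
    params = _build_params(model, merged.get("params") or {})
    return RunConfig(
        model=model,
        params=params,
        experiment=merged.get("experiment") or {},
        numerics=merged.get("numerics") or {},
        seed=int(merged.get("seed", 0)),
        outdir=merged.get("outdir", "runs/out"),
    )


def load_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return resolve_config(data, overrides)


def write_results(outputs: dict, outdir: str | Path, config: RunConfig | None = None,
                  t_start: float | None = None) -> dict:
    """Write run outputs and a JSON manifest; returns the manifest.

    DataFrames go to CSV, dicts of arrays to an HDF5 container with named
    datasets, plain dicts to JSON.  File naming is deterministic (the output
    key); the manifest records shapes, the config hash and wall time.
    """
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}, "complete": False}
    if config is not None:
        manifest["config_hash"] = config.hash()
        manifest["seed"] = config.seed
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(config.resolved(), fh, sort_keys=True)
    from . import __version__

    manifest["version"] = __version__
    try:
        for name, obj in outputs.items():
            if isinstance(obj, pd.DataFrame):
                path = outdir / f"{name}.csv"
                obj.to_csv(path, index=False, float_format="%.10g")
                manifest["files"][name] = {"path": path.name, "rows": len(obj)}
            elif isinstance(obj, dict) and all(isinstance(v, np.ndarray) for v in obj.values()):
                import h5py

                path = outdir / f"{name}.h5"
                with h5py.File(path, "w") as h5:
                    for key, arr in obj.items():
                        h5.create_dataset(key, data=arr)
                manifest["files"][name] = {
                    "path": path.name,
                    "dims": {k: list(v.shape) for k, v in obj.items()},
                }
            else:
                path = outdir / f"{name}.json"
                with open(path, "w") as fh:
                    json.dump(obj, fh, indent=2, default=float)
                manifest["files"][name] = {"path": path.name}
        manifest["complete"] = True
    finally:
        if t_start is not None:
            manifest["wall_time_s"] = round(time.time() - t_start, 3)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return manifest
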