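"""Layered run configuration and run manifests.

A :class:`RunConfig` is fully resolved (defaults < config file < CLI flags)
before anything runs; every experiment output is accompanied by a JSON
manifest recording the config hash, seeds and a digest of the results, so a
run can be reproduced bit-identically from its manifest alone
(single-threaded execution).

One global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``; stage order is fixed (cohort,
folds, training), so stages are independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["RunConfig", "resolve_config", "config_hash", "stage_seeds", "emit_manifest"]


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the pipeline, with its default."""

    montage: str = "physionet64"
    groups_file: str = ""  # empty -> builtin angular grouping
    n_groups: int = 8
    window_s: float = 1.0
    overlap: float = 0.5
    threshold_mode: str = "density"  # "density" | "fixed"
    threshold: float = 0.2
    virtual_weight: float = 1.0
    feature_dim: int = 32
    model: str = "vn_gcn"
    folds: int = 5
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 3e-3
    split_mode: str = "per-window"  # "per-window" | "per-block"
    seed: int = 7

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def resolve_config(
    defaults: "RunConfig | None" = None,
    file: "str | Path | dict | None" = None,
    flags: "dict | None" = None,
) -> RunConfig:
    """Merge settings with precedence flags > file > defaults.

    ``file`` may be a YAML/JSON path or an already-parsed mapping. Unknown
    keys and type mismatches are rejected.
    """
    base = (defaults or RunConfig()).to_dict()
    valid = set(base)

    def merge(source: dict, origin: str) -> None:
        for key, value in source.items():
            if key not in valid:
                raise KeyError(f"unknown config key {key!r} (from {origin})")
            want = type(base[key])
            if want is float and isinstance(value, int):
                value = float(value)
            if not isinstance(value, want):
                raise TypeError(
                    f"config key {key!r} expects {want.__name__}, got "
                    f"{type(value).__name__} (from {origin})"
                )
            base[key] = value

    if file is not None:
        if isinstance(file, dict):
            merge(file, "mapping")
        else:
            import yaml

            with open(file) as f:
                loaded = yaml.safe_load(f) or {}
            if not isinstance(loaded, dict):
                raise TypeError("config file must contain a mapping")
            merge(loaded, str(file))
    if flags:
        merge({k: v for k, v in flags.items() if v is not None}, "flags")
    return RunConfig(**base)


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 over the canonical JSON form of the config."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()


_STAGES = ("cohort", "folds", "training")


def stage_seeds(seed: int) -> dict:
    """Fan one global seed out to named per-stage seeds (< 2**31)."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def results_digest(results) -> str:
    """sha256 digest of a canonical JSON rendering of arbitrary results."""
    payload = json.dumps(results, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def emit_manifest(
    cfg: RunConfig,
    results=None,
    path: "str | Path | None" = None,
    status: str = "completed",
    extra: "dict | None" = None,
) -> dict:
    """Build (and optionally write) the JSON manifest of one run."""
    from . import __version__

    manifest = {
        "schema": "vnfc-manifest/1",
        "status": status,
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg),
        "stage_seeds": stage_seeds(cfg.seed),
        "results_digest": results_digest(results) if results is not None else None,
    }
    if extra:
        manifest["extra"] = extra
    if path is not None:
        with open(path, "w") as f:
            json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest


def validate_manifest(manifest: dict) -> None:
    """Check the fixed manifest schema; raises on violation."""
    required = {"schema", "status", "version", "config", "config_hash", "stage_seeds"}
    missing = required - set(manifest)
    if missing:
        raise ValueError(f"manifest missing keys: {sorted(missing)}")
    if manifest["schema"] != "vnfc-manifest/1":
        raise ValueError("unknown manifest schema")
    cfg = RunConfig(**manifest["config"])
    if config_hash(cfg) != manifest["config_hash"]:
        raise ValueError("config hash mismatch")
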