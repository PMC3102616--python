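"""Run configuration for the pipeline: YAML config files, seed fan-out,
and the run manifest written next to every output."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "load_config", "substream_seed", "write_manifest"]

#: top-level config keys; sections with a set restrict their subkeys,
#: None marks a free-form section (per-parameter priors, truth overrides)
_KNOWN_KEYS = {
    "seed": None,
    "out_dir": None,
    "dose_grid": None,
    "mcid": None,
    "mcmc": {"n_chains", "n_warmup", "n_draws", "target_acceptance"},
    "optimizer": {"n_starts", "maxiter"},
    "priors": None,
    "study_truth": None,
    "patient_truth": None,
}


@dataclass
class RunConfig:
    """Validated pipeline settings shared by all CLI stages."""

    seed: int = 0
    out_dir: str = "emaxdr_out"
    dose_grid: tuple = (18.75, 37.5, 75.0, 150.0, 300.0, 600.0)
    mcid: float = 120.0
    mcmc: dict = field(default_factory=dict)
    optimizer: dict = field(default_factory=dict)
    priors: dict = field(default_factory=dict)
    study_truth: dict = field(default_factory=dict)
    patient_truth: dict = field(default_factory=dict)

    def digest(self) -> str:
        """Stable short hash of the configuration contents."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML config; unknown keys raise with the full offending list."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    unknown = [k for k in raw if k not in _KNOWN_KEYS]
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in _KNOWN_KEYS.items():
        if isinstance(allowed, set) and section in raw:
            bad = [k for k in raw[section] if k not in allowed]
            if bad:
                raise ValueError(f"unknown config keys in {section!r}: {sorted(bad)}")
    if "dose_grid" in raw:
        raw["dose_grid"] = tuple(float(d) for d in raw["dose_grid"])
    return RunConfig(**raw)


def substream_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, fanned out from the master
    seed via named substreams (so stages are independent but reproducible)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def write_manifest(out_dir, stage: str, config: RunConfig, inputs: dict,
                   outputs: list) -> Path:
    """Write the machine-readable run manifest for one pipeline stage."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "stage_seed": substream_seed(config.seed, stage),
        "config_hash": config.digest(),
        "config": asdict(config),
        "inputs": inputs,
        "outputs": outputs,
        "software_version": __version__,
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
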