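"""Run configuration, seed management, and result bundles.

Configuration files are YAML mappings with one block per parameter
group (``neuron``, ``synapse``, ``plasticity``, ``external``,
``experiment``, ``tension``). Every parameter has a default -- an empty
file is a valid, fully specified run -- and unknown keys are rejected
with the offending name.

Seed policy: a single master seed deterministically derives every
stream seed as ``SeedSequence([master, crc32(label)])``; the label says
what the stream drives (e.g. ``replicate-0``, ``train``,
``recall-tension_1.5x``). Derived seeds are 31-bit.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .params import (ConfigurationError, ExternalDriveParams, NeuronParams,
                     PlasticityParams, SynapseParams, params_to_dict)


def derive_seed(master: int, label: str) -> int:
    """31-bit stream seed derived from the master seed and a label."""
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF,
                                 zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


@dataclass(frozen=True)
class RunConfig:
    """Validated merge of file overrides onto the model defaults."""

    neuron: NeuronParams = field(default_factory=NeuronParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    external: ExternalDriveParams = field(default_factory=ExternalDriveParams)
    experiment: dict = field(default_factory=dict)
    tension_segments_rel: tuple = ()   # (t_start, t_end, eps_rel)
    seed: int = 0

    def to_dict(self) -> dict:
        return {"neuron": params_to_dict(self.neuron),
                "synapse": params_to_dict(self.synapse),
                "plasticity": params_to_dict(self.plasticity),
                "external": params_to_dict(self.external),
                "experiment": dict(self.experiment),
                "tension": [list(s) for s in self.tension_segments_rel],
                "seed": self.seed}


_SECTIONS = {"neuron": NeuronParams, "synapse": SynapseParams,
             "plasticity": PlasticityParams, "external": ExternalDriveParams}


def _merge_section(cls, overrides: dict, section: str):
    valid = {f.name for f in fields(cls)}
    for key in overrides:
        if key not in valid:
            raise ConfigurationError(
                f"unknown key {section}.{key!r}; valid: {sorted(valid)}")
    try:
        return cls(**overrides)
    except TypeError as e:  # pragma: no cover - defensive
        raise ConfigurationError(str(e))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields the full defaults. Validation errors name the
    offending key.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("config root must be a mapping")
    from .experiments import ExperimentConfig
    known = set(_SECTIONS) | {"experiment", "tension", "seed"}
    for key in data:
        if key not in known:
            raise ConfigurationError(
                f"unknown section {key!r}; valid: {sorted(known)}")
    parts = {}
    for name, cls in _SECTIONS.items():
        parts[name] = _merge_section(cls, data.get(name) or {}, name)
    exp_over = data.get("experiment") or {}
    valid_exp = {f.name for f in fields(ExperimentConfig)}
    for key in exp_over:
        if key not in valid_exp:
            raise ConfigurationError(
                f"unknown key experiment.{key!r}; valid: {sorted(valid_exp)}")
    segs = tuple(tuple(s) for s in (data.get("tension") or []))
    for s in segs:
        if len(s) != 3:
            raise ConfigurationError(
                "tension segments must be [t_start, t_end, eps_rel]")
        if s[2] <= 0:
            raise ConfigurationError("tension.eps_rel must be positive")
    seed = int(data.get("seed", 0))
    return RunConfig(**parts, experiment=exp_over,
                     tension_segments_rel=segs, seed=seed)


# ---------------------------------------------------------------------------
# result bundle


class BundleError(RuntimeError):
    """Raised when a bundle fails its checksum verification."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_run_bundle(out_dir, spikes=None, weights=None, metrics=None,
                     config: Optional[RunConfig] = None) -> dict:
    """Write spikes (CSV), a weight snapshot (sparse triplet CSV),
    metrics (JSON) and a config echo, plus a checksum manifest.
    Returns the manifest."""
    import pandas as pd
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = {}
    if spikes is not None:
        p = out / "spikes.csv"
        spikes.write_csv(p)
        entries["spikes.csv"] = _sha256(p)
    if weights is not None:
        pre, post, w = weights
        p = out / "weights.csv"
        pd.DataFrame({"pre_id": pre, "post_id": post, "w": w}
                     ).to_csv(p, index=False)
        entries["weights.csv"] = _sha256(p)
    if metrics is not None:
        p = out / "metrics.json"
        p.write_text(json.dumps(metrics, indent=2, sort_keys=True))
        entries["metrics.json"] = _sha256(p)
    if config is not None:
        p = out / "config.yaml"
        p.write_text(yaml.safe_dump(config.to_dict()))
        entries["config.yaml"] = _sha256(p)
    manifest = {"files": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def read_run_bundle(out_dir) -> dict:
    """Re-read a bundle, verifying checksums; returns the in-memory
    structures (spikes as SpikeRecord, weights as arrays, metrics as
    dict)."""
    import pandas as pd
    from .dynamics import SpikeRecord
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    result = {}
    for name, digest in manifest["files"].items():
        p = out / name
        if not p.exists():
            raise BundleError(f"missing bundle file {name}")
        if _sha256(p) != digest:
            raise BundleError(f"checksum mismatch for {name}")
    if "spikes.csv" in manifest["files"]:
        result["spikes"] = SpikeRecord.read_csv(out / "spikes.csv")
    if "weights.csv" in manifest["files"]:
        df = pd.read_csv(out / "weights.csv")
        result["weights"] = (df["pre_id"].to_numpy(np.int32),
                             df["post_id"].to_numpy(np.int32),
                             df["w"].to_numpy(float))
    if "metrics.json" in manifest["files"]:
        result["metrics"] = json.loads((out / "metrics.json").read_text())
    if "config.yaml" in manifest["files"]:
        result["config"] = yaml.safe_load((out / "config.yaml").read_text())
    return result
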