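"""Serialization: spike logs, weight snapshots, rate traces and run
manifests, plus YAML config loading.

All tables are delimited text (TSV) and every output directory gets a JSON
manifest carrying the seed, a hash of the configuration, and wall-clock
info, so outputs from different configurations refuse to aggregate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core import SpikeRecord

__all__ = [
    "config_hash", "write_manifest", "read_manifest",
    "write_spikes", "read_spikes", "write_weights", "read_weights",
    "write_table", "read_table", "load_config", "dump_config",
]


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def config_hash(cfg: Any) -> str:
    """Stable short hash of a configuration object (dataclass or dict)."""
    blob = json.dumps(_to_plain(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir: Path | str, cfg: Any, seed: int,
                   extra: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config_hash(cfg),
        "config": _to_plain(cfg),
        "seed": int(seed),
        "wall_clock": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    if extra:
        manifest.update(_to_plain(extra))
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_manifest(out_dir: Path | str) -> dict:
    return json.loads((Path(out_dir) / "manifest.json").read_text())


def write_spikes(path: Path | str, record: SpikeRecord) -> Path:
    """Spike log as TSV with columns population, neuron, time_ms."""
    path = Path(path)
    frames = []
    for pop in record.populations:
        t, i = record.spikes(pop)
        frames.append(pd.DataFrame({"population": pop, "neuron": i,
                                    "time_ms": t}))
    df = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=["population", "neuron", "time_ms"])
    df.sort_values("time_ms", kind="stable").to_csv(path, sep="\t",
                                                    index=False)
    return path


def read_spikes(path: Path | str) -> SpikeRecord:
    df = pd.read_csv(path, sep="\t")
    pops = list(dict.fromkeys(df["population"])) if len(df) else []
    rec = SpikeRecord(pops)
    for pop in pops:
        sub = df[df["population"] == pop]
        rec.add(pop, 0.0, np.empty(0, dtype=np.int64))  # init t_start
        rec._times[pop] = [sub["time_ms"].to_numpy(dtype=float)]
        rec._idx[pop] = [sub["neuron"].to_numpy(dtype=np.int32)]
    if len(df):
        rec.t_start = float(df["time_ms"].min())
        rec.duration = float(df["time_ms"].max())
    return rec


def write_weights(path: Path | str, W: np.ndarray,
                  meta: dict | None = None) -> Path:
    """Dense weight matrix as TSV plus a JSON sidecar of metadata."""
    path = Path(path)
    np.savetxt(path, W, delimiter="\t")
    if meta is not None:
        Path(str(path) + ".json").write_text(json.dumps(_to_plain(meta),
                                                        indent=2))
    return path


def read_weights(path: Path | str) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def write_table(path: Path | str, df: pd.DataFrame) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path: Path | str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(path: Path | str, cfg: Any) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))
    return path
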