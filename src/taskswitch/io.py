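"""Run configuration, serialization and manifests.

All file formats are plain text: CSVs with explicit headers and ms/spikes-per-ms
units in column names, JSON for fit results and manifests, YAML or JSON for
configuration.  Every run writes its resolved configuration and a manifest
(config hash, master seed, package version) beside its outputs so any output
file can be traced to the exact inputs that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .integrators import IntegratorConfig
from .synthetic_mt import DEFAULT_LEVELS, PopulationRateTable


@dataclass
class RunConfig:
    """Resolved configuration of one simulation/analysis run."""

    n_neurons: int = 117
    tuning: str = "default"  # {"default", "balanced"}
    levels: list[float] = field(
        default_factory=lambda: [float(x) for x in DEFAULT_LEVELS])
    table_trials_per_condition: int = 10
    variant: str = "gated"
    w: float | None = 0.3
    tau_ms: float | None = None  # leak/gate time constant; k = 1/tau_ms
    trials_per_condition: int = 1000
    n_boot: int = 10000
    seed: int = 0
    save_spikes: bool = False
    commitment_times: list[float] = field(
        default_factory=lambda: [float(t) for t in range(0, 601, 50)])
    regimes: list[str] = field(default_factory=lambda: ["open", "closed"])

    def integrator_config(self) -> IntegratorConfig:
        k = None if self.tau_ms is None else 1.0 / self.tau_ms
        w = self.w if self.variant in ("gated", "single_leaky") else None
        return IntegratorConfig(variant=self.variant, w=w, k=k)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(outdir: str | Path, config: RunConfig,
                   extra: dict | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "taskswitch",
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": config.seed,
        "variant": config.variant,
        "w": config.w,
        "tau_ms": config.tau_ms,
        "k_per_ms": None if config.tau_ms is None else 1.0 / config.tau_ms,
    }
    manifest.update(extra or {})
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.save(outdir / "config.yaml")
    return path


# ---------------------------------------------------------------------------
# table / trial / spike CSV formats
# ---------------------------------------------------------------------------

def save_rate_table(table: PopulationRateTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def load_rate_table(path: str | Path) -> PopulationRateTable:
    return PopulationRateTable.from_frame(pd.read_csv(path))


def save_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def load_trials(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_spikes(spikes: pd.DataFrame, path: str | Path) -> None:
    """One row per spike: trial_id, neuron_id, task, c_dir, c_dep, choice,
    spike_time_ms."""
    spikes.to_csv(path, index=False)


def load_spikes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def spikes_to_counts(spikes: pd.DataFrame, trials: pd.DataFrame,
                     bin_starts: np.ndarray | None = None,
                     bin_width: float = 100.0) -> pd.DataFrame:
    """Bin a spike-times table into the per-trial 100-ms counts CP consumes.

    ``trials`` supplies the complete trial list (so zero-spike trials still
    appear with count 0).
    """
    bin_starts = (np.arange(-100, 700, 100) if bin_starts is None
                  else np.asarray(bin_starts, dtype=float))
    keys = ["task", "c_dir", "c_dep", "trial"]
    base = trials[keys + ["choice"]].drop_duplicates()
    frames = []
    sp = spikes.rename(columns={"trial_id": "trial", "neuron_id": "neuron"})
    for b in bin_starts:
        in_bin = sp[(sp["spike_time_ms"] >= b)
                    & (sp["spike_time_ms"] < b + bin_width)]
        cnt = in_bin.groupby(keys + ["neuron"], as_index=False).size()
        cnt = cnt.rename(columns={"size": "count"})
        full = base.merge(pd.DataFrame({"neuron": np.arange(1, 9)}), how="cross")
        full = full.merge(cnt, on=keys + ["neuron"], how="left")
        full["count"] = full["count"].fillna(0).astype(int)
        full["bin_start"] = b
        frames.append(full)
    return pd.concat(frames, ignore_index=True)


def fit_result_to_json(result: dict, path: str | Path) -> None:
    """Serialize a psychometric fit bundle (betas, p_err, lnL, AIC, SR, ...)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o):
            d = dataclasses.asdict(o)
            d.pop("curve", None)
            return d
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(result, indent=2, default=default))
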