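"""Config parsing, result serialization and run manifests.

Topologies travel as YAML (compartments, fluxes with {source, target, k,
epsilon}, intake block); all tabular results are tidy CSV with
deterministic row ordering (compartment order, then time).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
import yaml

from .calibration import resources_open
from .topology import DIET, CompartmentSpec, FluxSpec, ModelTopology, TopologyError


class ConfigError(ValueError):
    pass


def topology_to_dict(topology: ModelTopology) -> dict:
    return {
        "diet": {
            "intake": topology.intake,
            "delta15N": topology.diet_delta,
        },
        "compartments": [
            {"id": c.id, "label": c.label, "subsystem": c.subsystem,
             "fraction": c.fraction}
            for c in topology.compartments
        ],
        "fluxes": [
            {"id": f.id, "source": f.source, "target": f.target,
             "k": float(f.k), "epsilon": float(f.epsilon)}
            for f in topology.fluxes
        ],
    }


def topology_from_dict(raw: dict) -> ModelTopology:
    try:
        comps = tuple(
            CompartmentSpec(
                id=c["id"], label=c.get("label", ""),
                subsystem=c.get("subsystem", "peripheral"),
                fraction=c.get("fraction", "free-AA"),
            )
            for c in raw["compartments"]
        )
        fluxes = tuple(
            FluxSpec(id=f["id"], source=f["source"], target=f["target"],
                     k=float(f["k"]), epsilon=float(f.get("epsilon", 0.0)))
            for f in raw["fluxes"]
        )
        diet = raw.get("diet", {})
        diet_delta = float(diet.get("delta15N", 0.0))
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed topology config: {exc}") from exc
    topo = ModelTopology(comps, fluxes, diet_delta=diet_delta)
    declared = diet.get("intake")
    if declared is not None and abs(topo.intake - float(declared)) > 1e-9:
        raise ConfigError(
            f"declared intake {declared} does not match DIET fluxes ({topo.intake})"
        )
    return topo


def load_model_config(path) -> ModelTopology:
    """Load and validate a topology config (YAML)."""
    with resources_open(path) as fh:
        raw = yaml.safe_load(fh)
    return topology_from_dict(raw)


def save_model_config(topology: ModelTopology, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(topology_to_dict(topology), fh, sort_keys=False)


def write_trajectory(trajectory, path) -> None:
    """Tidy CSV: time, compartment, N, delta15N, Delta15N."""
    df = trajectory.to_frame()
    df = df.sort_values(
        ["compartment", "time"],
        key=lambda s: (s.map({c: i for i, c in enumerate(trajectory.topology.ids)})
                       if s.name == "compartment" else s),
        kind="stable",
    )
    df.to_csv(path, index=False, float_format="%.10g")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted once per CLI run."""

    command: str
    seed: int | None = None
    inputs: dict = dc_field(default_factory=dict)     # path -> sha256
    outputs: list = dc_field(default_factory=list)
    timings_s: dict = dc_field(default_factory=dict)
    version: str = ""

    def add_input(self, path) -> None:
        p = str(path)
        self.inputs[p] = file_sha256(p)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        from . import __version__
        payload = {
            "command": self.command,
            "seed": self.seed,
            "package_version": self.version or __version__,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "timings_s": self.timings_s,
            "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


class StageTimer:
    """Context helper recording per-stage wall time into a manifest."""

    def __init__(self, manifest: RunManifest, stage: str):
        self.manifest = manifest
        self.stage = stage

    def __enter__(self):
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.manifest.timings_s[self.stage] = round(
            time.perf_counter() - self._t0, 6
        )
        return False
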