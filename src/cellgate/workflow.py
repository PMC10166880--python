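"""Scripted multi-step workflows: simulate -> select -> stats -> filter -> plot.

A workflow is an ordered list of step dicts, each with an ``"op"`` field.
Steps that reference annotation keys are validated against keys defined by
earlier steps (or already present in the loaded dataset) *before* anything
runs, so a typo fails fast with a :class:`~cellgate.errors.ConfigError`.

The ``filter`` step drops all cells carrying a label and writes the reduced
raw dataset; embedding recomputation is deliberately not performed — the
reduced matrix is emitted for external re-embedding.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import core_data, mixture, regionstats, selection
from .core_data import CellDataset
from .errors import ConfigError
from .geometry import AxesContext, PolygonSet
from .plotting import render_overlay
from .synthetic import MarkerSpec, SimSpec, simulate

logger = logging.getLogger(__name__)

KNOWN_OPS = {
    "simulate", "select", "select-scatter", "rename", "stats", "gmm", "plot", "filter",
}


@dataclass
class RunConfig:
    """Paths and global settings for one workflow run."""

    out_dir: Path
    dataset_dir: Path | None = None  # load this dataset unless a simulate step runs
    seed: int = 0
    log_level: str = "INFO"
    steps: list[dict] = field(default_factory=list)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            out_dir=Path(d.get("out_dir", ".")),
            dataset_dir=Path(d["dataset_dir"]) if d.get("dataset_dir") else None,
            seed=int(d.get("seed", 0)),
            log_level=d.get("log_level", "INFO"),
            steps=list(d.get("steps", [])),
        )


def _spec_from_dict(d: dict, seed: int) -> SimSpec:
    markers = [
        MarkerSpec(m["gene"], frozenset(m["clusters"]), float(m["fold"]))
        for m in d.pop("marker_table", [])
    ]
    return SimSpec(marker_table=markers, seed=int(d.pop("seed", seed)), **d)


def validate_steps(steps: list[dict], initial_keys: set[str]) -> None:
    """Check ops and key references before execution; raise ConfigError early."""
    keys = set(initial_keys)
    have_dataset = bool(initial_keys) or any(s.get("op") == "simulate" for s in steps)
    for i, step in enumerate(steps):
        op = step.get("op")
        if op not in KNOWN_OPS:
            raise ConfigError(f"step {i}: unknown op {op!r}")
        if op == "simulate":
            keys.add("true_cluster")
        if op in ("select", "select-scatter", "gmm"):
            if "key" not in step:
                raise ConfigError(f"step {i} ({op}): missing 'key'")
            keys.add(step["key"])
        elif op in ("rename", "stats", "filter"):
            key = step.get("key")
            if op == "filter":
                key = step.get("key") or step.get("drop_key")
            if key is None:
                raise ConfigError(f"step {i} ({op}): missing 'key'")
            if have_dataset and keys and key not in keys:
                raise ConfigError(
                    f"step {i} ({op}): key {key!r} not defined by any earlier step "
                    f"(defined: {sorted(keys)})"
                )


def run_workflow(config: RunConfig) -> dict[str, Path]:
    """Execute the steps in order; returns a map of step outputs to paths."""
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ds: CellDataset | None = None
    if config.dataset_dir is not None:
        ds = core_data.read_dataset_dir(config.dataset_dir)
    initial = set(ds.annotations.columns) if ds is not None else set()
    validate_steps(config.steps, initial)

    outputs: dict[str, Path] = {}
    for i, step in enumerate(config.steps):
        op = step["op"]
        t0 = time.perf_counter()
        if op == "simulate":
            ds = simulate(_spec_from_dict(dict(step.get("spec", {})), config.seed))
            target = out_dir / step.get("out", "dataset")
            core_data.write_dataset_dir(ds, target)
            outputs[f"{i}:simulate"] = target
        elif ds is None:
            raise ConfigError(f"step {i} ({op}): no dataset loaded or simulated")
        elif op in ("select", "select-scatter"):
            polys = PolygonSet.load(step["session"])
            selection.apply_session(ds, polys, step["key"])
        elif op == "rename":
            selection.rename_labels(ds, step["key"], dict(step["mapping"]))
        elif op == "stats":
            table = regionstats.region_stats(
                ds, step["key"], genes=step.get("genes", [])
            )
            target = out_dir / step.get("out", f"stats_{step['key']}.csv")
            table.to_csv(target)
            outputs[f"{i}:stats"] = target
        elif op == "gmm":
            model = mixture.fit_gmm(
                ds,
                step["x"],
                step["y"],
                K=int(step["k"]),
                seed=int(step.get("seed", config.seed)),
                layer=step.get("layer", "normalized"),
            )
            mixture.assign_groups(model, ds, step["key"])
        elif op == "filter":
            label = step["drop_label"]
            key = step.get("key") or step.get("drop_key")
            mask = regionstats.label_mask(ds, key, label)
            ds = ds.subset(~mask)
            target = out_dir / step.get("out", "filtered")
            core_data.write_dataset_dir(ds, target)
            outputs[f"{i}:filter"] = target
        elif op == "plot":
            polys = ds.polygon_store.get(step.get("key", ""))
            if step.get("session"):
                polys = PolygonSet.load(step["session"])
            axes = (
                polys.axes
                if polys is not None
                else AxesContext(kind="embedding", embedding_name=step["embedding"])
            )
            target = out_dir / step.get("out", f"plot_{i}.png")
            render_overlay(ds, axes, polys, step.get("color_by"), target)
            outputs[f"{i}:plot"] = target
        logger.info("step %d (%s) done in %.2fs", i, op, time.perf_counter() - t0)
    return outputs
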