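"""Parametric sweeps: vary one configuration field, replicate over seeds,
and tabulate the resulting headline quantities.

A parameter is addressed with a dotted path into the configuration, where
the ``groups`` segment is followed by a group *name*, e.g.
``groups.uf.loops.count`` or ``groups.ax.coupling.cs``.  Each (value,
replicate) cell runs one full simulation with its own derived seed and
yields final strain, peak forces and event count; the aggregate reports
mean ± sd per value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from pydantic import ValidationError

from .bundle import simulate
from .config import ConfigError, ThreadConfig, build_bundle, config_fingerprint

__all__ = ["SweepSpec", "set_config_value", "run_sweep", "aggregate_sweep"]


@dataclass(frozen=True)
class SweepSpec:
    """One-dimensional sweep: a parameter path, its values, replication."""

    parameter_path: str
    values: Sequence[Any]
    replicates: int = 1
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("sweep needs at least one value")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")


def set_config_value(config: ThreadConfig, path: str, value: Any) -> ThreadConfig:
    """Return a copy of ``config`` with the field at dotted ``path`` replaced.

    After ``groups``, the next segment selects a group by name.  The modified
    configuration is re-validated, so a sweep can never produce an invalid
    model silently.
    """
    tokens = path.split(".")
    data = config.model_dump(exclude_none=True)
    node: Any = data
    for i, tok in enumerate(tokens[:-1]):
        if isinstance(node, list):
            match = [g for g in node if isinstance(g, dict) and g.get("name") == tok]
            if not match:
                raise ConfigError(f"sweep path {path!r}: no group named {tok!r}")
            node = match[0]
        elif isinstance(node, dict):
            if tok not in node:
                raise ConfigError(f"sweep path {path!r}: unknown field {tok!r}")
            node = node[tok]
        else:
            raise ConfigError(f"sweep path {path!r}: cannot descend into {tok!r}")
    leaf = tokens[-1]
    if isinstance(node, list):
        raise ConfigError(f"sweep path {path!r}: path ends at a list; name a group")
    if leaf not in node:
        raise ConfigError(f"sweep path {path!r}: unknown field {leaf!r}")
    node[leaf] = value
    try:
        return ThreadConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(f"sweep value {value!r} at {path!r} is invalid:\n{exc}") from exc


def _cell_seed(base_seed: int, value_index: int, replicate: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(value_index, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def run_sweep(config: ThreadConfig, spec: SweepSpec) -> pd.DataFrame:
    """Run the sweep; one row per (value, replicate)."""
    rows = []
    for vi, value in enumerate(spec.values):
        cfg = set_config_value(config, spec.parameter_path, value)
        fp = config_fingerprint(cfg)
        for rep in range(spec.replicates):
            seed = _cell_seed(spec.base_seed, vi, rep)
            bundle = build_bundle(cfg, seed=seed)
            res = simulate(bundle, x_max=cfg.x_max, dx=cfg.dx, seed=seed, config_fingerprint=fp)
            rows.append(
                {
                    "value": value,
                    "replicate": rep,
                    "seed": seed,
                    "final_strain": res.final_strain,
                    "peak_force": res.peak_force,
                    "strain_at_peak": res.strain_at_peak,
                    "n_events": res.n_events(),
                    "n_loop_open": res.n_events("loop_open"),
                    "fingerprint": fp,
                }
            )
    return pd.DataFrame(rows)


def aggregate_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd of the headline quantities per swept value."""
    agg = (
        table.groupby("value", sort=False)[["final_strain", "peak_force", "n_events"]]
        .agg(["mean", "std"])
    )
    agg.columns = ["_".join(col) for col in agg.columns]
    return agg.reset_index()
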