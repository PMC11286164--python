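"""Bundle assembly and the quasi-static displacement-controlled solver.

The thread is modelled as N parallel elements clamped at both ends: under
displacement control every surviving element sees the same external strain
``x`` and the measured force is the plain sum of element forces (equal load
sharing is implicit — "redistribution" after a failure is just the shrinking
sum).  The solver ramps ``x`` on a fixed grid; at each grid point it resolves
loop openings and material failures to a fixed point, because one opening can
change a coupled element's effective elongation and trigger further events
at the same strain.

Also provides the classic fibre-bundle-model closed form
``F = N·k·x·(1 − P(x))`` used as an analytic cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .elements import Element, LoopedElement, StraightElement

__all__ = ["Bundle", "Event", "SimulationResult", "classic_fbm_force", "simulate"]

_EPS = 1e-9


@dataclass(frozen=True)
class Event:
    """One discrete event in a simulation: a loop opening or an element failure."""

    strain: float
    element_id: str
    kind: str  # "loop_open" | "element_fail"
    threshold: Optional[float] = None
    hidden_length: Optional[float] = None


class Bundle:
    """An ordered collection of parallel elements plus their coupling graph.

    Coupled straight elements (the axial fibres) read, at every step, the
    accumulated slack of the *most elongating* member of their coupling set
    (the looped element with the largest accumulated slack) scaled by ``Cs``.
    """

    def __init__(self, elements: Sequence[Element]):
        ids = [e.id for e in elements]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate element ids: {dupes}")
        self.elements: list[Element] = list(elements)
        by_id = {e.id: e for e in self.elements}
        self._sources: dict[str, list[LoopedElement]] = {}
        for e in self.elements:
            srcs = []
            for sid in e.coupling_sources:
                if sid not in by_id:
                    raise ValueError(f"{e.id}: coupling source {sid!r} does not exist")
                src = by_id[sid]
                if not isinstance(src, LoopedElement):
                    raise ValueError(f"{e.id}: coupling source {sid!r} is not a looped element")
                srcs.append(src)
            self._sources[e.id] = srcs

    def __len__(self) -> int:
        return len(self.elements)

    def upstream_slack(self, element: Element) -> float:
        """Largest accumulated slack among the element's coupling sources."""
        sources = self._sources[element.id]
        if not sources:
            return 0.0
        return max(s.accumulated_slack for s in sources)

    @property
    def all_failed(self) -> bool:
        return all(e.failed for e in self.elements)

    def total_force(self, x: float) -> float:
        """Sum of element forces at external strain ``x`` (current state)."""
        total = 0.0
        for e in self.elements:
            if e.failed:
                continue
            total += e.force_at(e.effective_elongation(x, self.upstream_slack(e)))
        return total

    def step(self, x: float) -> tuple[float, list[Event]]:
        """Advance to external strain ``x``: resolve the event cascade, return
        the post-cascade total force and the events triggered at ``x``."""
        events: list[Event] = []
        cap = 2 + len(self.elements) + sum(
            e.n_loops for e in self.elements if isinstance(e, LoopedElement)
        )
        for _ in range(cap):
            new: list[Event] = []
            for e in self.elements:
                if e.failed:
                    continue
                x_e = e.effective_elongation(x, self.upstream_slack(e))
                if x_e > e.max_effective_elongation:
                    e.max_effective_elongation = x_e
                if isinstance(e, LoopedElement) and e.has_unopened_loops:
                    if x_e >= e.next_threshold - _EPS:
                        op = e.open_next_loop(x)
                        new.append(Event(x, e.id, "loop_open", op.threshold, op.hidden_length))
                elif x_e > e.applicable_critical_strain() + _EPS:
                    e.failed = True
                    new.append(Event(x, e.id, "element_fail"))
            if not new:
                break
            events.extend(new)
        else:  # pragma: no cover - cap is a strict upper bound on events
            raise RuntimeError("event cascade failed to reach a fixed point")
        return self.total_force(x), events


@dataclass
class SimulationResult:
    """Force–elongation trace plus the event log of one simulation."""

    strains: np.ndarray
    forces: np.ndarray
    events: list[Event]
    element_max_elongation: dict[str, float]
    dx: float
    seed: Optional[int] = None
    config_fingerprint: Optional[str] = None

    @property
    def final_strain(self) -> float:
        """Largest external strain at which the bundle still carries force."""
        nz = np.nonzero(self.forces > 0.0)[0]
        return float(self.strains[nz[-1]]) if nz.size else 0.0

    @property
    def peak_force(self) -> float:
        return float(self.forces.max()) if self.forces.size else 0.0

    @property
    def strain_at_peak(self) -> float:
        return float(self.strains[int(np.argmax(self.forces))])

    def n_events(self, kind: Optional[str] = None) -> int:
        if kind is None:
            return len(self.events)
        return sum(1 for ev in self.events if ev.kind == kind)

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"strain": self.strains, "force": self.forces})

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain": [ev.strain for ev in self.events],
                "element_id": [ev.element_id for ev in self.events],
                "event_kind": [ev.kind for ev in self.events],
                "threshold": [ev.threshold for ev in self.events],
                "hidden_length": [ev.hidden_length for ev in self.events],
            }
        )

    def summary(self) -> dict:
        return {
            "n_elements": len(self.element_max_elongation),
            "final_strain": self.final_strain,
            "peak_force": self.peak_force,
            "strain_at_peak": self.strain_at_peak,
            "n_loop_open": self.n_events("loop_open"),
            "n_element_fail": self.n_events("element_fail"),
            "element_max_elongation": self.element_max_elongation,
            "dx": self.dx,
            "seed": self.seed,
            "config_fingerprint": self.config_fingerprint,
        }

    def save(self, prefix: str | Path) -> dict[str, Path]:
        """Write curve CSV, events CSV and a JSON sidecar; returns the paths."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "curve": prefix.with_name(prefix.name + "_curve.csv"),
            "events": prefix.with_name(prefix.name + "_events.csv"),
            "summary": prefix.with_name(prefix.name + "_summary.json"),
        }
        with open(paths["curve"], "w") as fh:
            fh.write("# units=relative\n")
            self.curve_frame().to_csv(fh, index=False)
        self.events_frame().to_csv(paths["events"], index=False)
        paths["summary"].write_text(json.dumps(self.summary(), indent=2) + "\n")
        return paths


def simulate(
    bundle: Bundle,
    x_max: float = 50.0,
    dx: float = 0.005,
    seed: Optional[int] = None,
    config_fingerprint: Optional[str] = None,
) -> SimulationResult:
    """Quasi-static ramp of external strain from 0 to ``x_max`` in steps ``dx``.

    Stops at the first grid point where every element has failed (that point
    is recorded, with zero force) or at ``x_max``, whichever comes first.
    ``seed`` is recorded metadata only: all randomness lives in bundle
    construction, so the run is deterministic given (bundle, dx).
    """
    if dx <= 0:
        raise ValueError(f"dx must be > 0, got {dx}")
    if x_max <= 0:
        raise ValueError(f"x_max must be > 0, got {x_max}")
    strains: list[float] = []
    forces: list[float] = []
    events: list[Event] = []
    i = 0
    while True:
        x = i * dx
        force, new_events = bundle.step(x)
        strains.append(x)
        forces.append(force)
        events.extend(new_events)
        if bundle.all_failed or x >= x_max:
            break
        i += 1
    return SimulationResult(
        strains=np.asarray(strains),
        forces=np.asarray(forces),
        events=events,
        element_max_elongation={e.id: e.max_effective_elongation for e in bundle.elements},
        dx=dx,
        seed=seed,
        config_fingerprint=config_fingerprint,
    )


def classic_fbm_force(
    N: int,
    k: float,
    x: float | np.ndarray,
    threshold_cdf: Callable[[np.ndarray], np.ndarray] | tuple[np.ndarray, np.ndarray],
) -> float | np.ndarray:
    """Classic equal-load-sharing fibre-bundle force ``F = N·k·x·(1 − P(x))``.

    ``threshold_cdf`` is either a callable CDF (e.g. a frozen scipy
    distribution's ``.cdf``) or a tabulated ``(xs, ps)`` pair, which must be
    monotone with ``ps`` in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("elongation must be non-negative")
    if callable(threshold_cdf):
        p = np.asarray(threshold_cdf(x), dtype=float)
    else:
        xs, ps = (np.asarray(a, dtype=float) for a in threshold_cdf)
        if xs.shape != ps.shape or xs.ndim != 1:
            raise ValueError("tabulated CDF must be two equal-length 1-d arrays")
        if np.any(np.diff(xs) <= 0) or np.any(np.diff(ps) < 0):
            raise ValueError("tabulated CDF must be monotone")
        if np.any(ps < 0) or np.any(ps > 1):
            raise ValueError("CDF values must lie in [0, 1]")
        p = np.interp(x, xs, ps, left=0.0, right=1.0)
    out = N * k * x * (1.0 - p)
    return float(out) if out.ndim == 0 else out
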