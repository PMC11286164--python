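"""Force–elongation curve I/O, summary statistics, and test-geometry helpers.

Curves are two-column CSVs (``strain, force``) with optional ``# key=value``
metadata lines for units and gauge length; simulation output and empirical
tensile-test exports share the format.  The summary statistics mirror what
is reported from axial tensile tests of capture threads: the dominant radial
peak, the largest post-radial peak, and the strain at break.  Geometry
helpers convert the vertical (perpendicular pull) test's linear-table travel
into thread strain and a microbalance weight reading into force.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ForceCurve",
    "DropEvent",
    "CurveSummary",
    "read_curve",
    "write_curve",
    "detect_drops",
    "summarize",
    "vertical_strain_from_travel",
    "force_from_weight",
    "GRAVITY",
]

GRAVITY = 9.81  # m/s²; grams × g → mN


@dataclass
class ForceCurve:
    """A force–elongation trace: strictly increasing strain, finite forces."""

    strain: np.ndarray
    force: np.ndarray
    units: str = "relative"  # "mN" for empirical data
    gauge_length: Optional[float] = None  # mm

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.strain.shape != self.force.shape or self.strain.ndim != 1:
            raise ValueError("strain and force must be equal-length 1-d sequences")
        bad = np.nonzero(np.diff(self.strain) <= 0)[0]
        if bad.size:
            # cite the 1-based data row whose strain fell back
            raise ValueError(f"strain must be strictly increasing (violated at row {bad[0] + 2})")
        nonfinite = np.nonzero(~np.isfinite(self.force))[0]
        if nonfinite.size:
            raise ValueError(f"force must be finite (violated at row {nonfinite[0] + 1})")

    def __len__(self) -> int:
        return len(self.strain)


@dataclass(frozen=True)
class DropEvent:
    """A sudden force drop: strain at the local peak, forces before/after."""

    strain: float
    force_before: float
    force_after: float


@dataclass
class CurveSummary:
    """Headline statistics of one force–elongation curve."""

    radial_peak_force: Optional[float]
    strain_at_radial_peak: Optional[float]
    post_radial_peak_force: Optional[float]
    strain_at_break: float
    drop_events: list[DropEvent] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "radial_peak_force": self.radial_peak_force,
            "strain_at_radial_peak": self.strain_at_radial_peak,
            "post_radial_peak_force": self.post_radial_peak_force,
            "strain_at_break": self.strain_at_break,
            "n_drop_events": len(self.drop_events),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_row(self) -> pd.DataFrame:
        """One-row frame using the tensile-test report column names."""
        return pd.DataFrame(
            [
                {
                    "radial line peak force": self.radial_peak_force,
                    "peak force before break": self.post_radial_peak_force,
                    "strain at peak force": self.strain_at_radial_peak,
                    "strain at break": self.strain_at_break,
                }
            ]
        )


def read_curve(path: str | Path) -> ForceCurve:
    """Read a two-column (strain, force) CSV with optional ``# key=value`` metadata."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            for token in line[1:].split():
                if "=" in token:
                    key, _, val = token.partition("=")
                    meta[key.strip()] = val.strip()
        else:
            data_lines.append(line)
    from io import StringIO

    frame = pd.read_csv(StringIO("".join(data_lines)))
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (strain, force)")
    strain = frame.iloc[:, 0].to_numpy(dtype=float)
    force = frame.iloc[:, 1].to_numpy(dtype=float)
    gauge = float(meta["gauge_length"]) if "gauge_length" in meta else None
    try:
        return ForceCurve(strain, force, units=meta.get("units", "relative"), gauge_length=gauge)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_curve(curve: ForceCurve, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        meta = f"# units={curve.units}"
        if curve.gauge_length is not None:
            meta += f" gauge_length={curve.gauge_length}"
        fh.write(meta + "\n")
        pd.DataFrame({"strain": curve.strain, "force": curve.force}).to_csv(fh, index=False)


def detect_drops(curve: ForceCurve, min_rel_drop: float = 0.05) -> list[DropEvent]:
    """Find sudden force drops along the curve.

    Each maximal strictly-decreasing run of samples becomes one event if its
    relative drop ``1 − f_after/f_before`` is at least ``min_rel_drop``.
    """
    if not (0.0 < min_rel_drop < 1.0):
        raise ValueError(f"min_rel_drop must be in (0, 1), got {min_rel_drop}")
    force, strain = curve.force, curve.strain
    events = []
    i = 0
    n = len(force)
    while i < n - 1:
        if force[i + 1] < force[i]:
            start = i
            while i < n - 1 and force[i + 1] < force[i]:
                i += 1
            before, after = force[start], force[i]
            if before > 0 and (1.0 - after / before) >= min_rel_drop:
                events.append(DropEvent(float(strain[start]), float(before), float(after)))
        else:
            i += 1
    return events


def summarize(
    curve: ForceCurve,
    noise_floor: float = 0.01,
    min_rel_drop: float = 0.05,
    radial: bool = True,
) -> CurveSummary:
    """Extract the headline statistics of a force–elongation curve.

    With ``radial=True`` (axial tensile tests, where the stiff radial line's
    early failure dominates every later force) the global maximum is read as
    the radial peak and the largest later force as the peak before break.
    With ``radial=False`` (vertical tests on the cribellar band alone) only
    the overall peak and the strain at break are reported.

    ``strain_at_break`` is the largest strain whose force exceeds
    ``noise_floor`` × (global max force).
    """
    if len(curve) == 0:
        raise ValueError("cannot summarize an empty curve")
    force, strain = curve.force, curve.strain
    fmax = float(force.max())
    if fmax <= 0:
        raise ValueError("cannot summarize an all-zero curve")
    i_peak = int(np.argmax(force))
    floor = noise_floor * fmax
    above = np.nonzero(force > floor)[0]
    strain_at_break = float(strain[above[-1]])
    drops = detect_drops(curve, min_rel_drop=min_rel_drop)
    if not radial:
        return CurveSummary(
            radial_peak_force=None,
            strain_at_radial_peak=None,
            post_radial_peak_force=fmax,
            strain_at_break=strain_at_break,
            drop_events=drops,
        )
    tail = force[i_peak + 1 :]
    return CurveSummary(
        radial_peak_force=fmax,
        strain_at_radial_peak=float(strain[i_peak]),
        post_radial_peak_force=float(tail.max()) if tail.size else 0.0,
        strain_at_break=strain_at_break,
        drop_events=drops,
    )


def vertical_strain_from_travel(travel: float, half_length: float) -> float:
    """Thread strain in a vertical (perpendicular pull) test.

    A hook snags the midpoint of a thread of half-length ``h`` (mm) and is
    withdrawn by ``travel`` (mm); each half stretches to ``√(h² + travel²)``,
    so the engineering strain is ``(2·√(h² + t²) − 2h) / (2h)``.
    """
    if half_length <= 0:
        raise ValueError(f"half_length must be > 0, got {half_length}")
    if travel < 0:
        raise ValueError(f"travel must be >= 0, got {travel}")
    return (2.0 * math.hypot(half_length, travel) - 2.0 * half_length) / (2.0 * half_length)


def force_from_weight(weight_reading_g: float) -> float:
    """Convert a microbalance weight reading (grams) into force (mN).

    The minimal (most negative) reading during a pull-off gives the peak
    force: |grams| × 9.81 m/s² = mN.
    """
    if not math.isfinite(weight_reading_g):
        raise ValueError("weight reading must be finite")
    return abs(weight_reading_g) * GRAVITY
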