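"""Per-element mechanics of the looped-thread bundle.

Two element kinds make up a cribellar-thread model:

* :class:`StraightElement` — a plain fibre (radial line, axial fibre) that
  carries load up to a critical strain and then fails.  It may be *coupled*
  to looped fibres, receiving a fraction ``Cs`` of the slack those fibres
  generate, which delays its own loading.
* :class:`LoopedElement` — a fibre folded into a series of loops (undulating
  or paracribellar fibre).  Each loop has an opening threshold and a hidden
  length; when the effective elongation reaches the smallest unopened
  threshold the loop unravels, the released length is added to the element's
  accumulated slack and the force across it resets to zero.

The effective elongation of an element under external strain ``x`` is

    x_e = x − (own accumulated slack) − Cs · (upstream slack)

and the force it carries is ``σ(x_e) · d_rel²`` while ``0 < x_e ≤ x_c``,
zero when slack (``x_e ≤ 0``), and zero permanently once ``x_e`` exceeds the
applicable critical strain (material failure, irreversible).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .constitutive import ConstitutiveLaw

__all__ = [
    "Loop",
    "StraightElement",
    "LoopedElement",
    "LoopOpening",
    "element_failed",
    "loop_opening_strains",
]

# numerical tolerance for threshold comparisons on the strain grid
_EPS = 1e-9


@dataclass(frozen=True)
class Loop:
    """One loop of hidden length: opens when x_e reaches ``threshold``."""

    threshold: float
    hidden_length: float

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"loop threshold must be > 0, got {self.threshold}")
        if self.hidden_length < 0:
            raise ValueError(f"hidden length must be >= 0, got {self.hidden_length}")


@dataclass(frozen=True)
class LoopOpening:
    """Event record: a loop unravelled at external strain ``strain``."""

    element_id: str
    strain: float
    threshold: float
    hidden_length: float


@dataclass
class _ElementBase:
    id: str
    rel_diameter: float
    law: ConstitutiveLaw
    coupling_sources: tuple[str, ...] = ()
    cs: float = 1.0
    failed: bool = field(default=False, init=False)
    max_effective_elongation: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if self.rel_diameter <= 0:
            raise ValueError(f"{self.id}: rel_diameter must be > 0")
        if self.coupling_sources and not (0.0 < self.cs <= 1.0):
            raise ValueError(f"{self.id}: Cs must be in (0, 1] when coupled, got {self.cs}")

    @property
    def area(self) -> float:
        """Relative cross-section: (relative diameter)²."""
        return self.rel_diameter**2

    @property
    def accumulated_slack(self) -> float:
        return 0.0

    def effective_elongation(self, x: float, upstream_slack: float = 0.0) -> float:
        """x_e = x − own slack − Cs · upstream slack (may be negative: slack)."""
        return x - self.accumulated_slack - upstream_slack * self.cs

    def applicable_critical_strain(self) -> float:
        raise NotImplementedError

    def force_at(self, x_e: float) -> float:
        """Force carried at effective elongation ``x_e`` (relative units).

        Zero if already failed or slack; exceeding the applicable critical
        strain irreversibly marks the element failed.
        """
        if self.failed or x_e <= 0.0:
            return 0.0
        if x_e > self.applicable_critical_strain() + _EPS:
            self.failed = True
            return 0.0
        return self.law.stress(x_e) * self.area


@dataclass
class StraightElement(_ElementBase):
    """A straight fibre failing at ``critical_strain``."""

    critical_strain: float = 0.5

    def applicable_critical_strain(self) -> float:
        return self.critical_strain


@dataclass
class LoopedElement(_ElementBase):
    """A series-of-loops fibre.

    Loops open in ascending threshold order (after each force reset the
    effective elongation climbs back from below zero, so the smallest
    remaining threshold is necessarily hit first).  While any loop remains
    unopened the element cannot fail; once all loops are open it behaves as
    a straight fibre with critical strain ``post_loop_critical_strain``.
    """

    loops: Sequence[Loop] = ()
    post_loop_critical_strain: float = 0.5
    slack_mode: Literal["reset", "hidden_only"] = "reset"
    _slack: float = field(default=0.0, init=False)
    _next: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        super().__post_init__()
        # ties broken by original loop index (stable sort)
        self.loops = tuple(sorted(self.loops, key=lambda lp: lp.threshold))
        if self.slack_mode not in ("reset", "hidden_only"):
            raise ValueError(f"{self.id}: unknown slack_mode {self.slack_mode!r}")

    @property
    def accumulated_slack(self) -> float:
        return self._slack

    @property
    def n_loops(self) -> int:
        return len(self.loops)

    @property
    def n_opened(self) -> int:
        return self._next

    @property
    def has_unopened_loops(self) -> bool:
        return self._next < len(self.loops)

    @property
    def next_threshold(self) -> Optional[float]:
        if not self.has_unopened_loops:
            return None
        return self.loops[self._next].threshold

    def applicable_critical_strain(self) -> float:
        if self.has_unopened_loops:
            return float("inf")
        return self.post_loop_critical_strain

    def open_next_loop(self, x: float) -> LoopOpening:
        """Unravel the smallest-threshold unopened loop at external strain ``x``.

        In ``reset`` mode the accumulated slack grows by
        ``threshold + hidden_length``, so the new effective elongation is
        ``−hidden_length``: the force resets to zero and the released length
        must straighten before the element re-engages.  In ``hidden_only``
        mode only the hidden length is added.
        """
        if not self.has_unopened_loops:
            raise RuntimeError(f"{self.id}: no unopened loops")
        loop = self.loops[self._next]
        if self.slack_mode == "reset":
            self._slack += loop.threshold + loop.hidden_length
        else:
            self._slack += loop.hidden_length
        self._next += 1
        return LoopOpening(self.id, x, loop.threshold, loop.hidden_length)


Element = StraightElement | LoopedElement


def element_failed(element: Element, x_e: float) -> bool:
    """Would the element be failed at effective elongation ``x_e``?

    True iff the element is straight and ``x_e`` exceeds its critical strain,
    or looped with every loop already open and ``x_e`` beyond the post-loop
    critical strain.  A looped element with unopened loops cannot fail: the
    next loop opens first.
    """
    if element.failed:
        return True
    if isinstance(element, LoopedElement) and element.has_unopened_loops:
        return False
    return x_e > element.applicable_critical_strain() + _EPS


def loop_opening_strains(loops: Sequence[Loop]) -> list[float]:
    """Closed-form external strains at which each loop of a single looped
    element opens under a quasi-static ramp in ``reset`` mode.

    With thresholds sorted ascending ``t_(1..n)`` and hidden lengths
    ``ℓ_(i)``, opening ``i`` occurs at ``Σ_{j<i} (t_(j) + ℓ_(j)) + t_(i)``:
    every earlier opening pushed the slack up by its threshold plus hidden
    length, and the effective elongation must climb back to the next
    threshold.  Serves as the independent oracle for the stepping solver.
    """
    ordered = sorted(loops, key=lambda lp: lp.threshold)
    strains, slack = [], 0.0
    for loop in ordered:
        strains.append(slack + loop.threshold)
        slack += loop.threshold + loop.hidden_length
    return strains
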