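"""Stress–strain laws and threshold distributions shared by all bundle elements.

Silk fibres in the model are either linearly elastic (``σ = E·ε``) or follow a
stiffening odd polynomial (``σ = c1·ε + c3·ε³``), with stress in GPa and strain
dimensionless.  Loop-opening thresholds and hidden lengths are drawn from
uniform ``mean ± halfwidth`` distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConstitutiveLaw", "UniformPM", "sample_pm"]


@dataclass(frozen=True)
class ConstitutiveLaw:
    """Odd polynomial stress–strain law through the origin.

    Parameters
    ----------
    coefficients : dict[int, float]
        Mapping of odd polynomial degree to its coefficient (GPa), e.g.
        ``{1: 0.1, 3: 5.0}`` for ``σ = 0.1·ε + 5·ε³``.  All degrees must be
        odd and all coefficients non-negative, which guarantees ``σ(0) = 0``
        and monotone non-decreasing stress.
    """

    coefficients: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for degree, coeff in self.coefficients.items():
            if not (isinstance(degree, int) and degree >= 1 and degree % 2 == 1):
                raise ValueError(f"polynomial degree must be a positive odd integer, got {degree!r}")
            if coeff < 0:
                raise ValueError(f"coefficient for degree {degree} must be non-negative, got {coeff}")

    @classmethod
    def linear(cls, modulus: float) -> "ConstitutiveLaw":
        """Linear elastic law ``σ = E·ε`` with Young's modulus in GPa."""
        return cls({1: float(modulus)})

    def stress(self, strain: float | np.ndarray) -> float | np.ndarray:
        """Evaluate ``σ(ε) = Σ c_i · ε^i`` for ``ε ≥ 0``.

        Negative strain is a caller error: slack elements carry zero force
        and must be clamped before evaluating the material law.
        """
        strain = np.asarray(strain, dtype=float)
        if np.any(strain < 0):
            raise ValueError("strain must be non-negative; clamp slack elements to zero force")
        out = np.zeros_like(strain)
        for degree, coeff in self.coefficients.items():
            out = out + coeff * strain**degree
        return float(out) if out.ndim == 0 else out

    def secant_stiffness(self, strain: float) -> float:
        """Secant stiffness ``k(ε) = σ(ε)/ε`` (the per-unit-area tooth slope)."""
        if strain <= 0:
            # limit ε→0 of σ/ε is the linear coefficient
            return float(self.coefficients.get(1, 0.0))
        return self.stress(strain) / strain


@dataclass(frozen=True)
class UniformPM:
    """Uniform distribution written ``mean ± halfwidth``.

    Samples lie in ``[mean − halfwidth, mean + halfwidth]``.  For strain-like
    quantities the lower support bound must be non-negative.
    """

    mean: float
    halfwidth: float = 0.0

    def __post_init__(self) -> None:
        if self.halfwidth < 0:
            raise ValueError(f"halfwidth must be >= 0, got {self.halfwidth}")
        if self.mean - self.halfwidth < 0:
            raise ValueError(
                f"support must be non-negative: mean - halfwidth = {self.mean - self.halfwidth}"
            )

    @property
    def low(self) -> float:
        return self.mean - self.halfwidth

    @property
    def high(self) -> float:
        return self.mean + self.halfwidth

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError(f"sample size must be >= 1, got {n}")
        if self.halfwidth == 0:
            return np.full(n, self.mean)
        return rng.uniform(self.low, self.high, size=n)


def sample_pm(dist: UniformPM, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` values from ``dist`` with a fresh generator seeded by ``seed``.

    Identical ``(dist, n, seed)`` triples yield bit-identical samples.
    """
    return dist.sample(n, np.random.default_rng(seed))
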