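"""Thread configuration: schema, validation, I/O and bundle construction.

A configuration describes *groups* of identical elements (counts, relative
diameters, material laws, loop inventories, coupling) plus the global
simulation controls.  The shipped default is the 11-element *Kukulcania
hibernalis* capture-thread model: one stiff radial carrier line, two axial
fibres coupled to the undulating fibres, and eight looped meta-structures
(2 undulating + 6 paracribellar fibres, 200 loops each).

Files are plain YAML or JSON (YAML is a superset, both parse); ``save_config``
followed by ``load_config`` is an identity.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .bundle import Bundle
from .constitutive import ConstitutiveLaw, UniformPM
from .elements import Loop, LoopedElement, StraightElement

__all__ = [
    "ConfigError",
    "PMSpec",
    "LawSpec",
    "LoopSpec",
    "CouplingSpec",
    "ElementGroup",
    "ThreadConfig",
    "default_kukulcania_config",
    "load_config",
    "save_config",
    "build_bundle",
    "config_fingerprint",
]


class ConfigError(ValueError):
    """A configuration failed schema or referential validation."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PMSpec(_Model):
    """Uniform ``mean ± pm`` distribution (pm is the halfwidth)."""

    mean: float
    pm: float = 0.0

    @model_validator(mode="after")
    def _support(self) -> "PMSpec":
        if self.pm < 0:
            raise ValueError("pm must be >= 0")
        if self.mean - self.pm < 0:
            raise ValueError("support must be non-negative (mean - pm < 0)")
        return self

    def to_dist(self) -> UniformPM:
        return UniformPM(self.mean, self.pm)


class _LinearParams(_Model):
    E: float = Field(gt=0, description="Young's modulus in GPa")


class LawSpec(_Model):
    """Material law: ``{"linear": {"E": 7}}`` or ``{"poly": {"c1": 0.1, "c3": 5}}``."""

    linear: Optional[_LinearParams] = None
    poly: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _exactly_one(self) -> "LawSpec":
        if (self.linear is None) == (self.poly is None):
            raise ValueError("specify exactly one of 'linear' or 'poly'")
        if self.poly is not None:
            for key, coeff in self.poly.items():
                if not key.startswith("c") or not key[1:].isdigit() or int(key[1:]) % 2 == 0:
                    raise ValueError(f"poly keys must be 'c<odd degree>', got {key!r}")
                if coeff < 0:
                    raise ValueError(f"poly coefficient {key} must be non-negative")
        return self

    def to_law(self) -> ConstitutiveLaw:
        if self.linear is not None:
            return ConstitutiveLaw.linear(self.linear.E)
        assert self.poly is not None
        return ConstitutiveLaw({int(k[1:]): v for k, v in self.poly.items()})


class LoopSpec(_Model):
    """Loop inventory per fibre: count plus threshold/hidden-length distributions."""

    count: int = Field(ge=0)
    threshold: PMSpec
    hidden_length: PMSpec


class CouplingSpec(_Model):
    """Hierarchical slack reception from looped source groups, scaled by Cs."""

    sources: list[str] = Field(min_length=1)
    cs: float = Field(gt=0, le=1)


class ElementGroup(_Model):
    name: str
    count: int = Field(ge=1)
    rel_diameter: float = Field(gt=0)
    law: LawSpec
    critical_strain: Union[float, PMSpec, None] = None
    loops: Optional[LoopSpec] = None
    coupling: Optional[CouplingSpec] = None

    @model_validator(mode="after")
    def _consistent(self) -> "ElementGroup":
        if self.loops is None and self.critical_strain is None:
            raise ValueError(f"group {self.name!r}: straight groups need a critical_strain")
        if isinstance(self.critical_strain, float) and self.critical_strain <= 0:
            raise ValueError(f"group {self.name!r}: critical_strain must be > 0")
        return self


class ThreadConfig(_Model):
    """Full model configuration: element groups plus global simulation controls."""

    groups: list[ElementGroup] = Field(min_length=1)
    dx: float = Field(default=0.005, gt=0)
    x_max: float = Field(default=50.0, gt=0)
    slack_mode: Literal["reset", "hidden_only"] = "reset"
    post_loop_critical_strain: float = Field(default=0.5, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _referential(self) -> "ThreadConfig":
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate group names: {sorted({n for n in names if names.count(n) > 1})}")
        looped = {g.name for g in self.groups if g.loops is not None}
        for g in self.groups:
            if g.coupling is not None:
                for src in g.coupling.sources:
                    if src not in names:
                        raise ValueError(f"group {g.name!r}: coupling source {src!r} does not exist")
                    if src not in looped:
                        raise ValueError(
                            f"group {g.name!r}: coupling source {src!r} is not a looped group"
                        )
        return self


def default_kukulcania_config() -> ThreadConfig:
    """The default *K. hibernalis* capture-thread model (11 parallel elements).

    Groups: 1 radial (linear 7 GPa, fails at 20% strain), 2 axial
    (``σ = 0.1·ε + 5·ε³``, fail at 50%, coupled to the undulating fibres with
    Cs = 0.999), 2 undulating and 6 paracribellar fibres (linear 7 GPa,
    200 loops each, opening thresholds uniform 0.150 ± 0.145, hidden lengths
    uniform 0.038 ± 0.002).
    """
    loop_spec = LoopSpec(
        count=200,
        threshold=PMSpec(mean=0.150, pm=0.145),
        hidden_length=PMSpec(mean=0.038, pm=0.002),
    )
    return ThreadConfig(
        groups=[
            ElementGroup(
                name="ra",
                count=1,
                rel_diameter=1.0,
                law=LawSpec(linear=_LinearParams(E=7.0)),
                critical_strain=0.2,
            ),
            ElementGroup(
                name="ax",
                count=2,
                rel_diameter=0.2,
                law=LawSpec(poly={"c1": 0.1, "c3": 5.0}),
                critical_strain=0.5,
                coupling=CouplingSpec(sources=["uf"], cs=0.999),
            ),
            ElementGroup(
                name="uf",
                count=2,
                rel_diameter=0.175,
                law=LawSpec(linear=_LinearParams(E=7.0)),
                loops=loop_spec,
            ),
            ElementGroup(
                name="pc",
                count=6,
                rel_diameter=0.035,
                law=LawSpec(linear=_LinearParams(E=7.0)),
                loops=loop_spec,
            ),
        ]
    )


def _dump(config: ThreadConfig) -> dict:
    return config.model_dump(exclude_none=True)


def load_config(path: str | Path) -> ThreadConfig:
    """Load a YAML or JSON configuration file; schema errors carry field paths."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        return ThreadConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"{path}: invalid configuration:\n{exc}") from exc


def save_config(config: ThreadConfig, path: str | Path) -> None:
    """Write a configuration as JSON (``.json``) or YAML (anything else)."""
    path = Path(path)
    data = _dump(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def config_fingerprint(config: ThreadConfig) -> str:
    """Stable short hash of the canonicalized configuration."""
    blob = json.dumps(_dump(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# substream codes so threshold / hidden-length / critical-strain draws are
# independent: changing one stream never shifts another
_Q_THRESHOLD, _Q_HIDDEN, _Q_CRITICAL = 0, 1, 2


def _rng(seed: int, group_index: int, fibre_index: int, quantity: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(group_index, fibre_index, quantity))
    return np.random.default_rng(ss)


def build_bundle(config: ThreadConfig, seed: Optional[int] = None) -> Bundle:
    """Expand the configuration into a concrete :class:`Bundle`.

    Per-loop thresholds and hidden lengths and per-element critical strains
    are sampled from independent substreams keyed by (seed, group, fibre,
    quantity), so the expansion is deterministic given (config, seed).
    ``seed=None`` uses the config's own seed.
    """
    if seed is None:
        seed = config.seed
    group_elements: dict[str, list[str]] = {}
    elements = []
    for gi, group in enumerate(config.groups):
        group_elements[group.name] = []
        for fi in range(group.count):
            eid = f"{group.name}{fi + 1}"
            group_elements[group.name].append(eid)
            crit = group.critical_strain
            if isinstance(crit, PMSpec):
                crit = float(crit.to_dist().sample(1, _rng(seed, gi, fi, _Q_CRITICAL))[0])
            law = group.law.to_law()
            if group.loops is not None:
                n = group.loops.count
                if n > 0:
                    thresholds = group.loops.threshold.to_dist().sample(
                        n, _rng(seed, gi, fi, _Q_THRESHOLD)
                    )
                    lengths = group.loops.hidden_length.to_dist().sample(
                        n, _rng(seed, gi, fi, _Q_HIDDEN)
                    )
                    loops = [Loop(t, l) for t, l in zip(thresholds, lengths)]
                else:
                    loops = []  # zero-loop group: behaves as a straight fibre
                elem = LoopedElement(
                    id=eid,
                    rel_diameter=group.rel_diameter,
                    law=law,
                    loops=loops,
                    post_loop_critical_strain=(
                        crit if crit is not None else config.post_loop_critical_strain
                    ),
                    slack_mode=config.slack_mode,
                )
            else:
                elem = StraightElement(
                    id=eid,
                    rel_diameter=group.rel_diameter,
                    law=law,
                    critical_strain=crit,
                )
            elements.append((elem, group))
    # resolve group-level coupling into element ids now that all ids exist
    out = []
    for elem, group in elements:
        if group.coupling is not None:
            src_ids = [eid for s in group.coupling.sources for eid in group_elements[s]]
            elem.coupling_sources = tuple(src_ids)
            elem.cs = group.coupling.cs
        out.append(elem)
    return Bundle(out)
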