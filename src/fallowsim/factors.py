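"""Uncertain model factors: probability specs and inverse-CDF sampling.

The enrollment model has nine uncertain inputs. Three are farmer-level
demographics estimated from survey data (RETIREMENT, PRODUCTION, TENURE,
given as discrete weighted distributions), the rest are institutional or
behavioral knobs with uniform uncertainty (neighborhood extent DE, decision
rule OWA, parcel fraction LAND, bid rate BID, benefit-index layer EBI, and
the annual acceptance cap n).

Every factor is sampled through its inverse CDF from a coordinate of a
quasi-random point in the unit hypercube, so the same machinery serves both
plain Monte Carlo and the Saltelli sensitivity design.  Discrete inverse
CDFs use right-open cumulative intervals (u in [0, p1) maps to the first
value); continuous (lo, hi] supports map u=0 to lo + eps*(hi-lo) so the
open bound is never returned.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "FactorSpec",
    "FactorVector",
    "DISCRETE_WEIGHTED",
    "DISCRETE_UNIFORM",
    "CONTINUOUS_UNIFORM",
    "CATEGORICAL",
    "make_default_factors",
    "inverse_cdf",
    "fix_factor",
    "free_factors",
    "transform_row",
    "factor_median",
    "factor_mean",
    "factor_midpoint",
    "save_factors",
    "load_factors",
    "FACTOR_ORDER",
]

DISCRETE_WEIGHTED = "discrete-weighted"
DISCRETE_UNIFORM = "discrete-uniform-range"
CONTINUOUS_UNIFORM = "continuous-uniform"
CATEGORICAL = "categorical"

_DISCRETE_KINDS = {DISCRETE_WEIGHTED, DISCRETE_UNIFORM, CATEGORICAL}
_KINDS = _DISCRETE_KINDS | {CONTINUOUS_UNIFORM}

#: epsilon used to realize the open lower bound of (lo, hi] supports
_EPS = 1e-12

#: canonical factor order used throughout the package
FACTOR_ORDER = (
    "RETIREMENT",
    "PRODUCTION",
    "TENURE",
    "DE",
    "OWA",
    "LAND",
    "BID",
    "EBI",
    "n",
)


@dataclass(frozen=True)
class FactorSpec:
    """One uncertain input: its name, distribution kind and support.

    ``support`` is an ordered tuple of values for the discrete kinds and a
    ``(lo, hi)`` pair (interpreted as the half-open interval ``(lo, hi]``)
    for ``continuous-uniform``.  ``probabilities`` is required for
    ``discrete-weighted`` and implied equiprobable otherwise.  A
    ``fixed_value`` overrides sampling entirely (used for model
    simplification).
    """

    name: str
    kind: str
    support: tuple
    probabilities: tuple | None = None
    fixed_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown factor kind {self.kind!r}")
        object.__setattr__(self, "support", tuple(self.support))
        if self.probabilities is not None:
            object.__setattr__(self, "probabilities", tuple(self.probabilities))
        if self.kind == CONTINUOUS_UNIFORM:
            lo, hi = self.support
            if not lo < hi:
                raise ValueError(f"{self.name}: need lo < hi, got {self.support}")
            if self.probabilities is not None:
                raise ValueError(f"{self.name}: continuous factors carry no masses")
        else:
            vals = self.support
            if len(vals) == 0:
                raise ValueError(f"{self.name}: empty support")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{self.name}: support must be strictly increasing")
            p = self.masses
            if any(x < 0 for x in p):
                raise ValueError(f"{self.name}: negative probability mass")
            if abs(sum(p) - 1.0) > 1e-12:
                raise ValueError(f"{self.name}: masses sum to {sum(p)}, not 1")
        if self.fixed_value is not None and not self.contains(self.fixed_value):
            raise ValueError(
                f"{self.name}: fixed value {self.fixed_value} outside support"
            )

    @property
    def masses(self) -> tuple:
        """Probability masses; equiprobable for unweighted discrete kinds."""
        if self.kind == CONTINUOUS_UNIFORM:
            raise ValueError(f"{self.name}: continuous factor has no masses")
        if self.probabilities is not None:
            return self.probabilities
        m = len(self.support)
        return tuple([1.0 / m] * m)

    @property
    def is_fixed(self) -> bool:
        return self.fixed_value is not None

    def contains(self, value) -> bool:
        if self.kind == CONTINUOUS_UNIFORM:
            lo, hi = self.support
            return lo < value <= hi
        return any(math.isclose(value, v, rel_tol=0, abs_tol=1e-9) for v in self.support)

    def to_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind, "support": list(self.support)}
        if self.probabilities is not None:
            d["probabilities"] = list(self.probabilities)
        if self.fixed_value is not None:
            d["fixed_value"] = self.fixed_value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FactorSpec":
        return cls(
            name=d["name"],
            kind=d["kind"],
            support=tuple(d["support"]),
            probabilities=tuple(d["probabilities"]) if "probabilities" in d else None,
            fixed_value=d.get("fixed_value"),
        )


@dataclass(frozen=True)
class FactorVector:
    """A sampled point: unit-hypercube coordinates of the free factors and
    the transformed values of all factors (fixed factors at their constants).
    """

    u: tuple
    values: dict
    free_names: tuple

    def __post_init__(self) -> None:
        if len(self.u) != len(self.free_names):
            raise ValueError("u and free_names must have equal length")


def make_default_factors() -> list[FactorSpec]:
    """The nine model factors with their survey- and program-derived
    probability distributions.

    RETIREMENT: operator retired (0) vs working (1), D={(0,.06),(1,.94)}.
    PRODUCTION: normalized total value of production,
        D={(0,0),(.2,.06),(.4,.06),(.6,.11),(.8,.15),(1,.62)} — the zero-mass
        atom at 0 is retained verbatim and can never be drawn.
    TENURE: ratio of owned to operated acres,
        D={(0,.04),(.2,.14),(.4,.18),(.6,.14),(.8,.15),(1,.35)}.
    DE: neighborhood radius for enrollment density, 500–1500 m step 100 m.
    OWA: decision rule, 17 equiprobable rules indexed 0..16 by descending
        orness (0 = most OR-like / risk-taking, 16 = most AND-like).
    LAND: fraction of parcel offered, continuous uniform on (0, 1].
    BID: voluntary payment reduction, 0–16 % in 1 % steps.
    EBI: which of the six benefit-index layers is in force, equiprobable.
    n: offers accepted annually by the agency, 18–28 step 1, equiprobable.
    """
    return [
        FactorSpec("RETIREMENT", DISCRETE_WEIGHTED, (0, 1), (0.06, 0.94)),
        FactorSpec(
            "PRODUCTION",
            DISCRETE_WEIGHTED,
            (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
            (0.0, 0.06, 0.06, 0.11, 0.15, 0.62),
        ),
        FactorSpec(
            "TENURE",
            DISCRETE_WEIGHTED,
            (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
            (0.04, 0.14, 0.18, 0.14, 0.15, 0.35),
        ),
        FactorSpec("DE", DISCRETE_UNIFORM, tuple(range(500, 1501, 100))),
        FactorSpec("OWA", CATEGORICAL, tuple(range(17))),
        FactorSpec("LAND", CONTINUOUS_UNIFORM, (0.0, 1.0)),
        FactorSpec(
            "BID", DISCRETE_UNIFORM, tuple(round(0.01 * i, 2) for i in range(17))
        ),
        FactorSpec("EBI", CATEGORICAL, tuple(range(6))),
        FactorSpec("n", DISCRETE_UNIFORM, tuple(range(18, 29))),
    ]


def inverse_cdf(spec: FactorSpec, u: float):
    """Transform a unit-interval coordinate into a factor value.

    Discrete kinds return the first support value whose cumulative mass
    strictly exceeds ``u`` (right-open intervals); continuous-uniform
    returns ``lo + u*(hi-lo)`` with u=0 nudged by eps to respect the open
    lower bound.
    """
    if spec.is_fixed:
        raise ValueError(f"{spec.name} is fixed; sampling it is a misuse")
    if not (0.0 <= u < 1.0):
        raise ValueError(f"u={u} outside [0, 1)")
    if spec.kind == CONTINUOUS_UNIFORM:
        lo, hi = spec.support
        return lo + max(u, _EPS) * (hi - lo)
    cum = np.cumsum(spec.masses)
    idx = int(np.searchsorted(cum, u, side="right"))
    idx = min(idx, len(spec.support) - 1)  # guard float roundoff at u->1
    return spec.support[idx]


def inverse_cdf_array(spec: FactorSpec, u: np.ndarray) -> np.ndarray:
    """Vectorized :func:`inverse_cdf` (no fixed-spec or range checks skipped)."""
    if spec.is_fixed:
        raise ValueError(f"{spec.name} is fixed; sampling it is a misuse")
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u >= 1)):
        raise ValueError("u outside [0, 1)")
    if spec.kind == CONTINUOUS_UNIFORM:
        lo, hi = spec.support
        return lo + np.maximum(u, _EPS) * (hi - lo)
    cum = np.cumsum(spec.masses)
    idx = np.minimum(
        np.searchsorted(cum, u, side="right"), len(spec.support) - 1
    )
    return np.asarray(spec.support, dtype=float)[idx]


def fix_factor(specs: Sequence[FactorSpec], name: str, value) -> list[FactorSpec]:
    """Return a new spec list with ``name`` pinned to ``value``."""
    names = [s.name for s in specs]
    if name not in names:
        raise KeyError(f"unknown factor {name!r}")
    out = []
    for s in specs:
        if s.name == name:
            if not s.contains(value):
                raise ValueError(f"{name}: value {value} outside support")
            out.append(dataclasses.replace(s, fixed_value=value))
        else:
            out.append(s)
    return out


def free_factors(specs: Sequence[FactorSpec]) -> list[FactorSpec]:
    return [s for s in specs if not s.is_fixed]


def transform_row(specs: Sequence[FactorSpec], u_row: Sequence[float]) -> FactorVector:
    """Map a unit-hypercube row (one coordinate per *free* factor, in spec
    order) to a full factor-value assignment."""
    free = free_factors(specs)
    u_row = tuple(float(x) for x in u_row)
    if len(u_row) != len(free):
        raise ValueError(f"expected {len(free)} coordinates, got {len(u_row)}")
    values = {}
    it = iter(u_row)
    for s in specs:
        values[s.name] = s.fixed_value if s.is_fixed else inverse_cdf(s, next(it))
    return FactorVector(u=u_row, values=values, free_names=tuple(s.name for s in free))


def factor_median(spec: FactorSpec):
    """Distribution median: inverse CDF at 0.5 (midpoint for continuous)."""
    if spec.kind == CONTINUOUS_UNIFORM:
        lo, hi = spec.support
        return (lo + hi) / 2.0
    cum = np.cumsum(spec.masses)
    idx = int(np.searchsorted(cum, 0.5, side="left"))
    return spec.support[min(idx, len(spec.support) - 1)]


def factor_mean(spec: FactorSpec):
    if spec.kind == CONTINUOUS_UNIFORM:
        lo, hi = spec.support
        return (lo + hi) / 2.0
    return float(np.dot(spec.support, spec.masses))


def factor_midpoint(spec: FactorSpec):
    """Support midpoint used when refining the dominant factor: the middle
    element of an ordered discrete support, the interval midpoint otherwise."""
    if spec.kind == CONTINUOUS_UNIFORM:
        lo, hi = spec.support
        return (lo + hi) / 2.0
    return spec.support[len(spec.support) // 2]


def save_factors(specs: Sequence[FactorSpec], path) -> None:
    """Serialize a factor space to YAML or JSON (by file extension)."""
    path = Path(path)
    doc = {"factors": [s.to_dict() for s in specs]}
    if path.suffix in {".yml", ".yaml"}:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2))


def load_factors(path) -> list[FactorSpec]:
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
    return [FactorSpec.from_dict(d) for d in doc["factors"]]
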