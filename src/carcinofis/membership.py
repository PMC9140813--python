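"""Membership functions, linguistic variables and fuzzification.

A *linguistic variable* (e.g. ``age``) owns a numeric universe of discourse and
an ordered set of labelled fuzzy terms (``Low``/``Average``/``High``), each
realised as a parameterized membership function. Fuzzification maps a crisp
input value to its degree of membership, in ``[0, 1]``, in every term.

Supported shapes
----------------
triangular ``(a, b, c)``
    Piecewise-linear ramp up on ``[a, b]`` and down on ``[b, c]``. Degenerate
    feet (``a == b`` or ``b == c``) are permitted and yield a vertical edge
    with degree 1 at the peak, so saturating "shoulder" terms at a universe
    edge can be expressed.
trapezoidal ``(a, b, c, d)``
    Ramp up on ``[a, b]``, plateau of 1 on ``[b, c]``, ramp down on ``[c, d]``;
    degenerate edges as for triangles.
gaussian ``(mean, sigma)``
    ``exp(-(x - mean)^2 / (2 sigma^2))``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple, Union

import numpy as np

from .errors import ConfigurationError, InvalidInputError

_log = logging.getLogger(__name__)

SHAPES = ("triangular", "trapezoidal", "gaussian")

ArrayLike = Union[float, np.ndarray]


def _as_finite_array(x: ArrayLike) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"membership evaluation requires finite input, got {x!r}")
    return arr


@dataclass(frozen=True)
class Universe:
    """The admissible numeric range of a variable.

    ``resolution`` is the number of evenly spaced grid points (both bounds
    included) used whenever a fuzzy set on this universe is discretized.
    """

    name: str
    lower: float
    upper: float
    resolution: int = 1001

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ConfigurationError(f"universe {self.name!r}: bounds must be finite")
        if not self.lower < self.upper:
            raise ConfigurationError(
                f"universe {self.name!r}: lower ({self.lower}) must be < upper ({self.upper})"
            )
        if int(self.resolution) != self.resolution or self.resolution < 2:
            raise ConfigurationError(
                f"universe {self.name!r}: resolution must be an integer >= 2"
            )

    def grid(self) -> np.ndarray:
        """Evenly spaced sample points, both bounds included."""
        return np.linspace(self.lower, self.upper, self.resolution)

    def clamp(self, x: float) -> float:
        """Clamp a crisp value to the universe bounds, logging a warning."""
        x = float(x)
        if not np.isfinite(x):
            raise InvalidInputError(f"{self.name}: crisp input must be finite, got {x!r}")
        if x < self.lower or x > self.upper:
            clamped = min(max(x, self.lower), self.upper)
            _log.warning(
                "%s: input %g outside universe [%g, %g]; clamped to %g",
                self.name, x, self.lower, self.upper, clamped,
            )
            return clamped
        return x


@dataclass(frozen=True)
class MembershipFunction:
    """A labelled fuzzy term: a shape plus its parameters."""

    term: str
    shape: str
    params: Tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.shape not in SHAPES:
            raise ConfigurationError(
                f"term {self.term!r}: unknown shape {self.shape!r}; expected one of {SHAPES}"
            )
        p = self.params
        if self.shape == "triangular":
            if len(p) != 3:
                raise ConfigurationError(f"term {self.term!r}: triangular needs 3 params (a, b, c)")
            a, b, c = p
            if not (a <= b <= c) or not a < c:
                raise ConfigurationError(
                    f"term {self.term!r}: triangular params must satisfy a <= b <= c, a < c; got {p}"
                )
        elif self.shape == "trapezoidal":
            if len(p) != 4:
                raise ConfigurationError(
                    f"term {self.term!r}: trapezoidal needs 4 params (a, b, c, d)"
                )
            a, b, c, d = p
            if not (a <= b <= c <= d) or not a < d:
                raise ConfigurationError(
                    f"term {self.term!r}: trapezoidal params must satisfy "
                    f"a <= b <= c <= d, a < d; got {p}"
                )
        else:  # gaussian
            if len(p) != 2:
                raise ConfigurationError(f"term {self.term!r}: gaussian needs 2 params (mean, sigma)")
            if p[1] <= 0:
                raise ConfigurationError(f"term {self.term!r}: gaussian sigma must be > 0; got {p[1]}")

    def __call__(self, x: ArrayLike) -> ArrayLike:
        return eval_membership(self, x)


def eval_membership(mf: MembershipFunction, x: ArrayLike) -> ArrayLike:
    """Degree of membership of ``x`` in ``mf``, always in ``[0, 1]``.

    Accepts a scalar or an array; returns the matching type.
    """
    arr = _as_finite_array(x)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    p = mf.params
    # near-degenerate ramps may transiently overflow before the final clip
    with np.errstate(over="ignore"):
        if mf.shape == "triangular":
            a, b, c = p
            deg = np.minimum(_ramp_up(arr, a, b), _ramp_down(arr, b, c))
        elif mf.shape == "trapezoidal":
            a, b, c, d = p
            deg = np.minimum(_ramp_up(arr, a, b), _ramp_down(arr, c, d))
        else:
            mean, sigma = p
            deg = np.exp(-((arr - mean) ** 2) / (2.0 * sigma * sigma))
    deg = np.clip(deg, 0.0, 1.0)
    return float(deg[0]) if scalar else deg


def _ramp_up(x: np.ndarray, a: float, b: float) -> np.ndarray:
    # 0 left of a, 1 right of b; a == b gives a vertical edge (1 at x >= a).
    if a == b:
        return (x >= a).astype(float)
    return (x - a) / (b - a)


def _ramp_down(x: np.ndarray, c: float, d: float) -> np.ndarray:
    if c == d:
        return (x <= d).astype(float)
    return (d - x) / (d - c)


@dataclass(frozen=True)
class FuzzifiedValue:
    """A crisp input together with its degrees in every term of a variable."""

    variable: str
    crisp: float
    degrees: Dict[str, float] = field(default_factory=dict)

    def __getitem__(self, term: str) -> float:
        return self.degrees[term]


@dataclass(frozen=True)
class LinguisticVariable:
    """A universe of discourse plus its ordered, uniquely labelled term set."""

    universe: Universe
    terms: Tuple[MembershipFunction, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if len(self.terms) < 2:
            raise ConfigurationError(
                f"variable {self.name!r}: needs at least 2 terms, got {len(self.terms)}"
            )
        labels = [t.term for t in self.terms]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"variable {self.name!r}: duplicate term labels in {labels}")

    @property
    def name(self) -> str:
        return self.universe.name

    @property
    def term_labels(self) -> Tuple[str, ...]:
        return tuple(t.term for t in self.terms)

    def term(self, label: str) -> MembershipFunction:
        for t in self.terms:
            if t.term == label:
                return t
        raise ConfigurationError(f"variable {self.name!r} has no term {label!r}")

    def fuzzify(self, x: float) -> FuzzifiedValue:
        return fuzzify(self, x)

    def covers_universe(self) -> bool:
        """True if every grid point has degree > 0 in at least one term.

        Input variables of a well-formed system should satisfy this (no "dead
        zone" where no rule can fire). Output variables may legitimately not:
        the default diagnostic output deliberately uses non-overlapping terms.
        """
        grid = self.universe.grid()
        total = np.zeros_like(grid)
        for t in self.terms:
            total = np.maximum(total, eval_membership(t, grid))
        return bool(np.all(total > 0.0))


def fuzzify(var: LinguisticVariable, x: float) -> FuzzifiedValue:
    """Map a crisp value to its membership degree in every term of ``var``.

    Out-of-universe values are clamped to the nearest bound (with a logged
    warning); fuzzification is therefore idempotent under clamping.
    """
    clamped = var.universe.clamp(x)
    degrees = {t.term: float(eval_membership(t, clamped)) for t in var.terms}
    return FuzzifiedValue(variable=var.name, crisp=float(x), degrees=degrees)


def discretize(obj, universe: Universe):
    """Sample a membership function (or every term of a variable) on a universe grid.

    Returns ``(grid, degrees)`` where ``degrees`` is an array for a single
    membership function or a ``{label: array}`` mapping for a variable.
    Gaussian terms are simply truncated at the universe bounds (no
    renormalization), matching discretized-toolbox behavior.
    """
    grid = universe.grid()
    if isinstance(obj, MembershipFunction):
        return grid, np.asarray(eval_membership(obj, grid))
    if isinstance(obj, LinguisticVariable):
        return grid, {t.term: np.asarray(eval_membership(t, grid)) for t in obj.terms}
    raise ConfigurationError(f"cannot discretize object of type {type(obj).__name__}")
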