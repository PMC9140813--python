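"""Mamdani inference: rule evaluation, implication, aggregation, defuzzification.

The engine follows the classical max–min scheme. Each rule's antecedent
clauses are combined with AND (minimum) or OR (maximum); the firing strength
is scaled multiplicatively by the rule weight; the consequent term is clipped
(min-implication) at the weighted strength; all clipped consequents are
aggregated pointwise on the output grid; and the aggregate set is collapsed
to a crisp number.

Aggregation methods
-------------------
maximum
    pointwise ``max`` (the default; pointwise-dominated by the others)
probabilistic_or
    ``a ⊕ b = a + b - a·b``, folded left-associatively (it is associative,
    so the fold order is immaterial)
bounded_sum
    ``min(1, Σ)``

Defuzzification methods
-----------------------
centroid (default)
    centre of gravity ``∫ μ(x)·x dx / ∫ μ(x) dx`` approximated with
    trapezoidal weights on the fixed output grid
bisector
    first grid point at which the cumulative area reaches half the total
middle_of_maximum / smallest_of_maximum / largest_of_maximum
    taken from the argmax plateau (ties detected with tolerance 1e-9);
    middle_of_maximum is the mean of the plateau endpoints
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigurationError, InvalidInputError, NoRuleFiredError
from .membership import (
    FuzzifiedValue,
    LinguisticVariable,
    MembershipFunction,
    discretize,
    fuzzify,
)

AGGREGATION_METHODS = ("maximum", "probabilistic_or", "bounded_sum")
DEFUZZIFICATION_METHODS = (
    "centroid",
    "bisector",
    "middle_of_maximum",
    "largest_of_maximum",
    "smallest_of_maximum",
)
_MAX_TIE_TOL = 1e-9


@dataclass(frozen=True)
class RuleClause:
    """One antecedent atom: ``<variable> is [not] <term>``."""

    variable: str
    term: str
    negated: bool = False

    def __str__(self) -> str:
        rel = "is not" if self.negated else "is"
        return f"({self.variable} {rel} {self.term})"


@dataclass(frozen=True)
class FuzzyRule:
    """A weighted IF–THEN rule with AND/OR-joined antecedent clauses."""

    antecedent: Tuple[RuleClause, ...]
    consequent_term: str
    weight: float = 1.0
    connective: str = "and"

    def __post_init__(self) -> None:
        object.__setattr__(self, "antecedent", tuple(self.antecedent))
        if not self.antecedent:
            raise ConfigurationError("rule antecedent must be non-empty")
        variables = [c.variable for c in self.antecedent]
        if len(set(variables)) != len(variables):
            raise ConfigurationError(
                f"rule references a variable twice in its antecedent: {variables}"
            )
        if self.connective not in ("and", "or"):
            raise ConfigurationError(f"rule connective must be 'and' or 'or', got {self.connective!r}")
        if not 0.0 <= self.weight <= 1.0:
            raise ConfigurationError(f"rule weight must be in [0, 1], got {self.weight}")

    def __str__(self) -> str:
        joint = f" {self.connective} "
        body = joint.join(str(c) for c in self.antecedent)
        return f"If {body} then (prob_carcinomatosis is {self.consequent_term}) ({self.weight:g})"


@dataclass(frozen=True)
class InferenceSettings:
    """Inference-stage configuration. AND and implication are fixed to min."""

    and_method: str = "min"
    implication: str = "min"
    aggregation: str = "maximum"
    defuzzification: str = "centroid"

    def __post_init__(self) -> None:
        if self.and_method != "min":
            raise ConfigurationError("only and_method='min' is supported")
        if self.implication != "min":
            raise ConfigurationError("only implication='min' is supported")
        if self.aggregation not in AGGREGATION_METHODS:
            raise ConfigurationError(
                f"aggregation must be one of {AGGREGATION_METHODS}, got {self.aggregation!r}"
            )
        if self.defuzzification not in DEFUZZIFICATION_METHODS:
            raise ConfigurationError(
                f"defuzzification must be one of {DEFUZZIFICATION_METHODS}, "
                f"got {self.defuzzification!r}"
            )


@dataclass(frozen=True)
class RuleActivation:
    """Per-rule record in an inference trace."""

    rule: FuzzyRule
    strength: float          # firing strength α of the antecedent
    weighted_strength: float  # α × weight, applied before implication
    clipped: np.ndarray       # min-implication of the consequent on the output grid


@dataclass(frozen=True)
class InferenceTrace:
    """Full record of one inference: a roadmap from crisp inputs to crisp output."""

    fuzzified: Dict[str, FuzzifiedValue]
    activations: Tuple[RuleActivation, ...]
    grid: np.ndarray
    aggregate: np.ndarray
    crisp_output: float

    def report(self) -> str:
        """Plain-text per-rule firing table (index, antecedent, α, w, α·w)."""
        lines = ["  #  alpha  weight  alpha*w  rule"]
        for i, act in enumerate(self.activations, start=1):
            lines.append(
                f"{i:>3}  {act.strength:5.3f}  {act.rule.weight:6.3f}  "
                f"{act.weighted_strength:7.3f}  {act.rule}"
            )
        lines.append(f"crisp output: {self.crisp_output:.4f}")
        return "\n".join(lines)


def firing_strength(rule: FuzzyRule, fuzzified: Mapping[str, FuzzifiedValue]) -> float:
    """Antecedent truth degree α: min (AND) or max (OR) over clause degrees."""
    degrees = []
    for clause in rule.antecedent:
        if clause.variable not in fuzzified:
            raise ConfigurationError(f"rule clause references unfuzzified variable {clause.variable!r}")
        fv = fuzzified[clause.variable]
        if clause.term not in fv.degrees:
            raise ConfigurationError(
                f"rule clause references unknown term {clause.term!r} of variable {clause.variable!r}"
            )
        d = fv.degrees[clause.term]
        degrees.append(1.0 - d if clause.negated else d)
    return float(min(degrees) if rule.connective == "and" else max(degrees))


def implicate(consequent_sampled: np.ndarray, strength: float) -> np.ndarray:
    """Mamdani min-implication: clip the sampled consequent at ``strength``."""
    if not 0.0 <= strength <= 1.0:
        raise InvalidInputError(f"implication strength must be in [0, 1], got {strength}")
    return np.minimum(np.asarray(consequent_sampled, dtype=float), strength)


def aggregate(clipped_sets: Sequence[np.ndarray], method: str = "maximum") -> np.ndarray:
    """Pointwise combination of clipped consequent sets sampled on one grid."""
    if method not in AGGREGATION_METHODS:
        raise ConfigurationError(f"unknown aggregation method {method!r}")
    sets = [np.asarray(s, dtype=float) for s in clipped_sets]
    if not sets:
        raise ConfigurationError("aggregate requires at least one clipped set")
    shape = sets[0].shape
    if any(s.shape != shape for s in sets):
        raise ConfigurationError("all clipped sets must be sampled on the identical grid")
    out = np.zeros(shape)
    for s in sets:
        if method == "maximum":
            out = np.maximum(out, s)
        elif method == "probabilistic_or":
            out = out + s - out * s
        else:  # bounded_sum
            out = out + s
    if method == "bounded_sum":
        out = np.minimum(out, 1.0)
    return out


def defuzzify(grid: np.ndarray, mu: np.ndarray, method: str = "centroid") -> float:
    """Collapse a sampled aggregate set to a crisp number.

    Raises :class:`NoRuleFiredError` if the set is identically zero.
    """
    if method not in DEFUZZIFICATION_METHODS:
        raise ConfigurationError(f"unknown defuzzification method {method!r}")
    grid = np.asarray(grid, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if grid.shape != mu.shape or grid.ndim != 1:
        raise ConfigurationError("grid and membership arrays must be 1-D and the same length")
    if not np.any(mu > 0.0):
        raise NoRuleFiredError(
            "aggregate output set is identically zero: no rule fired for this input"
        )
    if method == "centroid":
        area = np.trapezoid(mu, grid)
        moment = np.trapezoid(mu * grid, grid)
        return float(moment / area)
    if method == "bisector":
        cum = cumulative_trapezoid(mu, grid, initial=0.0)
        half = cum[-1] / 2.0
        idx = int(np.searchsorted(cum, half))
        return float(grid[min(idx, grid.size - 1)])
    peak = float(np.max(mu))
    plateau = np.flatnonzero(mu >= peak - _MAX_TIE_TOL)
    if method == "smallest_of_maximum":
        return float(grid[plateau[0]])
    if method == "largest_of_maximum":
        return float(grid[plateau[-1]])
    # middle_of_maximum: mean of the plateau endpoints
    return float((grid[plateau[0]] + grid[plateau[-1]]) / 2.0)


@dataclass(frozen=True)
class FuzzySystem:
    """A complete Mamdani system: input variables, output variable, rule base."""

    inputs: Tuple[LinguisticVariable, ...]
    output: LinguisticVariable
    rules: Tuple[FuzzyRule, ...]
    settings: InferenceSettings = field(default_factory=InferenceSettings)

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "rules", tuple(self.rules))
        names = [v.name for v in self.inputs]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate input variable names: {names}")
        if self.output.name in names:
            raise ConfigurationError("output variable name collides with an input")
        by_name = {v.name: v for v in self.inputs}
        out_terms = set(self.output.term_labels)
        for i, rule in enumerate(self.rules, start=1):
            for clause in rule.antecedent:
                if clause.variable not in by_name:
                    raise ConfigurationError(
                        f"rule {i}: unknown input variable {clause.variable!r}"
                    )
                if clause.term not in by_name[clause.variable].term_labels:
                    raise ConfigurationError(
                        f"rule {i}: variable {clause.variable!r} has no term {clause.term!r}"
                    )
            if rule.consequent_term not in out_terms:
                raise ConfigurationError(
                    f"rule {i}: output has no term {rule.consequent_term!r}"
                )

    @property
    def input_names(self) -> Tuple[str, ...]:
        return tuple(v.name for v in self.inputs)

    def input(self, name: str) -> LinguisticVariable:
        for v in self.inputs:
            if v.name == name:
                return v
        raise ConfigurationError(f"system has no input variable {name!r}")

    def _consequent_samples(self) -> Dict[str, np.ndarray]:
        # Cached discretized output terms (the grid is fixed by the output universe).
        cache = getattr(self, "_cons_cache", None)
        if cache is None:
            _, sampled = discretize(self.output, self.output.universe)
            object.__setattr__(self, "_cons_cache", sampled)
            cache = sampled
        return cache

    def with_settings(self, **changes) -> "FuzzySystem":
        """Copy of the system with modified inference settings."""
        return replace(self, settings=replace(self.settings, **changes))

    def infer(self, inputs: Mapping[str, float]) -> InferenceTrace:
        return infer(self, inputs)


def infer(system: FuzzySystem, inputs: Mapping[str, float]) -> InferenceTrace:
    """Run the full Mamdani pipeline and return the complete trace.

    ``inputs`` must contain one finite crisp value per input variable.
    """
    missing = [n for n in system.input_names if n not in inputs]
    if missing:
        raise InvalidInputError(f"missing input variable(s): {missing}")
    fuzzified = {v.name: fuzzify(v, float(inputs[v.name])) for v in system.inputs}

    grid = system.output.universe.grid()
    consequents = system._consequent_samples()
    activations: List[RuleActivation] = []
    for rule in system.rules:
        alpha = firing_strength(rule, fuzzified)
        weighted = alpha * rule.weight
        clipped = implicate(consequents[rule.consequent_term], weighted)
        activations.append(RuleActivation(rule, alpha, weighted, clipped))

    agg = aggregate([a.clipped for a in activations], system.settings.aggregation)
    crisp = defuzzify(grid, agg, system.settings.defuzzification)
    return InferenceTrace(
        fuzzified=fuzzified,
        activations=tuple(activations),
        grid=grid,
        aggregate=agg,
        crisp_output=crisp,
    )
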