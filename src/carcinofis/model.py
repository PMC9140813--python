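"""The concrete carcinomatosis diagnostic system.

Five routine inputs — age (years), hemoglobin (g/dL), C-reactive protein
(mg/dL), platelet count (/mm³) and alkaline phosphatase (U/L) — map through a
weighted Mamdani rule base to a probability of peritoneal carcinomatosis in
colorectal-cancer patients.

The default membership parameters encode the published verbal anchors (e.g.
low age below 57 years; the high-risk age band 50–70 peaking at 60; CRP
pathological above ~5 mg/dL; PLT and ALP risky near/above the upper normal
limit) and are fully overridable through the FIS configuration. Edge terms
place a foot slightly outside the universe bound so that every in-universe
value retains positive membership in at least one term (no dead zones).

The rule base is generated combinatorially from an additive risk-point map:
18 three-antecedent rules over (age, hb, crp) plus 72 five-antecedent rules
over all five inputs. Each combination's normalized risk score selects the
consequent (Low / Average / High); combinations whose score falls close to a
decision threshold are demoted to weight 0.5, mirroring the published rules
where borderline combinations carry half weight.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .engine import FuzzyRule, FuzzySystem, InferenceSettings, InferenceTrace, RuleClause, infer
from .errors import ConfigurationError, InvalidInputError
from .membership import LinguisticVariable, MembershipFunction, Universe, discretize

INPUT_ORDER = ("age", "hb", "crp", "plt", "alp")
OUTPUT_NAME = "prob_carcinomatosis"

#: Crisp inputs of the published single-patient walk-through
#: (age 60 y, Hb 10.5 g/dL, CRP 15 mg/dL, PLT 4.66e5 /mm³, ALP 260 U/L).
WORKED_EXAMPLE: Dict[str, float] = {
    "age": 60.0,
    "hb": 10.5,
    "crp": 15.0,
    "plt": 4.66e5,
    "alp": 260.0,
}


@dataclass(frozen=True)
class PatientRecord:
    """One patient's five study parameters."""

    age: float   # years
    hb: float    # g/dL
    crp: float   # mg/dL
    plt: float   # /mm³
    alp: float   # U/L
    id: Optional[str] = None

    def __post_init__(self) -> None:
        for name in INPUT_ORDER:
            value = getattr(self, name)
            if value is None or not math.isfinite(float(value)):
                raise InvalidInputError(f"patient record {self.id!r}: {name} must be finite, got {value!r}")
            if float(value) <= 0:
                raise InvalidInputError(f"patient record {self.id!r}: {name} must be > 0, got {value!r}")

    def as_inputs(self) -> Dict[str, float]:
        return {name: float(getattr(self, name)) for name in INPUT_ORDER}


@dataclass(frozen=True)
class RiskScoreMap:
    """Additive risk points per (variable, term) plus decision thresholds.

    The normalized score of a term combination is ``s = points / max_points``
    (``max_points`` summed over the variables the rule actually uses). The
    consequent is Low for ``s < thresholds[0]``, High for ``s >= thresholds[1]``
    and Average in between; a combination with ``|s - nearest threshold| <=
    boundary_halfwidth`` gets weight 0.5 instead of 1.
    """

    points: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {
            "age": {"Low": 0, "Average": 1, "High": 2},
            "hb": {"Low": 0, "Average": 1, "High": 2},
            "crp": {"Low": 0, "High": 2},
            "plt": {"Normal": 0, "High": 2},
            "alp": {"Normal": 0, "High": 2},
        }
    )
    thresholds: Tuple[float, float] = (0.25, 0.65)
    boundary_halfwidth: float = 0.10
    labels: Tuple[str, str, str] = ("Low", "Average", "High")

    def __post_init__(self) -> None:
        lo, hi = self.thresholds
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError(f"thresholds must be strictly increasing in (0, 1), got {self.thresholds}")
        for var, terms in self.points.items():
            for term, pts in terms.items():
                if pts < 0:
                    raise ConfigurationError(f"risk points must be >= 0 ({var}.{term} = {pts})")

    def consequent(self, variables: Sequence[str], terms: Sequence[str]) -> Tuple[str, float]:
        """Consequent label and rule weight for one antecedent combination."""
        total = 0
        max_total = 0
        for var, term in zip(variables, terms):
            if var not in self.points or term not in self.points[var]:
                raise ConfigurationError(f"risk score map has no entry for {var!r} term {term!r}")
            total += self.points[var][term]
            max_total += max(self.points[var].values())
        s = total / max_total
        lo, hi = self.thresholds
        if s < lo:
            label = self.labels[0]
        elif s < hi:
            label = self.labels[1]
        else:
            label = self.labels[2]
        weight = 0.5 if min(abs(s - lo), abs(s - hi)) <= self.boundary_halfwidth else 1.0
        return label, weight


@dataclass(frozen=True)
class SurfaceGrid:
    """Crisp outputs over a 2-D sweep of two input variables."""

    var_x: str
    var_y: str
    x: np.ndarray
    y: np.ndarray
    values: np.ndarray  # shape (len(y), len(x)); values[i, j] = output at (x[j], y[i])
    fixed: Dict[str, float]


def default_variables(resolution: int = 1001) -> Tuple[Tuple[LinguisticVariable, ...], LinguisticVariable]:
    """The five default input variables and the output variable."""

    def tri(term, a, b, c):
        return MembershipFunction(term, "triangular", (a, b, c))

    def trap(term, a, b, c, d):
        return MembershipFunction(term, "trapezoidal", (a, b, c, d))

    age = LinguisticVariable(
        Universe("age", 30.0, 100.0, resolution),
        (
            tri("Low", 30.0, 30.0, 57.0),
            # peak influence near 75 with a slow descending slope whose foot
            # lies slightly above the universe edge, keeping age=100 covered
            tri("Average", 65.0, 75.0, 102.0),
            tri("High", 50.0, 60.0, 70.0),
        ),
    )
    hb = LinguisticVariable(
        Universe("hb", 5.0, 17.0, resolution),
        (
            tri("Low", 5.0, 5.0, 9.0),          # moderate/severe anemia
            tri("Average", 8.0, 10.5, 13.0),     # mild anemia .. lower normal
            tri("High", 11.5, 14.0, 17.5),       # within the normal range
        ),
    )
    crp = LinguisticVariable(
        Universe("crp", 0.0, 30.0, resolution),
        (
            trap("Low", 0.0, 0.0, 3.0, 6.0),     # normal range and < 5 mg/dL
            trap("High", 1.0, 5.0, 30.0, 30.0),  # saturated above ~5 mg/dL
        ),
    )
    plt = LinguisticVariable(
        Universe("plt", 1.0e5, 8.0e5, resolution),
        (
            trap("Normal", 0.9e5, 1.6e5, 3.8e5, 4.5e5),
            trap("High", 4.0e5, 4.7e5, 8.0e5, 8.0e5),  # near/above upper normal
        ),
    )
    alp = LinguisticVariable(
        Universe("alp", 40.0, 1200.0, resolution),
        (
            trap("Normal", 40.0, 40.0, 120.0, 160.0),
            trap("High", 130.0, 200.0, 1200.0, 1200.0),
        ),
    )
    # Output term supports are pairwise disjoint by design (no overlap), to
    # keep the crisp probability bands easy to read for clinicians.
    output = LinguisticVariable(
        Universe(OUTPUT_NAME, 0.0, 1.0, resolution),
        (
            tri("Low", 0.0, 0.10, 0.30),
            tri("Average", 0.35, 0.50, 0.65),
            tri("High", 0.80, 0.97, 1.00),
        ),
    )
    return (age, hb, crp, plt, alp), output


def generate_rule_base(
    score_map: Optional[RiskScoreMap] = None,
    inputs: Optional[Sequence[LinguisticVariable]] = None,
) -> Tuple[FuzzyRule, ...]:
    """Combinatorial rule base: 18 (age×hb×crp) + 72 (all five) = 90 rules.

    Deterministic: the rule order follows the fixed variable order and each
    variable's declared term order, so identical score maps always produce
    identical bases.
    """
    score_map = score_map or RiskScoreMap()
    if inputs is None:
        inputs, _ = default_variables()
    by_name = {v.name: v for v in inputs}
    missing = [n for n in INPUT_ORDER if n not in by_name]
    if missing:
        raise ConfigurationError(f"rule generation needs variables {missing}")

    rules = []
    for variables in ((("age", "hb", "crp")), INPUT_ORDER):
        term_sets = [by_name[v].term_labels for v in variables]
        for combo in itertools.product(*term_sets):
            label, weight = score_map.consequent(variables, combo)
            antecedent = tuple(RuleClause(v, t) for v, t in zip(variables, combo))
            rules.append(FuzzyRule(antecedent, label, weight))
    return tuple(rules)


def default_system(resolution: int = 1001, score_map: Optional[RiskScoreMap] = None) -> FuzzySystem:
    """The shipped diagnostic system: default variables, 90-rule base,
    maximum aggregation and centroid defuzzification."""
    inputs, output = default_variables(resolution)
    rules = generate_rule_base(score_map, inputs)
    return FuzzySystem(inputs=inputs, output=output, rules=rules, settings=InferenceSettings())


def score_patient(system: FuzzySystem, record: PatientRecord) -> Tuple[float, InferenceTrace]:
    """Probability of carcinomatosis for one patient, with the full trace."""
    trace = infer(system, record.as_inputs())
    return trace.crisp_output, trace


def response_surface(
    system: FuzzySystem,
    var_x: str,
    var_y: str,
    fixed: Mapping[str, float],
    resolution: int = 20,
) -> SurfaceGrid:
    """Sweep two inputs over their universes, holding the others fixed."""
    if var_x == var_y:
        raise ConfigurationError("surface variables must differ")
    names = set(system.input_names)
    for v in (var_x, var_y):
        if v not in names:
            raise ConfigurationError(f"unknown variable {v!r}; inputs are {sorted(names)}")
    remaining = names - {var_x, var_y}
    missing = remaining - set(fixed)
    if missing:
        raise ConfigurationError(f"fixed values missing for {sorted(missing)}")
    if resolution < 1:
        raise ConfigurationError("surface resolution must be >= 1")

    def axis(var: str) -> np.ndarray:
        u = system.input(var).universe
        if resolution == 1:
            return np.array([(u.lower + u.upper) / 2.0])
        return np.linspace(u.lower, u.upper, resolution)

    xs, ys = axis(var_x), axis(var_y)
    values = np.empty((ys.size, xs.size))
    base = {k: float(fixed[k]) for k in remaining}
    for i, yv in enumerate(ys):
        for j, xv in enumerate(xs):
            inputs = dict(base)
            inputs[var_x] = float(xv)
            inputs[var_y] = float(yv)
            values[i, j] = infer(system, inputs).crisp_output
    return SurfaceGrid(var_x=var_x, var_y=var_y, x=xs, y=ys, values=values,
                       fixed=dict(base))


def min_rule_activation(system: FuzzySystem, points_per_axis: int = 10) -> float:
    """Smallest best-rule firing strength over an exhaustive input grid.

    Evaluates every combination of ``points_per_axis`` evenly spaced values
    per input variable (bounds included) and returns the minimum over the
    grid of the maximum rule firing strength. A return value of 0 means some
    in-universe input fires no rule at all (a coverage hole); any positive
    value certifies that no ``NoRuleFiredError`` can occur for in-universe
    inputs on that grid.

    Vectorized over the full cartesian grid, so a 10⁵-point sweep is cheap.
    """
    grids = {
        v.name: np.linspace(v.universe.lower, v.universe.upper, points_per_axis)
        for v in system.inputs
    }
    # degrees[var][term] -> (points_per_axis,) membership values
    degrees: Dict[str, Dict[str, np.ndarray]] = {}
    for v in system.inputs:
        _, sampled = discretize(v, Universe(v.name, v.universe.lower, v.universe.upper, points_per_axis))
        degrees[v.name] = sampled

    order = list(system.input_names)
    n = len(order)
    shape = (points_per_axis,) * n
    best = np.zeros(shape)
    for rule in system.rules:
        alpha = np.ones(shape)
        for clause in rule.antecedent:
            axis_idx = order.index(clause.variable)
            d = degrees[clause.variable][clause.term]
            if clause.negated:
                d = 1.0 - d
            expand = [np.newaxis] * n
            expand[axis_idx] = slice(None)
            alpha = np.minimum(alpha, d[tuple(expand)])
        best = np.maximum(best, alpha)
    return float(best.min())
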