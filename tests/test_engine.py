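"""Rule evaluation, implication, aggregation and defuzzification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import carcinofis as cf
from carcinofis.errors import ConfigurationError, InvalidInputError, NoRuleFiredError


def fv(variable, **degrees):
    return cf.FuzzifiedValue(variable=variable, crisp=0.0, degrees=degrees)


def rule(clauses, consequent="High", weight=1.0, connective="and"):
    return cf.FuzzyRule(
        tuple(cf.RuleClause(v, t, n) for v, t, n in clauses), consequent, weight, connective
    )


class TestFiringStrength:
    FUZZ = {
        "a": fv("a", X=0.3),
        "b": fv("b", X=0.7),
        "c": fv("c", X=1.0),
    }

    def test_and_is_minimum(self):
        r = rule([("a", "X", False), ("b", "X", False), ("c", "X", False)])
        assert cf.firing_strength(r, self.FUZZ) == pytest.approx(0.3)

    def test_or_is_maximum(self):
        r = rule([("a", "X", False), ("b", "X", False)], connective="or")
        assert cf.firing_strength(r, self.FUZZ) == pytest.approx(0.7)

    def test_weight_scales_strength_multiplicatively(self):
        r = rule([("a", "X", False), ("b", "X", False)], weight=0.5)
        alpha = cf.firing_strength(r, self.FUZZ)
        assert alpha * r.weight == pytest.approx(0.15)

    def test_zero_clause_annihilates_and(self):
        degrees = dict(self.FUZZ)
        degrees["a"] = fv("a", X=0.0)
        r = rule([("a", "X", False), ("b", "X", False)])
        assert cf.firing_strength(r, degrees) == 0.0

    def test_negated_clause_complements_degree(self):
        r = rule([("a", "X", True)])
        assert cf.firing_strength(r, self.FUZZ) == pytest.approx(0.7)

    def test_unknown_references_raise(self):
        with pytest.raises(ConfigurationError):
            cf.firing_strength(rule([("zz", "X", False)]), self.FUZZ)
        with pytest.raises(ConfigurationError):
            cf.firing_strength(rule([("a", "Nope", False)]), self.FUZZ)


class TestImplicate:
    def test_strength_one_is_identity(self):
        sampled = np.array([0.0, 0.5, 1.0, 0.5, 0.0])
        np.testing.assert_array_equal(cf.implicate(sampled, 1.0), sampled)

    def test_strength_zero_gives_empty_set(self):
        assert not cf.implicate(np.array([0.2, 0.9]), 0.0).any()

    def test_level_cut_creates_plateau(self):
        u = cf.Universe("out", 0.0, 1.0, 1001)
        mf = cf.MembershipFunction("m", "triangular", (0.0, 0.5, 1.0))
        grid, sampled = cf.discretize(mf, u)
        clipped = cf.implicate(sampled, 0.5)
        inside = (grid >= 0.25) & (grid <= 0.75)
        np.testing.assert_allclose(clipped[inside], 0.5, atol=1e-12)
        assert (clipped[~inside] < 0.5).all()

    def test_out_of_range_strength_rejected(self):
        with pytest.raises(InvalidInputError):
            cf.implicate(np.array([0.5]), 1.5)


class TestAggregate:
    def test_constant_sets_all_methods(self):
        a, b = np.full(5, 0.3), np.full(5, 0.7)
        np.testing.assert_allclose(cf.aggregate([a, b], "maximum"), 0.7)
        np.testing.assert_allclose(cf.aggregate([a, b], "probabilistic_or"), 0.79)
        np.testing.assert_allclose(
            cf.aggregate([np.full(5, 0.5), b], "bounded_sum"), 1.0
        )

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ConfigurationError):
            cf.aggregate([np.zeros(3), np.zeros(4)], "maximum")

    @settings(derandomize=True, max_examples=100)
    @given(
        sets=st.lists(
            hnp.arrays(float, 17, elements=st.floats(0, 1)), min_size=2, max_size=5
        )
    )
    def test_pointwise_dominance_ordering(self, sets):
        """maximum <= probabilistic OR <= bounded sum, pointwise, always."""
        mx = cf.aggregate(sets, "maximum")
        por = cf.aggregate(sets, "probabilistic_or")
        bs = cf.aggregate(sets, "bounded_sum")
        assert (mx <= por + 1e-12).all()
        assert (por <= bs + 1e-12).all()
        assert (bs <= 1.0).all() and (mx >= 0.0).all()


class TestDefuzzify:
    U = cf.Universe("out", 0.0, 1.0, 1001)

    def _sampled(self, mf):
        return cf.discretize(mf, self.U)

    def test_symmetric_triangle_centroid_is_exact_midpoint(self):
        grid, mu = self._sampled(cf.MembershipFunction("m", "triangular", (0.35, 0.5, 0.65)))
        assert cf.defuzzify(grid, mu, "centroid") == pytest.approx(0.5, abs=1e-12)

    def test_asymmetric_triangle_matches_closed_form(self):
        # centroid of a full triangle is (a + b + c) / 3
        a, b, c = 0.80, 0.97, 1.00
        grid, mu = self._sampled(cf.MembershipFunction("m", "triangular", (a, b, c)))
        assert cf.defuzzify(grid, mu, "centroid") == pytest.approx((a + b + c) / 3, abs=1e-6)

    def test_full_trapezoid_matches_closed_form(self):
        # analytic centroid of trapezoid (a,b,c,d) via area-weighted pieces
        a, b, c, d = 0.1, 0.3, 0.6, 0.9
        pieces = [  # (area, centroid) of up-ramp, plateau, down-ramp
            ((b - a) / 2, a + 2 * (b - a) / 3),
            (c - b, (b + c) / 2),
            ((d - c) / 2, c + (d - c) / 3),
        ]
        expected = sum(ar * cn for ar, cn in pieces) / sum(ar for ar, _ in pieces)
        grid, mu = self._sampled(cf.MembershipFunction("m", "trapezoidal", (a, b, c, d)))
        assert cf.defuzzify(grid, mu, "centroid") == pytest.approx(expected, abs=1e-6)

    def test_clipped_triangle_matches_brute_force_oracle(self, rng):
        """Centroid of level-cut triangles vs a 1e5-point midpoint Riemann sum."""
        for _ in range(10):
            a, b, c = np.sort(rng.uniform(0.05, 0.95, size=3))
            if not (a < b < c):
                continue
            level = rng.uniform(0.1, 1.0)
            fine = cf.Universe("out", 0.0, 1.0, 100001)
            mf = cf.MembershipFunction("m", "triangular", (a, b, c))
            grid, mu = cf.discretize(mf, fine)
            clipped = np.minimum(mu, level)
            # independent oracle: midpoint Riemann sum on its own grid
            edges = np.linspace(0.0, 1.0, 100001)
            mid = (edges[:-1] + edges[1:]) / 2
            mu_oracle = np.minimum(np.interp(mid, [a, b, c], [0, 1, 0]), level)
            oracle = float(np.sum(mu_oracle * mid) / np.sum(mu_oracle))
            assert cf.defuzzify(grid, clipped, "centroid") == pytest.approx(oracle, abs=1e-6)

    def test_maximum_based_methods_on_plateau(self):
        grid = np.linspace(0.0, 1.0, 11)
        mu = np.zeros(11)
        mu[4:7] = 1.0  # plateau over [0.4, 0.6]
        assert cf.defuzzify(grid, mu, "smallest_of_maximum") == pytest.approx(0.4)
        assert cf.defuzzify(grid, mu, "largest_of_maximum") == pytest.approx(0.6)
        assert cf.defuzzify(grid, mu, "middle_of_maximum") == pytest.approx(0.5)

    def test_bisector_splits_area_in_half(self):
        grid, mu = self._sampled(cf.MembershipFunction("m", "triangular", (0.0, 0.5, 1.0)))
        x_star = cf.defuzzify(grid, mu, "bisector")
        left = np.trapezoid(np.where(grid <= x_star, mu, 0.0), grid)
        assert left == pytest.approx(np.trapezoid(mu, grid) / 2, abs=1e-3)

    def test_all_zero_aggregate_raises_no_rule_fired(self):
        with pytest.raises(NoRuleFiredError):
            cf.defuzzify(np.linspace(0, 1, 5), np.zeros(5), "centroid")


class TestInfer:
    def test_single_rule_system_at_full_strength_defuzzifies_consequent(self):
        out = cf.LinguisticVariable(
            cf.Universe("risk", 0.0, 1.0, 1001),
            (
                cf.MembershipFunction("Low", "triangular", (0.0, 0.2, 0.4)),
                cf.MembershipFunction("High", "triangular", (0.5, 0.8, 0.9)),
            ),
        )
        x = cf.LinguisticVariable(
            cf.Universe("x", 0.0, 10.0, 101),
            (
                cf.MembershipFunction("On", "trapezoidal", (0.0, 0.0, 10.0, 10.0)),
                cf.MembershipFunction("Off", "gaussian", (0.0, 1.0)),
            ),
        )
        sys1 = cf.FuzzySystem(
            inputs=(x,),
            output=out,
            rules=(cf.FuzzyRule((cf.RuleClause("x", "On"),), "High", 1.0),),
        )
        trace = sys1.infer({"x": 5.0})
        grid, mu = cf.discretize(out.term("High"), out.universe)
        assert trace.crisp_output == pytest.approx(cf.defuzzify(grid, mu, "centroid"))

    def test_missing_input_rejected(self, system, worked_example):
        bad = {k: v for k, v in worked_example.items() if k != "plt"}
        with pytest.raises(InvalidInputError):
            system.infer(bad)

    def test_rule_order_invariance(self, system, worked_example, rng):
        """Permuting the rule base changes neither aggregate nor crisp output."""
        reference = system.infer(worked_example)
        order = rng.permutation(len(system.rules))
        shuffled = cf.FuzzySystem(
            inputs=system.inputs,
            output=system.output,
            rules=tuple(system.rules[i] for i in order),
            settings=system.settings,
        )
        permuted = shuffled.infer(worked_example)
        np.testing.assert_array_equal(reference.aggregate, permuted.aggregate)
        assert reference.crisp_output == permuted.crisp_output

    def test_trace_is_recomputable(self, system, worked_example):
        trace = system.infer(worked_example)
        rebuilt = cf.aggregate([a.clipped for a in trace.activations],
                               system.settings.aggregation)
        np.testing.assert_array_equal(trace.aggregate, rebuilt)
        assert trace.crisp_output == cf.defuzzify(trace.grid, trace.aggregate, "centroid")
        # report table mentions every rule and the crisp value
        report = trace.report()
        assert f"{trace.crisp_output:.4f}" in report
        assert report.count("If ") == len(system.rules)

    def test_crisp_output_within_output_universe_and_support_hull(self, system, rng):
        for _ in range(20):
            inputs = {
                v.name: rng.uniform(v.universe.lower, v.universe.upper)
                for v in system.inputs
            }
            trace = system.infer(inputs)
            u = system.output.universe
            assert u.lower <= trace.crisp_output <= u.upper
            support = trace.grid[trace.aggregate > 0]
            assert support[0] <= trace.crisp_output <= support[-1]

    def test_invalid_rule_references_rejected_at_construction(self, system):
        bad_rule = cf.FuzzyRule((cf.RuleClause("age", "Medium"),), "High", 1.0)
        with pytest.raises(ConfigurationError, match="Medium"):
            cf.FuzzySystem(
                inputs=system.inputs, output=system.output, rules=(bad_rule,)
            )

    def test_rule_weight_range_enforced(self):
        with pytest.raises(ConfigurationError):
            cf.FuzzyRule((cf.RuleClause("age", "Low"),), "High", weight=1.5)
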