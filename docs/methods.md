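# Methods

## Inference model

The diagnostic score is a classical Mamdani fuzzy inference system with five
inputs and one output. All stages are deterministic:

- **AND / implication**: minimum (the only supported choice; the system's
  rules are conjunctive).
- **Rule weights** are applied multiplicatively to the firing strength
  *before* implication (the usual toolbox convention): the clipped consequent
  is min(α·w, μ_consequent).
- **Aggregation**: pointwise maximum by default. Probabilistic OR is folded
  left-associatively (it is associative, so order is immaterial — the
  rule-order invariance test checks this end to end); bounded sum caps at 1.
  These satisfy maximum ≤ probabilistic OR ≤ bounded sum pointwise, which is
  property-tested.
- **Defuzzification**: centre of gravity on the discretized output set, with
  trapezoidal weights on the fixed grid. Bisector returns the first grid
  point at which the cumulative area reaches half the total; the
  maximum-based methods detect the argmax plateau with an absolute tie
  tolerance of 1e-9, and middle-of-maximum returns the mean of the plateau
  endpoints. An "average" defuzzifier is sometimes listed alongside these
  but has no standard definition distinct from middle-of-maximum, so it is
  deliberately not implemented.
- **No-rule-fired inputs** raise an error rather than returning a default
  value: a silent fallback would be indistinguishable from a diagnosis.

### Numerical choices

Universes are discretized at 1001 evenly spaced points by default. On the
[0, 1] output universe this puts centroid integration error near 1e-7 for the
piecewise-linear sets the system produces — far below the 3-decimal precision
at which crisp outputs are reported (verified against closed forms and a
1e5-point brute-force oracle). Crisp inputs outside a universe are clamped to
the nearest bound with a logged warning; fuzzification is idempotent under
clamping. Gaussian terms are truncated (not renormalized) at the universe
bounds during discretization. Degenerate triangle/trapezoid feet (a = b) are
allowed and give a vertical edge, which is how saturating shoulder terms at
universe edges are expressed.

## Default variables and rule base

The membership parameters encode the clinical anchors the system was designed
around: low age below 57; the highest-risk age band 50–70 peaking at 60;
average age 65 upward with peak influence near 75 and a slow decline; Hb Low
as moderate/severe anemia (≤ 9 g/dL), Average spanning mild anemia, High
overlapping the normal range; CRP pathological above ~5 mg/dL; PLT High from
just below the upper normal limit (4.0×10⁵/mm³) upward; ALP Normal up to
~160 U/L and High above. Three conventions matter:

- **Edge coverage.** Terms adjacent to a universe bound place their outer
  foot *at or slightly beyond* the bound (e.g. age Average descends to 102,
  Hb High to 17.5, PLT Normal rises from 0.9×10⁵), so membership never
  vanishes everywhere at an in-universe point. Adjacent terms always overlap.
  Together these guarantee — and the tests verify on an exhaustive
  10-points-per-axis 5-D grid — that every in-universe input fires at least
  one rule.
- **CRP overlap width.** The CRP High ramp rises across 1–5 mg/dL, i.e. it
  starts growing well inside CRP Low's plateau. A narrower ramp makes the
  crisp output dip transiently as CRP crosses the normal/pathological
  boundary (the weight-0.5 rules keyed to CRP Low decay before the CRP High
  rules take over); the wide overlap keeps the response monotone
  non-decreasing in CRP, which the monotonicity tests pin down.
- **Output bands.** The output terms Low (0, 0.10, 0.30), Average
  (0.35, 0.50, 0.65) and High (0.80, 0.97, 1.00) have pairwise disjoint
  supports so a crisp score reads directly as a band. The High triangle was
  placed so that a fully fired High consequent defuzzifies to
  (0.80 + 0.97 + 1.00)/3 ≈ 0.923, consistent with the reference
  walk-through output; this is a calibration choice, not ground truth — the
  originally published membership functions exist only as figures, and the
  full 92-rule base was never printed. For the same reason the shipped
  combinatorial base has 90 rules (18 + 72); the two additional rules of the
  original system are not recoverable, and the worked example is reproduced
  to ≈ 0.001 without them. Additional rules can be appended via the config.

The rule generator scores each term combination additively (age and Hb
contribute 0/1/2 points for Low/Average/High; CRP, PLT and ALP contribute
0 or 2), normalizes by the maximum attainable for the variables the rule
uses, and maps score s to Low (s < 0.25), Average or High (s ≥ 0.65).
Combinations within 0.10 of a threshold are demoted to weight 0.5. With
these defaults the four published example rules fall out verbatim, including
the weight-0.5 borderline rule. "ALP is low" in the published rule 91 maps
to the Normal term: ALP has only two terms because pathologically *low* ALP
(hypophosphatasia) is rare and out of scope, so "low" can only mean
not-elevated.

## Synthetic cohorts

The generator stands in for the unpublished patient charts. Each parameter
is drawn independently per patient from a truncated location–scale family on
the tabulated [min, max]:

- **Families**: age and Hb truncated normal; CRP, PLT and ALP truncated
  lognormal. The published summaries are strongly right-skewed for the
  markers (PC-group ALP: median 95 U/L, max 1103 U/L), which a normal cannot
  express. Families are per-spec overridable.
- **Calibration** targets the *truncated* law, because the published min /
  max / median / std describe the observed (bounded) samples: the location
  is solved (bisection on the monotone truncated-median map) so the truncated
  median equals the tabulated median exactly, and the scale so the truncated
  standard deviation matches the tabulated one. Truncated moments are
  computed by trapezoidal integration of the normalized density on a
  4001-point grid of the (log-scale) support, which stays stable even under
  the extreme exponential tilts the solver may visit — tail-probability
  differences in the closed-form formulas cancel catastrophically there.
- **Spread ceiling.** On a bounded support with the median pinned, the
  truncated family's standard deviation has a finite supremum (approached in
  the large-scale, exponential-tilt limit). Three tabulated rows exceed it:
  PC-group ALP (tabulated 190.8 U/L vs ≈ 152 attainable), witness-group CRP
  (5.22 vs ≈ 4.29 mg/dL) and witness-group PLT (1.297×10⁵ vs ≈ 1.157×10⁵
  /mm³) — real samples evidently carried heavier tails or outlier structure
  than any truncated (log)normal allows. For these the solver takes the
  closest achievable scale and logs a warning; all ten medians are still
  recovered within 2% (measured < 1% at n = 10⁴), and the other seven
  standard deviations within 10%.
- **Sampling** is inverse-CDF from the truncated law (`scipy.stats.truncnorm`,
  exponentiated for the lognormal family) — distributionally identical to
  rejection sampling from the parent but exact and bit-reproducible given a
  seed. A spec whose median/std-matched parent would put < 1% of its mass
  inside [min, max] is rejected as infeasible.

What the generator does *not* emulate: inter-parameter correlation (no
correlation data were published — real anemia and inflammation markers
co-vary), the matched-pair structure of the witness group, and any
within-patient longitudinal structure. Tests passing on these cohorts
therefore validate the *pipeline* (calibration, scoring, statistics), not
clinical performance on real patients. In particular the group-difference
significance pattern (PLT/ALP/CRP separating strongly, age/Hb weakly) is
checked only as a soft diagnostic at the study sample sizes (74 vs 73).

The Welch unequal-variance t-test is delegated to
`scipy.stats.ttest_ind(equal_var=False)` (statistic, Satterthwaite df and
two-sided p), cross-checked in the tests against an independently written
closed-form computation. Sample standard deviations use the n−1 denominator
and medians the midpoint convention throughout.

## Problem sizes used by tests and the acceptance script

Calibration checks and the acceptance script use n = 10,000 cohorts (median
standard error ≲ 0.15 year for age — comfortably inside the 2% check), the
defuzzification oracle uses 100 random clipped shapes against a 1e5-point
Riemann sum, aggregation ordering 1000 random set pairs, and the coverage
check the full 10⁵-cell input grid (vectorized over the rule base). The
response-surface tests use 6–8 points per axis; surfaces at any resolution
are available through the API and CLI.

## Known limitations

- The membership parameters are reconstructions from verbal descriptions of
  figures; the original system's exact parameters are not recoverable, so
  agreement with the reference output is expected within ±0.05, not exactly.
- The score is monotone in the three marker inputs at the reference slice by
  construction, but no global monotonicity claim is made over the whole
  5-D input space (nor would one be clinically warranted for age or Hb,
  whose risk semantics are deliberately non-monotone).
- No claim of clinical validity: the package reproduces and stress-tests a
  modelling approach; it is not a diagnostic device.
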