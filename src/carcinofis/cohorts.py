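"""Synthetic patient cohorts, descriptive summaries, and the Welch t-test.

The two study cohorts (colorectal cancer with peritoneal carcinomatosis, and
a colorectal-cancer-only witness group) are emulated from their published
per-parameter summaries (min, max, median, standard deviation). Each
parameter is modelled as a truncated normal (age, hemoglobin) or truncated
lognormal (CRP, PLT, ALP — strongly right-skewed in the published summaries,
e.g. ALP max 1103 U/L against a median of 95) on the tabulated [min, max].

Calibration matches the *truncated* law to the tabulated statistics: the
location is solved so the truncated median equals the tabulated median
exactly, and the scale so the truncated standard deviation is as close as
possible to the tabulated one. (Matching the parent distribution instead and
truncating afterwards can shift the median drastically for heavy-tailed
parameters.) For two parameter rows the tabulated standard deviation exceeds
what any truncated (log)normal on those bounds with that median can attain;
for those the scale solver returns the closest achievable value — see the
methods note.

Sampling uses inverse-CDF draws from the truncated law, which is exact and
bit-reproducible for a given seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import GenerationError, InvalidInputError

_log = logging.getLogger(__name__)

FAMILIES = ("normal", "lognormal")

#: canonical CSV column per study parameter
COLUMNS: Dict[str, str] = {
    "age": "age",
    "hb": "hb_g_dl",
    "crp": "crp_mg_dl",
    "plt": "plt_per_mm3",
    "alp": "alp_u_l",
}
PARAMETERS = tuple(COLUMNS)

# Parent-distribution mass required inside [min, max]; below this the spec is
# considered infeasible (a literal rejection sampler would accept <1% of draws).
_MIN_ACCEPTANCE = 0.01


@dataclass(frozen=True)
class ParameterSpec:
    """Published summary row for one parameter: bounds, median, std, family."""

    name: str
    minimum: float
    maximum: float
    median: float
    std: float
    family: str = "normal"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidInputError(f"{self.name}: family must be one of {FAMILIES}")
        if not self.minimum < self.median < self.maximum:
            raise InvalidInputError(
                f"{self.name}: need min < median < max, got "
                f"({self.minimum}, {self.median}, {self.maximum})"
            )
        if self.std <= 0:
            raise InvalidInputError(f"{self.name}: std must be > 0")
        if self.family == "lognormal" and self.minimum <= 0:
            raise InvalidInputError(f"{self.name}: lognormal requires min > 0")

    def solved_params(self) -> Tuple[float, float]:
        """(location, scale) of the calibrated truncated law.

        For the normal family these are the parent mean/sd; for the lognormal
        family they live on the log scale.
        """
        return _solve_truncated(self)

    def distribution(self):
        """The calibrated ``scipy.stats.truncnorm`` (log scale for lognormal)."""
        mu, sigma = self.solved_params()
        lo, hi = self._bounds()
        return stats.truncnorm((lo - mu) / sigma, (hi - mu) / sigma, loc=mu, scale=sigma)

    def acceptance_rate(self) -> float:
        """Mass a median/std-matched parent places inside [min, max].

        This is the acceptance rate a literal reject-outside-bounds sampler
        drawing from the table-matched parent distribution would see; a value
        below 1% marks the spec as infeasible (std incompatible with the
        truncation bounds).
        """
        lo, hi = self._bounds()
        if self.family == "normal":
            mu, sigma = self.median, self.std
        else:
            # lognormal with median m and variance v: exp(mu) = m and
            # (e^{s^2}-1) e^{s^2} m^2 = v give closed-form log-scale params
            mu = math.log(self.median)
            ratio = (self.std / self.median) ** 2
            sigma = math.sqrt(math.log((1.0 + math.sqrt(1.0 + 4.0 * ratio)) / 2.0))
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        return float(stats.norm.sf(a) - stats.norm.sf(b))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        rate = self.acceptance_rate()
        if rate < _MIN_ACCEPTANCE:
            raise GenerationError(
                f"{self.name}: infeasible spec — parent acceptance rate "
                f"{rate:.4f} < {_MIN_ACCEPTANCE}"
            )
        draws = self.distribution().rvs(size=n, random_state=rng)
        if self.family == "lognormal":
            draws = np.exp(draws)
        return np.clip(draws, self.minimum, self.maximum)  # guard fp round-off

    def _bounds(self) -> Tuple[float, float]:
        if self.family == "lognormal":
            return math.log(self.minimum), math.log(self.maximum)
        return self.minimum, self.maximum

    def _target_median(self) -> float:
        return math.log(self.median) if self.family == "lognormal" else self.median


_GRID_POINTS = 4001


def _truncated_profile(spec: ParameterSpec, mu: float, sigma: float) -> Tuple[float, float]:
    """(median, std) of the truncated law on the original scale.

    Computed by trapezoidal integration of the normalized density on a fixed
    grid over the (log-scale, for lognormal) support. Working with weights
    relative to the density maximum keeps the computation stable even for
    extreme location/scale combinations where tail-probability differences
    cancel catastrophically.
    """
    lo, hi = spec._bounds()
    y = np.linspace(lo, hi, _GRID_POINTS)
    logw = -0.5 * ((y - mu) / sigma) ** 2
    w = np.exp(logw - logw.max())
    x = np.exp(y) if spec.family == "lognormal" else y

    cum = np.concatenate(([0.0], np.cumsum((w[1:] + w[:-1]) / 2.0 * np.diff(y))))
    total = cum[-1]
    median_y = float(np.interp(total / 2.0, cum, y))
    median = math.exp(median_y) if spec.family == "lognormal" else median_y

    mean = float(np.trapezoid(w * x, y) / total)
    var = float(np.trapezoid(w * (x - mean) ** 2, y) / total)
    return median, math.sqrt(max(var, 0.0))


def _solve_mu(spec: ParameterSpec, sigma: float) -> float:
    # The truncated median is strictly increasing in mu and spans (lo, hi).
    # The bracket must admit strong exponential tilts (|mu - centre| of order
    # lambda * sigma^2, with the tilt rate lambda up to ~100 / range for
    # medians very close to a truncation bound).
    lo, hi = spec._bounds()
    span = 6.0 * sigma + (hi - lo) + 100.0 * sigma * sigma / (hi - lo)
    return optimize.brentq(
        lambda mu: _truncated_profile(spec, mu, sigma)[0] - spec.median,
        lo - span, hi + span, xtol=1e-12,
    )


@lru_cache(maxsize=None)
def _solve_truncated(spec: ParameterSpec) -> Tuple[float, float]:
    """Solve (mu, sigma) so the truncated law matches median (exactly) and std
    (as closely as the bounded support allows)."""
    lo, hi = spec._bounds()
    span = hi - lo

    def std_with_median_matched(sigma: float) -> float:
        return _truncated_profile(spec, _solve_mu(spec, sigma), sigma)[1]

    sig_lo, sig_hi = 1e-4 * span, 2.0 * span
    target = spec.std
    best_effort = std_with_median_matched(sig_hi)
    if best_effort < target:
        # Tabulated std is unattainable on this bounded support (heavy-tailed
        # real data); take the closest achievable scale.
        sigma = sig_hi
        _log.warning(
            "%s: tabulated std %.4g exceeds the achievable maximum %.4g on "
            "[%g, %g]; using best-effort scale",
            spec.name, target, best_effort, spec.minimum, spec.maximum,
        )
    else:
        sigma = optimize.brentq(
            lambda s: std_with_median_matched(s) - target, sig_lo, sig_hi, xtol=1e-10,
        )
    return _solve_mu(spec, sigma), sigma


@dataclass(frozen=True)
class CohortSpec:
    """One cohort: label, size, per-parameter specs, and a seed."""

    label: str
    n: int
    specs: Tuple[ParameterSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidInputError("cohort size must be >= 1")
        names = tuple(s.name for s in self.specs)
        if sorted(names) != sorted(PARAMETERS):
            raise InvalidInputError(
                f"cohort needs exactly one spec per parameter {PARAMETERS}, got {names}"
            )

    def spec(self, name: str) -> ParameterSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise InvalidInputError(f"no spec for parameter {name!r}")


# Published cohort summary rows (min, max, median, std).
_PC_ROWS = {
    "age": (39, 85, 63, 11.29, "normal"),
    "hb": (6.5, 16.5, 12.1, 2.5, "normal"),
    "plt": (230_000, 705_000, 384_000, 95_613.62, "lognormal"),
    "crp": (0.48, 26.63, 6.2, 6.685, "lognormal"),
    "alp": (54, 1103, 95, 190.81, "lognormal"),
}
_CRC_ROWS = {
    "age": (29, 91, 69, 12.92, "normal"),
    "hb": (5, 15.8, 10.3, 2.61, "normal"),
    "plt": (155_000, 561_000, 301_000, 129_710.3, "lognormal"),
    "crp": (0.1, 14.78, 3.87, 5.22, "lognormal"),
    "alp": (43, 384, 80, 56.83, "lognormal"),
}


def _make_specs(rows) -> Tuple[ParameterSpec, ...]:
    return tuple(
        ParameterSpec(name, lo, hi, med, sd, family)
        for name, (lo, hi, med, sd, family) in rows.items()
    )


def pc_cohort_spec(n: int = 74, seed: int = 0) -> CohortSpec:
    """Cohort spec for the carcinomatosis (CRC+PC) group; study size 74."""
    return CohortSpec("PC+CRC", n, _make_specs(_PC_ROWS), seed)


def crc_cohort_spec(n: int = 73, seed: int = 0) -> CohortSpec:
    """Cohort spec for the CRC-only witness group; study size 73."""
    return CohortSpec("CRC-only", n, _make_specs(_CRC_ROWS), seed)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a reproducible synthetic cohort.

    Returns a DataFrame with columns
    ``id, age, hb_g_dl, crp_mg_dl, plt_per_mm3, alp_u_l, group``.
    """
    rng = np.random.default_rng(spec.seed)
    data = {"id": [f"{spec.label}-{i + 1:05d}" for i in range(spec.n)]}
    for name in PARAMETERS:
        data[COLUMNS[name]] = spec.spec(name).sample(spec.n, rng)
    data["group"] = spec.label
    return pd.DataFrame(data)


def summarize(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter min / max / median / std (sample, n−1 denominator).

    Medians use the midpoint convention for even sample sizes.
    """
    if len(cohort) == 0:
        raise InvalidInputError("cannot summarize an empty cohort")
    rows = {}
    for name in PARAMETERS:
        col = COLUMNS[name]
        if col not in cohort.columns:
            raise InvalidInputError(f"cohort is missing column {col!r}")
        values = cohort[col].to_numpy(dtype=float)
        rows[name] = {
            "min": float(np.min(values)),
            "max": float(np.max(values)),
            "median": float(np.median(values)),
            "std": float(np.std(values, ddof=1)) if values.size > 1 else float("nan"),
        }
    return pd.DataFrame(rows).T[["min", "max", "median", "std"]]


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample t-test: statistic, Welch–Satterthwaite df, two-sided p."""

    t: float
    df: float
    p: float


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> WelchResult:
    """Two-tailed t-test with unequal variances (Welch)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    for label, s in (("a", a), ("b", b)):
        if s.size < 2:
            raise InvalidInputError(f"sample {label} needs at least 2 values")
        if not np.all(np.isfinite(s)):
            raise InvalidInputError(f"sample {label} contains non-finite values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            # degenerate but well-defined: identical constant samples
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        raise InvalidInputError("both samples have zero variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))
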