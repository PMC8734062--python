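"""Closed-form Bayesian quantities for a dichotomous screening test.

A screening test is summarised by its sensitivity ``a = P(T+|D+)`` and
specificity ``b = P(T-|D-)``.  Given a disease prevalence (or pre-test
probability) ``phi``, Bayes' theorem gives the positive predictive value

    ppv(phi) = a*phi / (a*phi + (1-b)*(1-phi))

and the negative predictive value

    npv(phi) = b*(1-phi) / ((1-a)*phi + b*(1-phi)).

Repeating the same test independently ``n`` times and observing ``n``
positives multiplies the prior odds by the positive likelihood ratio
``LR+ = a/(1-b)`` once per test, giving the n-test posterior

    ppv_n(phi) = a^n*phi / (a^n*phi + (1-b)^n*(1-phi)).

All posteriors here are evaluated in log-odds space so the formulas stay
accurate for very large ``n`` where ``a^n`` underflows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Union

__all__ = [
    "UndefinedResultError",
    "InfiniteLikelihoodRatioError",
    "TestCharacteristics",
    "PosteriorResult",
    "ConvergenceClass",
    "ppv",
    "npv",
    "positive_likelihood_ratio",
    "sequential_ppv",
    "posterior_after_sequence",
    "convergence_class",
    "intersection_prevalence",
]

#: tolerance for equality comparisons between probabilities
PROB_TOL = 1e-12


class UndefinedResultError(ArithmeticError):
    """A posterior of the form 0/0: no probability mass on either branch."""


class InfiniteLikelihoodRatioError(ValueError):
    """LR+ = a/(1-b) is infinite because the specificity is exactly 1."""


def _check_probability(value: float, name: str, *, low_open: bool = False) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if low_open:
        if not 0.0 < value <= 1.0:
            raise ValueError(f"{name} must be in (0, 1], got {value!r}")
    elif not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")
    return value


def _logit(p: float) -> float:
    """log(p/(1-p)), with the conventional +/-inf at the endpoints."""
    if p <= 0.0:
        return -math.inf
    if p >= 1.0:
        return math.inf
    return math.log(p) - math.log1p(-p)


def _expit(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@dataclass(frozen=True)
class TestCharacteristics:
    """Sensitivity/specificity pair with derived likelihood ratios.

    Both probabilities must lie in (0, 1]; a test that never detects
    disease (a = 0) or never clears the healthy (b = 0) is rejected.
    """

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sensitivity",
            _check_probability(self.sensitivity, "sensitivity", low_open=True),
        )
        object.__setattr__(
            self, "specificity",
            _check_probability(self.specificity, "specificity", low_open=True),
        )

    @property
    def positive_likelihood_ratio(self) -> float:
        """LR+ = a/(1-b); raises if specificity = 1 (no false positives)."""
        return positive_likelihood_ratio(self)

    @property
    def log_positive_likelihood_ratio(self) -> float:
        """ln(LR+) = ln(a) - ln(1-b); +inf when specificity = 1."""
        if self.specificity >= 1.0:
            return math.inf
        return math.log(self.sensitivity) - math.log1p(-self.specificity)

    @property
    def negative_likelihood_ratio(self) -> float:
        """LR- = (1-a)/b; the odds update applied by a negative result."""
        return (1.0 - self.sensitivity) / self.specificity


@dataclass(frozen=True)
class PosteriorResult:
    """A disease probability together with the evidence that produced it."""

    posterior: float
    prior: float
    n_positive: int
    n_negative: int = 0


class ConvergenceClass(str, Enum):
    """Limit behaviour of the all-positive posterior as n grows.

    Determined by comparing a with (1-b): when a > 1-b each positive
    test raises the odds (LR+ > 1) so the posterior converges to 1;
    when a = 1-b the test is uninformative and the posterior stays at
    the prior; when a < 1-b a positive result is evidence *against*
    disease and the posterior converges to 0.
    """

    CONVERGES_TO_ONE = "converges_to_one"
    STAYS_AT_PRIOR = "stays_at_prior"
    CONVERGES_TO_ZERO = "converges_to_zero"


def ppv(test: TestCharacteristics, prevalence: float) -> float:
    """Positive predictive value P(D+|T+) at the given prevalence.

    Raises
    ------
    UndefinedResultError
        If the total probability of a positive test is zero
        (specificity = 1 together with prevalence = 0).
    """
    phi = _check_probability(prevalence, "prevalence")
    a, b = test.sensitivity, test.specificity
    tp = a * phi
    fp = (1.0 - b) * (1.0 - phi)
    if tp + fp == 0.0:
        raise UndefinedResultError(
            "PPV is 0/0: a positive test has probability zero "
            f"(sensitivity={a}, specificity={b}, prevalence={phi})"
        )
    return tp / (tp + fp)


def npv(test: TestCharacteristics, prevalence: float) -> float:
    """Negative predictive value P(D-|T-) at the given prevalence.

    Raises
    ------
    UndefinedResultError
        If the total probability of a negative test is zero
        (sensitivity = 1 together with prevalence = 1).
    """
    phi = _check_probability(prevalence, "prevalence")
    a, b = test.sensitivity, test.specificity
    tn = b * (1.0 - phi)
    fn = (1.0 - a) * phi
    if tn + fn == 0.0:
        raise UndefinedResultError(
            "NPV is 0/0: a negative test has probability zero "
            f"(sensitivity={a}, specificity={b}, prevalence={phi})"
        )
    return tn / (tn + fn)


def positive_likelihood_ratio(test: TestCharacteristics) -> float:
    """LR+ = a/(1-b), the odds multiplier applied by one positive test."""
    if test.specificity >= 1.0:
        raise InfiniteLikelihoodRatioError(
            "LR+ = a/(1-b) is infinite for specificity = 1: a positive "
            "result is then conclusive and no iteration count is defined"
        )
    return test.sensitivity / (1.0 - test.specificity)


def sequential_ppv(
    test: TestCharacteristics, prevalence: float, n: int
) -> PosteriorResult:
    """Posterior disease probability after ``n`` consecutive positive tests.

    Evaluates a^n*phi / (a^n*phi + (1-b)^n*(1-phi)) via log-odds
    (posterior logit = prior logit + n*ln(LR+)), which is exact in the
    odds domain and does not underflow even for n ~ 1e4 and beyond.
    """
    if n != int(n) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    n = int(n)
    phi = _check_probability(prevalence, "prevalence")
    a, b = test.sensitivity, test.specificity
    if phi == 0.0:
        if b >= 1.0:
            raise UndefinedResultError(
                "posterior is 0/0: prevalence 0 and specificity 1 leave "
                "no probability mass on an all-positive result"
            )
        post = 0.0
    elif phi == 1.0:
        post = 1.0
    else:
        post = _expit(_logit(phi) + n * test.log_positive_likelihood_ratio)
    return PosteriorResult(posterior=post, prior=phi, n_positive=n)


Outcome = Union[str, bool, int]

_POSITIVE = {"+", "positive", "pos", True, 1}
_NEGATIVE = {"-", "negative", "neg", False, 0}


def _parse_outcomes(outcomes: Iterable[Outcome]) -> tuple[int, int]:
    k = m = 0
    for o in outcomes:
        key = o.strip().lower() if isinstance(o, str) else o
        if key in _POSITIVE:
            k += 1
        elif key in _NEGATIVE:
            m += 1
        else:
            raise ValueError(f"unrecognised test outcome {o!r}")
    return k, m


def posterior_after_sequence(
    test: TestCharacteristics,
    prevalence: float,
    outcomes: Iterable[Outcome],
) -> PosteriorResult:
    """Fold Bayes' rule over an ordered list of test outcomes.

    Each positive result multiplies the disease odds by a/(1-b) and each
    negative result by (1-a)/b, so only the counts matter: the posterior
    is invariant under permutation of the outcome list.  An empty list
    returns the prior unchanged.
    """
    k, m = _parse_outcomes(outcomes)
    phi = _check_probability(prevalence, "prevalence")
    a, b = test.sensitivity, test.specificity

    # log P(outcomes|D) + log phi   vs   log P(outcomes|not D) + log (1-phi)
    def slog(x: float) -> float:
        return math.log(x) if x > 0.0 else -math.inf

    log_d = k * slog(a) + m * slog(1.0 - a) + slog(phi)
    log_nd = k * slog(1.0 - b) + m * slog(b) + slog(1.0 - phi)
    if log_d == -math.inf and log_nd == -math.inf:
        raise UndefinedResultError(
            "posterior is 0/0: the observed outcome sequence has "
            "probability zero under both disease states"
        )
    if log_d == -math.inf:
        post = 0.0
    elif log_nd == -math.inf:
        post = 1.0
    else:
        post = _expit(log_d - log_nd)
    return PosteriorResult(posterior=post, prior=phi, n_positive=k, n_negative=m)


def convergence_class(test: TestCharacteristics) -> ConvergenceClass:
    """Classify the n -> infinity limit of the all-positive posterior."""
    a = test.sensitivity
    fpr = 1.0 - test.specificity
    if abs(a - fpr) <= PROB_TOL:
        return ConvergenceClass.STAYS_AT_PRIOR
    if a > fpr:
        return ConvergenceClass.CONVERGES_TO_ONE
    return ConvergenceClass.CONVERGES_TO_ZERO


def intersection_prevalence(test: TestCharacteristics) -> float:
    """Prevalence phi_i at which PPV and NPV curves cross.

    Closed form::

        phi_i = (-b^2 + b - sqrt(a*b*(a*b - a + 1 - b))) / (a^2 - b^2 - a + b)

    The denominator factors as (a-b)(a+b-1), so the expression is 0/0
    both when a = b and when a + b = 1; in either degenerate case the
    curves are symmetric under phi -> 1-phi and the crossing is at 0.5.

    Requires 0 < a < 1 and 0 < b < 1.
    """
    a, b = test.sensitivity, test.specificity
    if not (0.0 < a < 1.0 and 0.0 < b < 1.0):
        raise ValueError(
            "intersection prevalence requires sensitivity and specificity "
            f"strictly inside (0, 1), got a={a}, b={b}"
        )
    denom = (a - b) * (a + b - 1.0)
    if abs(denom) <= PROB_TOL:
        return 0.5
    num = -b * b + b - math.sqrt(a * b * (a * b - a + 1.0 - b))
    return num / denom
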