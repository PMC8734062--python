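# Methods

## Model and assumptions

A dichotomous screening test is characterised by its sensitivity
`a = P(T+|D+)` and specificity `b = P(T-|D-)`, both required to lie in
(0, 1]. The prior probability of disease `φ` may be a population
prevalence or an individual pre-test probability; the algebra is the
same. All sequential results assume the repeats are *conditionally
independent given disease status* — the same `a` and `b` apply to every
repeat and errors do not recur systematically. The simulator (below)
exists largely to show what breaks when that assumption fails.

Posteriors are odds-multiplicative: a positive result multiplies the
disease odds by `LR+ = a/(1-b)`, a negative result by `LR- = (1-a)/b`.
All sequential quantities follow from that single fact, which is why
`posterior_after_sequence` is order-invariant and depends only on the
counts of positive and negative results, and why the iteration-count
formula depends on (a, b) only through `ln(LR+)`.

## Numerical choices

- **Log-odds evaluation.** The n-test posterior
  `aⁿφ / (aⁿφ + (1-b)ⁿ(1-φ))` is evaluated as
  `expit(logit(φ) + n·ln(LR+))`, never via the powers themselves:
  `0.9ⁿ` underflows around n ≈ 7000 and the naive form returns 0/0.
  The logit form is exact in the odds domain and valid for any n.
- **Convergence condition.** The limit class of the all-positive
  posterior is decided by comparing `a` with `1-b` (equivalently the
  sign of `a+b-1`, the sign of `ln LR+`). A statement of the same limit
  in terms of `P(T|D) ≷ 0.5` is only equivalent when `b = 0.5`; the
  odds-ratio condition is the one the algebra supports, and it is the
  one implemented. Ties are detected at `|a-(1-b)| ≤ 1e-12`.
- **Crossover prevalence.** The closed form for the PPV/NPV crossing
  has denominator `a²-b²-a+b = (a-b)(a+b-1)` and is 0/0 both at `a = b`
  and at `a+b = 1`. In both degenerate cases the two curves are
  symmetric under `φ → 1-φ` and the crossing is exactly 0.5, which is
  returned directly; the tests verify the closed form against a
  root-finding oracle elsewhere. The often-quoted observation that the
  crossing "hovers around 40–60% prevalence" for clinically useful
  tests is an observation, not a theorem — `a = 0.99, b = 0.51` crosses
  near 0.83 — so it is documented, not asserted.
- **Tolerances.** Probability equalities at 1e-12; root/crossover
  agreement at 1e-9; the uninformative boundary `a+b = 1` at 1e-12.
- **Degenerate inputs.** Parameter combinations that make a posterior
  0/0 (e.g. specificity 1 with prevalence 0, or an impossible outcome
  sequence) raise `UndefinedResultError` rather than silently returning
  a number. `LR+` with specificity exactly 1 raises
  `InfiniteLikelihoodRatioError`.

## Iteration planning

`required_iterations_continuous` returns
`(logit(ρ) - logit(φ)) / ln(LR+)`: the log-odds gap between target and
prior divided by the log-odds gained per positive test. It accepts
either a test or a raw `ln(LR+)` value, since nothing else enters.
`required_iterations` wraps it with a feasibility classification keyed
to the sign of `ln(LR+)`:

| class | condition | n_i |
|---|---|---|
| `feasible` | `a+b > 1`, `0 < φ < ρ` | `⌈n⌉ ≥ 1` |
| `already_satisfied` | `φ ≥ ρ` | 0 |
| `infeasible_uninformative` | `a+b = 1` | none |
| `infeasible_negative` | `a+b < 1` | none |
| `unreachable` | `φ = 0` | none |

The ceiling is applied to the unrounded continuous value; the 2-decimal
display rounding in reference tables is half-up and purely cosmetic.
A target of exactly 1 is rejected (`UnreachableTargetError`): the count
diverges for any prior below 1. The integer count is floored at 0 —
a negative "number of tests" has no clinical meaning. Classification
precedence follows the table order above: a test with `a+b ≤ 1` is
reported as infeasible even when the prior already meets the target,
because the planner's subject is the updating process, not the prior.

Reference tables default to `ln(LR+) ∈ {0.5, 1.0, …, 5.0}` rows by
prevalence `{0.02, 0.05, 0.07, 0.1, 0.15, 0.2}` columns at targets
`{0.99, 0.95, 0.75, 0.50}`, the grid conventional for screening
contexts where prevalence rarely exceeds 20%. CSV exports use comma
separators, "." decimals and "#"-prefixed metadata lines; infeasible
cells are the literal token `INF` in CSV and `null` in JSON, never a
negative number.

## Monte-Carlo simulator

The simulator draws disease status ~ Bernoulli(φ) per subject and then
`n_tests` results with per-test positive probability `a` (diseased) or
`1-b` (healthy), using one seeded `numpy.random.Generator` per run; the
seed is echoed in every result, and identical configurations are
bit-identical. The empirical estimand is the fraction diseased among
subjects whose results are *all* positive, compared with the analytic
posterior; the all-positive fraction is compared with the total
probability `aⁿφ + (1-b)ⁿ(1-φ)`. Uncertainty is the binomial standard
error `√(p̂(1-p̂)/n_all_positive)`, and agreement checks use 3 SE.
Default validation runs use 200,000 subjects, which puts the SE on the
two-test PPV near 0.003 — small enough to detect any real defect in the
closed forms while keeping a run under a second.

**Correlated repeats.** Real repeat tests on the same patient within a
short window are rarely independent: the same interfering factor can
reproduce the same error. To illustrate this, each subject carries a
latent "propensity" result drawn once with the subject's marginal
positive probability; each individual test copies that latent result
with probability `c` (the `correlation` knob) and is a fresh draw
otherwise. This mixture preserves per-test sensitivity and specificity
exactly — single-test operating characteristics are unchanged — while
giving within-subject result pairs a correlation of `c²`. As `c → 1`
the repeats collapse to copies of one test and the all-positive PPV
falls from the independent n-test value back to the single-test value;
`independence_violation_report` quantifies the fraction of the
sequential gain actually realised. The mechanism is a deliberately
simple stand-in: it does not model temporal drift in the measured
biology, operator learning, or any dependence that varies with disease
status, so passing simulator checks say nothing about how large `c` is
in any real assay — only that the closed forms are exactly right at
`c = 0` and directionally degraded otherwise.

## What the tests do and do not show

The package's quantitative surface is purely mathematical — closed
forms and their discretisation — so the test suite can verify it
essentially exactly: golden tables at printed precision, algebraic
inverses at 1e-9, property tests (hypothesis, derandomised) for
monotonicity, chaining equivalence, order invariance and ceiling
bracketing, and seeded Monte-Carlo agreement at 3 SE. None of this
validates the *clinical* premise that repeat tests can be made
independent; that is an empirical question outside the package's scope,
flagged by the correlation knob rather than answered by it. Planning in
the negative-result direction (target NPV) and two-test strategies with
a second, different assay are likewise out of scope.
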