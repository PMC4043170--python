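"""Expected clonal diversity and the childhood-ALL case study.

Diversity here means the expected number of *distinct* mutations (unique
clones, infinite-sites assumption) among the ``k + 1``-mutant progeny of a
single founder cell.  The diversity of compartment ``i`` grows either by new
mutation events of ``k``-mutant cells inside compartment ``i`` or by
differentiation of clones arriving from compartment ``i - 1``; solving that
recursion on the same template as the capacity recursion gives the closed
form

    D_i^{k+1} = u * W_i^{k+1} / (2*alpha - 1)
              = c * C(i - f + k + 1, k + 1) * a^(i-f) * b^(k+2),

with ``a, b, c`` as in :mod:`clonewave.capacity`.  Under the haematopoietic
parametrization (eps = 0.85, u = 1e-6) this yields roughly thirty distinct
single mutations among the mature progeny of one founder cell, exploding to
tens of thousands when the founder's differentiation probability drops to
0.75 — a span of three orders of magnitude for a change of 0.1 in eps.

The raw count of founded clones (each mutation event counted once,
regardless of clone size) is exposed separately as
:func:`expected_founded_clones`; it is the quantity estimated by the
stochastic engine's clone census and is far larger, because most clones are
founded late in the hierarchy and stay tiny.

The ALL case study inverts the clonal-wave forward map against a tumour
burden observed in a diagnosis window to estimate the mutant differentiation
probability, then predicts the diversity range for the inferred interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .capacity import DivergentCapacityError, capacity_neutral, neutral_coefficients
from .dynamics import closed_form_grid
from .params import (
    HierarchyParams,
    months_to_units,
    units_to_months,
    validate_params,
)

__all__ = [
    "DiversityTable",
    "ErrorBudget",
    "BurdenConstraints",
    "EpsilonInterval",
    "expected_diversity",
    "expected_founded_clones",
    "diversity_table",
    "diversity_with_exclusions",
    "diversity_error_budget",
    "default_reference_population",
    "burden_fraction",
    "time_to_burden",
    "estimate_epsilon_from_burden",
    "all_case_study",
    "DAILY_MARROW_OUTPUT",
    "InfeasibleConstraintsError",
    "UnreachableBurdenError",
]

#: daily bone-marrow output of mature cells the 31-compartment hierarchy is
#: calibrated to sustain (cells per day).
DAILY_MARROW_OUTPUT = 3.5e11


class InfeasibleConstraintsError(ValueError):
    """No differentiation probability satisfies the burden constraints."""


class UnreachableBurdenError(ValueError):
    """The clonal wave never reaches the requested burden fraction."""


# ----------------------------------------------------------------------
# expected diversity
# ----------------------------------------------------------------------
def _check_diversity_args(params: HierarchyParams, i: int, k_plus_1: int):
    params = validate_params(params)
    if not 1 <= i <= params.n_compartments:
        raise ValueError(f"compartment {i} out of range")
    if k_plus_1 < 1:
        raise ValueError("k_plus_1 must be >= 1 (clones carry >= 1 mutation)")
    return params


def expected_diversity(params: HierarchyParams, i: int, k_plus_1: int = 1) -> float:
    """Expected number of distinct ``k_plus_1``-fold mutations in
    compartment ``i`` founded within the progeny of a single founder cell.

    Closed form ``u * W_i^{k+1} / (2 alpha - 1)`` per founder cell, scaled by
    ``n0`` founder cells.  Exactly zero when ``u = 0``; requires ``eps > 0``
    (enforced at validation) and the wave regime ``alpha > 1/2``.
    """
    params = _check_diversity_args(params, i, k_plus_1)
    if params.u == 0.0:
        return 0.0
    f = params.founder_compartment
    if i < f:
        return 0.0
    a, b, c = neutral_coefficients(params)
    m = i - f
    k1 = k_plus_1
    log_d = (
        math.log(c)
        + math.lgamma(m + k1 + 1)
        - math.lgamma(k1 + 1)
        - math.lgamma(m + 1)
        + m * math.log(a)
        + (k1 + 1) * math.log(b)
    )
    return params.n0 * math.exp(log_d)


def expected_founded_clones(
    params: HierarchyParams, i: int, k_plus_1: int = 1
) -> float:
    """Expected number of distinct ``k_plus_1``-mutant clones founded in
    compartments up to ``i`` (per ``n0`` founder cells).

    Every division of a ``k``-mutant founds a new ``k + 1``-clone with
    probability ``u``; the expected division count of class ``(j, k)`` is
    ``W_j^k / alpha``, so the total is ``sum_j u W_j^k / alpha``.  In the
    wave regime every founded clone reaches all downstream compartments (up
    to O(u) re-mutation corrections), which makes this the expectation of the
    stochastic engine's clone census.
    """
    params = _check_diversity_args(params, i, k_plus_1)
    if params.u == 0.0:
        return 0.0
    k = k_plus_1 - 1
    alpha = params.epsilon_scalar + params.u
    total = 0.0
    for j in range(params.founder_compartment, i + 1):
        total += params.u * capacity_neutral(params, j, k) / alpha
    return params.n0 * total


@dataclass
class DiversityTable:
    """Per-compartment expected diversity ``D[i - 1]`` for one mutant order."""

    k_plus_1: int
    D: np.ndarray
    params: HierarchyParams = field(repr=False, default=None)

    def value(self, compartment: int) -> float:
        return float(self.D[compartment - 1])


def diversity_table(params: HierarchyParams, k_plus_1: int = 1) -> DiversityTable:
    params = validate_params(params)
    D = np.array(
        [
            expected_diversity(params, i, k_plus_1)
            for i in range(1, params.n_compartments + 1)
        ]
    )
    return DiversityTable(k_plus_1=k_plus_1, D=D, params=params)


def diversity_with_exclusions(
    params: HierarchyParams,
    i: int,
    excluded_compartments=frozenset(),
    k_plus_1: int = 1,
) -> float:
    """Expected diversity with the mutation events of some compartments
    removed.

    Excluded compartments contribute no *new* mutation events but still
    transmit (and amplify) clones founded upstream — the exclusion acts on
    event origin, not clone presence.  Excluding every compartment up to
    ``i`` therefore yields zero; excluding none reproduces
    :func:`expected_diversity`.
    """
    params = _check_diversity_args(params, i, k_plus_1)
    excluded = {int(j) for j in excluded_compartments}
    if not excluded.issubset(set(range(1, i + 1))):
        raise ValueError("excluded compartments must lie within 1..i")
    if params.u == 0.0:
        return 0.0
    f = params.founder_compartment
    if i < f:
        return 0.0
    a, b, c = neutral_coefficients(params)
    u = params.u
    s = 2.0 * (params.epsilon_scalar + u) - 1.0
    k = k_plus_1 - 1
    D = 0.0
    for j in range(f, i + 1):
        src = 0.0
        if j not in excluded:
            src = u * b * capacity_neutral(params, j, k)
        D = (2.0 * params.epsilon_scalar * D + src) / s
    return params.n0 * D


@dataclass(frozen=True)
class ErrorBudget:
    """Linear error propagation of the expected diversity.

    ``contribution_u = |dD/du| * delta_u`` and
    ``contribution_eps = |dD/deps| * delta_eps``; ``delta_total`` is their
    sum (worst-case linear combination).
    """

    delta_total: float
    contribution_u: float
    contribution_eps: float
    delta_u: float
    delta_eps: float


def diversity_error_budget(
    params: HierarchyParams,
    i: int,
    delta_u: float,
    delta_eps: float,
    k_plus_1: int = 1,
) -> ErrorBudget:
    """First-order sensitivity of :func:`expected_diversity` to ``u``, ``eps``.

    The partial derivatives follow analytically from the closed form:
    with ``m = i - f`` and ``k1 = k_plus_1``,

        dlnD/du   = 1/alpha + (k1 + 1)/u - 2 (m + k1 + 2)/(2 alpha - 1)
        dlnD/deps = 1/alpha +  m/eps     - 2 (m + k1 + 2)/(2 alpha - 1)
    """
    if delta_u < 0 or delta_eps < 0:
        raise ValueError("uncertainties must be non-negative")
    params = _check_diversity_args(params, i, k_plus_1)
    D = expected_diversity(params, i, k_plus_1)
    if D == 0.0:
        return ErrorBudget(0.0, 0.0, 0.0, delta_u, delta_eps)
    eps = params.epsilon_scalar
    u = params.u
    alpha = eps + u
    s = 2.0 * alpha - 1.0
    m = i - params.founder_compartment
    k1 = k_plus_1
    dlnD_du = 1.0 / alpha + (k1 + 1.0) / u - 2.0 * (m + k1 + 2.0) / s
    dlnD_de = 1.0 / alpha + m / eps - 2.0 * (m + k1 + 2.0) / s
    cu = abs(dlnD_du) * D * delta_u
    ce = abs(dlnD_de) * D * delta_eps
    return ErrorBudget(cu + ce, cu, ce, delta_u, delta_eps)


# ----------------------------------------------------------------------
# ALL case study: burden inversion and time to load
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class BurdenConstraints:
    """Clinical constraint box for the burden inversion.

    ``founder_count`` mutant founder cells start in the founder compartment;
    at diagnosis, between ``burden_fraction_range[0]`` and ``[1]`` of the
    mature pool are tumour cells, and diagnosis falls inside
    ``diagnosis_window_months``.  ``reference_population`` is the healthy
    mature-compartment pool used as the burden denominator (default: the
    steady pool sustaining the calibrated daily marrow output).
    """

    founder_count: float = 100.0
    burden_fraction_range: tuple[float, float] = (0.10, 0.75)
    diagnosis_window_months: tuple[float, float] = (48.0, 77.0)
    reference_population: float | None = None

    def __post_init__(self):
        lo, hi = self.burden_fraction_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("burden fractions must lie in (0, 1] and be ordered")
        t0, t1 = self.diagnosis_window_months
        if not (0 < t0 <= t1):
            raise ValueError("diagnosis window must be positive and ordered")
        if self.founder_count < 1:
            raise ValueError("founder_count must be >= 1")


@dataclass(frozen=True)
class EpsilonInterval:
    """Differentiation-probability interval returned by the inversion.

    ``low`` pairs with the high-burden/early-diagnosis corner of the
    constraint box and ``high`` with the low-burden/late-diagnosis corner
    (smaller eps means a larger clone reaching a given load sooner).
    """

    low: float
    high: float


def default_reference_population(params: HierarchyParams) -> float:
    """Healthy mature-compartment pool size used as the burden denominator.

    Steady state of the last compartment sustaining the calibrated marrow
    output: with production ``P`` cells per time unit arriving in the mature
    compartment and per-cell turnover ``(2 alpha - 1) r_n``, the pool is
    ``P / ((2 alpha - 1) r_n)``; ``P`` converts the daily output of 3.5e11
    cells into model time units (400 units per year).
    """
    params = validate_params(params)
    eps = 0.85  # healthy haematopoietic differentiation probability
    alpha = eps + params.u
    r_n = params.rate_schedule().rate(params.n_compartments)
    per_unit = DAILY_MARROW_OUTPUT * 365.0 / 400.0
    return per_unit / ((2.0 * alpha - 1.0) * r_n)


def _mutant_size_fn(params: HierarchyParams, epsilon_mutant: float, n0: float):
    """Closed-form mutant population in the mature compartment vs time.

    Values below the cancellation noise of the Bateman sum (dominant at small
    times and near-critical eps) are clipped to zero so that the root finders
    never react to numerical residue.
    """
    p = params.with_(epsilon=epsilon_mutant, n0=n0)
    grid = closed_form_grid(p, p.n_compartments, 0)

    def size(t):
        v = np.asarray(grid(t), dtype=float)
        noise = np.asarray(grid.noise_floor(t), dtype=float)
        out = np.where(v > noise, v, 0.0)
        return float(out) if out.ndim == 0 else out

    return size


def burden_fraction(
    params: HierarchyParams,
    epsilon_mutant: float,
    t_units: float,
    constraints: BurdenConstraints,
) -> float:
    """Tumour-cell fraction of the mature compartment at time ``t_units``."""
    ref = constraints.reference_population
    if ref is None:
        ref = default_reference_population(params)
    fn = _mutant_size_fn(params, epsilon_mutant, constraints.founder_count)
    m = max(fn(t_units), 0.0)
    return m / (m + ref)


def time_to_burden(
    params: HierarchyParams,
    epsilon_mutant: float,
    constraints: BurdenConstraints,
    burden: float | None = None,
    t_max_months: float = 600.0,
) -> float:
    """Months until the mutant clone first reaches the burden fraction.

    ``burden`` defaults to the lower end of the constraint range.  Raises
    :class:`UnreachableBurdenError` when the wave peaks and washes out below
    the requested load.
    """
    params = validate_params(params)
    if burden is None:
        burden = constraints.burden_fraction_range[0]
    ref = constraints.reference_population
    if ref is None:
        ref = default_reference_population(params)
    fn = _mutant_size_fn(params, epsilon_mutant, constraints.founder_count)
    target = burden / (1.0 - burden) * ref if burden < 1 else math.inf

    t_hi = months_to_units(t_max_months)
    ts = np.linspace(0.0, t_hi, 2049)
    vals = np.maximum(fn(ts), 0.0)
    above = np.nonzero(vals >= target)[0]
    if above.size == 0:
        raise UnreachableBurdenError(
            f"burden {burden:.3g} is never reached within {t_max_months} months"
        )
    j = int(above[0])
    if j == 0:
        return 0.0
    lo, hi = ts[j - 1], ts[j]
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if fn(mid) >= target:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-9 * max(hi, 1.0):
            break
    return units_to_months(0.5 * (lo + hi))


def _solve_epsilon_for(
    params: HierarchyParams,
    constraints: BurdenConstraints,
    burden: float,
    months: float,
    tol: float = 1e-4,
) -> float:
    """eps such that the clone first reaches ``burden`` exactly at ``months``.

    ``time_to_burden`` is increasing in eps (smaller eps, larger clone,
    earlier load), so bisection applies.  The search is restricted to
    eps >= 0.55: closer to the critical point 1/2 the transit slows down and
    the crossing time is no longer monotone in eps.
    """
    params = validate_params(params)
    u = params.u
    lo = 0.55
    hi = 1.0 - u - 1e-12

    def t_of(eps):
        try:
            return time_to_burden(params, eps, constraints, burden=burden)
        except UnreachableBurdenError:
            return math.inf

    if t_of(lo) > months or t_of(hi) < months:
        raise InfeasibleConstraintsError(
            "infeasible constraints: no differentiation probability in "
            "(1/2 + u, 1 - u] reaches the burden at the required time"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if t_of(mid) <= months:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def estimate_epsilon_from_burden(
    params: HierarchyParams, constraints: BurdenConstraints, tol: float = 1e-4
) -> EpsilonInterval:
    """Invert the clonal-wave forward map against the constraint box.

    The interval endpoints map to the extremes of the box by monotonicity:
    the lower eps reaches the maximal burden at the start of the diagnosis
    window, the upper eps reaches the minimal burden at its end.
    """
    b_lo, b_hi = constraints.burden_fraction_range
    t_lo, t_hi = constraints.diagnosis_window_months
    eps_low = _solve_epsilon_for(params, constraints, b_hi, t_lo, tol)
    eps_high = _solve_epsilon_for(params, constraints, b_lo, t_hi, tol)
    if eps_low > eps_high:
        raise InfeasibleConstraintsError(
            "infeasible constraints: burden/window box maps to an empty interval"
        )
    return EpsilonInterval(low=eps_low, high=eps_high)


def all_case_study(
    params: HierarchyParams,
    constraints: BurdenConstraints | None = None,
    excluded_compartments=(30, 31),
) -> dict:
    """Complete case-study pipeline for the inferred mutant clone.

    Returns the inferred eps interval, the months to reach the minimal load
    at both endpoints, and the predicted distinct-mutation range (with and
    without mutation events of the late compartments).
    """
    params = validate_params(params)
    if constraints is None:
        constraints = BurdenConstraints()
    interval = estimate_epsilon_from_burden(params, constraints)
    i_last = params.n_compartments
    excluded = {j for j in excluded_compartments if j <= i_last}

    def _at(eps):
        p = params.with_(epsilon=eps, n0=1.0)
        return (
            expected_diversity(p, i_last, 1),
            diversity_with_exclusions(p, i_last, excluded, 1),
        )

    d_high_eps, dx_high_eps = _at(interval.high)  # smaller counts
    d_low_eps, dx_low_eps = _at(interval.low)  # larger counts
    # each endpoint reaches its defining burden corner at its defining time,
    # so the months-to-load range reproduces the diagnosis window (inverse
    # consistency of the box mapping)
    months = sorted(
        (
            time_to_burden(
                params, interval.low, constraints,
                burden=constraints.burden_fraction_range[1],
            ),
            time_to_burden(
                params, interval.high, constraints,
                burden=constraints.burden_fraction_range[0],
            ),
        )
    )
    return {
        "epsilon_interval": (interval.low, interval.high),
        "months_to_load": tuple(months),
        "diversity_range": (d_high_eps, d_low_eps),
        "diversity_range_excluding_late": (dx_high_eps, dx_low_eps),
        "excluded_compartments": sorted(excluded),
        "constraints": constraints,
    }
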