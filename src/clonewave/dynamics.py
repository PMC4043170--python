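"""Deterministic dynamics of clonal waves in a hierarchical tissue.

The expected occupancies ``N_i^k(t)`` (compartment ``i``, mutation count
``k``) obey the linear system

    dN_i^k/dt = (1 - 2*alpha_i^k) * r_i * N_i^k
                + 2 * eps_{i-1}^k * r_{i-1} * N_{i-1}^k
                + u * r_i * N_i^{k-1}

with ``alpha = eps + u`` and initial condition ``N_i^k(0) = n0`` for the
founder class and zero elsewhere.  Gains are influx from upstream (two
daughters per differentiation), mutation inflow from the class below and
self-renewal; losses are differentiation and mutation out of the class.

Because the system is lower triangular in ``(i, k)``, the solution is a sum
of polynomial-times-exponential terms (a Bateman-type chain; mutation inflow
within a compartment repeats the eigenvalue and lifts the polynomial degree).
:class:`ExpPoly` carries this representation exactly, which provides closed
forms for arbitrary ``i`` and ``k`` as well as exact time integrals.  The
adaptive-step numerical integrator :func:`integrate_dynamics` is retained as
an independent oracle for all closed forms.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .params import HierarchyParams, RateSchedule, validate_params

__all__ = [
    "ExpPoly",
    "TrajectoryGrid",
    "PeakSummary",
    "assemble_flow_rates",
    "integrate_dynamics",
    "closed_form_grid",
    "closed_form_unmutated",
    "closed_form_multimutant",
    "peak_summary",
    "peak_numeric",
    "cumulative_count",
    "AccumulationRegimeError",
]

#: relative gap below which two decay rates are merged into one eigenvalue
#: (polynomial lift) instead of dividing by their difference.
RATE_MERGE_TOL = 1e-9

_LD = np.longdouble


class AccumulationRegimeError(ValueError):
    """Raised when a wave-regime quantity is requested with alpha <= 1/2."""


# ----------------------------------------------------------------------
# exact polynomial x exponential representation
# ----------------------------------------------------------------------
class ExpPoly:
    """A function ``f(t) = sum_j P_j(t) * exp(-lam_j * t)``.

    Polynomials are stored as ascending-power longdouble coefficient arrays
    keyed by the decay rate ``lam``.  Supports the three operations needed to
    solve the occupancy chain exactly: linear combination, solving
    ``y' = -lam*y + f`` with ``y(0)`` given, and definite integration.
    """

    __slots__ = ("terms",)

    def __init__(self, terms=None):
        self.terms: dict = {} if terms is None else terms

    # -- construction --------------------------------------------------
    @classmethod
    def exponential(cls, coeff: float, lam: float) -> "ExpPoly":
        return cls({float(lam): np.array([coeff], dtype=_LD)})

    def _key(self, lam: float) -> float:
        """Merge nearly identical decay rates to avoid dividing by a
        vanishing rate gap (repeated-rate degeneracy, e.g. gamma = 1)."""
        for existing in self.terms:
            scale = max(abs(existing), abs(lam), 1e-300)
            if abs(existing - lam) <= RATE_MERGE_TOL * scale:
                return existing
        return float(lam)

    def add_term(self, lam: float, coeffs: np.ndarray) -> None:
        key = self._key(lam)
        cur = self.terms.get(key)
        if cur is None:
            self.terms[key] = np.array(coeffs, dtype=_LD)
        else:
            n = max(cur.size, len(coeffs))
            out = np.zeros(n, dtype=_LD)
            out[: cur.size] += cur
            out[: len(coeffs)] += np.asarray(coeffs, dtype=_LD)
            self.terms[key] = out

    def scaled(self, factor: float) -> "ExpPoly":
        return ExpPoly({lam: c * _LD(factor) for lam, c in self.terms.items()})

    def __add__(self, other: "ExpPoly") -> "ExpPoly":
        out = ExpPoly({lam: c.copy() for lam, c in self.terms.items()})
        for lam, c in other.terms.items():
            out.add_term(lam, c)
        return out

    # -- evaluation ----------------------------------------------------
    def __call__(self, t):
        t_arr = np.asarray(t, dtype=_LD)
        total = np.zeros(t_arr.shape, dtype=_LD)
        for lam, coeffs in self.terms.items():
            poly = np.zeros(t_arr.shape, dtype=_LD)
            for c in coeffs[::-1]:
                poly = poly * t_arr + c
            with np.errstate(over="ignore", under="ignore"):
                total = total + poly * np.exp(-_LD(lam) * t_arr)
        result = np.asarray(total, dtype=float)
        return float(result) if np.isscalar(t) or result.ndim == 0 else result

    def at_zero(self) -> float:
        return float(sum(c[0] for c in self.terms.values()))

    def noise_floor(self, t) -> float | np.ndarray:
        """Estimate of the cancellation noise of ``self(t)``.

        Bateman-type sums cancel almost completely at small ``t`` when the
        coefficients are large and alternating; anything below
        ``machine_eps * sum_j |P_j|(t) e^(-lam_j t)`` is numerically zero.
        """
        t_arr = np.asarray(t, dtype=_LD)
        total = np.zeros(t_arr.shape, dtype=_LD)
        for lam, coeffs in self.terms.items():
            poly = np.zeros(t_arr.shape, dtype=_LD)
            for c in np.abs(coeffs)[::-1]:
                poly = poly * np.abs(t_arr) + c
            with np.errstate(over="ignore", under="ignore"):
                total = total + poly * np.exp(-_LD(lam) * t_arr)
        result = np.asarray(total * _LD(1e-17), dtype=float)
        return float(result) if np.isscalar(t) or result.ndim == 0 else result

    # -- calculus ------------------------------------------------------
    def solve_linear_ode(self, lam_new: float, y0: float) -> "ExpPoly":
        """Solve ``y' = -lam_new * y + self(t)`` with ``y(0) = y0``.

        For a source ``Q(t) e^{-mu t}`` the particular solution is
        ``R(t) e^{-mu t}`` with ``R' + (lam_new - mu) R = Q``; when the rates
        coincide the response is secular, ``R = integral(Q)``.
        """
        sol = ExpPoly()
        lam_new = float(lam_new)
        for mu, coeffs in self.terms.items():
            scale = max(abs(mu), abs(lam_new), 1e-300)
            if abs(mu - lam_new) <= RATE_MERGE_TOL * scale:
                # resonant: R(t) = integral of Q, constant of integration 0
                integ = np.zeros(coeffs.size + 1, dtype=_LD)
                integ[1:] = coeffs / np.arange(1, coeffs.size + 1, dtype=_LD)
                sol.add_term(lam_new, integ)
            else:
                d = _LD(lam_new) - _LD(mu)
                # R = sum_m (-1)^m Q^{(m)} / d^{m+1}
                R = np.zeros_like(coeffs)
                Q = coeffs.copy()
                sign = _LD(1.0)
                power = d
                while Q.size:
                    R[: Q.size] += sign * Q / power
                    Q = Q[1:] * np.arange(1, Q.size, dtype=_LD)
                    sign = -sign
                    power = power * d
                sol.add_term(mu, R)
        # homogeneous term fixes the initial condition
        sol.add_term(lam_new, np.array([_LD(y0) - _LD(sol.at_zero())]))
        return sol

    def integral(self, t: float | None = None) -> float:
        """``int_0^t self(s) ds``; ``t=None`` gives the limit t -> infinity.

        The infinite limit requires every decay rate to be positive (wave
        regime); otherwise the integral diverges.
        """
        total = _LD(0.0)
        for lam, coeffs in self.terms.items():
            if lam <= 0 and t is None:
                if np.any(coeffs != 0):
                    return math.inf
                continue
            if abs(lam) < 1e-300:
                if t is None:
                    return math.inf
                # plain polynomial integral
                integ = coeffs / np.arange(1, coeffs.size + 1, dtype=_LD)
                val = _LD(0.0)
                for c in integ[::-1]:
                    val = val * _LD(t) + c
                total += val * _LD(t)
                continue
            # antiderivative of P e^{-lam s} is -S(s) e^{-lam s} with
            # S = (P + S') / lam  (solved by back-substitution)
            S = np.zeros_like(coeffs)
            for m in range(coeffs.size - 1, -1, -1):
                deriv = S[m + 1] * _LD(m + 1) if m + 1 < S.size else _LD(0.0)
                S[m] = (coeffs[m] + deriv) / _LD(lam)
            s0 = S[0]
            if t is None:
                total += s0
            else:
                val = _LD(0.0)
                for c in S[::-1]:
                    val = val * _LD(t) + c
                with np.errstate(over="ignore", under="ignore"):
                    total += s0 - val * np.exp(-_LD(lam) * _LD(t))
        return float(total)


# ----------------------------------------------------------------------
# data containers
# ----------------------------------------------------------------------
@dataclass
class TrajectoryGrid:
    """Expected occupancies on a time grid.

    ``counts[i - 1, k, m]`` is ``N_i^k(times[m])``.
    """

    times: np.ndarray
    counts: np.ndarray
    params: HierarchyParams = field(repr=False, default=None)

    def occupancy(self, compartment: int, k: int) -> np.ndarray:
        return self.counts[compartment - 1, k, :]


@dataclass(frozen=True)
class PeakSummary:
    """Clonal-wave maximum in the founder compartment for mutation count k.

    ``n_peak`` is the Stirling-approximation value; ``n_peak_exact`` keeps the
    exact ``k!``.  For ``k = 0`` the wave peaks at t = 0 with ``n0`` cells.
    """

    k: int
    t_peak: float
    n_peak: float
    n_peak_exact: float


# ----------------------------------------------------------------------
# the flow field (right-hand side of the ODE system)
# ----------------------------------------------------------------------
def assemble_flow_rates(
    state: np.ndarray, params: HierarchyParams, schedule: RateSchedule
) -> np.ndarray:
    """Time derivative of the occupancy grid under the compartment model.

    ``state`` has shape ``(n_compartments, k_max + 1)``.  The derivative of
    class ``(i, k)`` collects influx from upstream (``2 eps r N`` — two
    daughters per differentiation), mutation inflow from ``(i, k - 1)``,
    self-renewal gain and the differentiation/mutation losses; boundary terms
    are absent in the first compartment and the k = 0 class.
    """
    state = np.asarray(state, dtype=float)
    expected = (params.n_compartments, params.k_max + 1)
    if state.shape != expected:
        raise ValueError(f"state has shape {state.shape}, expected {expected}")
    eps = params.eps_table
    u = params.u
    r = schedule.rates[:, None]
    net = (1.0 - 2.0 * (eps + u)) * r * state
    influx = np.zeros_like(state)
    influx[1:, :] = 2.0 * eps[:-1, :] * schedule.rates[:-1, None] * state[:-1, :]
    mut = np.zeros_like(state)
    mut[:, 1:] = u * r * state[:, :-1]
    return net + influx + mut


# ----------------------------------------------------------------------
# numerical oracle
# ----------------------------------------------------------------------
def integrate_dynamics(
    params: HierarchyParams,
    t_grid: np.ndarray,
    rtol: float = 1e-10,
    atol: float | None = None,
) -> TrajectoryGrid:
    """Adaptive-step solution of the occupancy system on ``t_grid``.

    The grid must be increasing and start at zero.  LSODA handles the
    stiffness induced by the geometric rate span (up to ``gamma**31``).
    """
    params = validate_params(params)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1:
        raise ValueError("t_grid must be a non-empty vector")
    if t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be increasing and start at 0")
    schedule = params.rate_schedule()
    shape = (params.n_compartments, params.k_max + 1)
    y0 = np.zeros(shape)
    y0[params.founder_compartment - 1, 0] = params.n0
    if atol is None:
        atol = params.n0 * 1e-12

    def rhs(_t, y):
        return assemble_flow_rates(y.reshape(shape), params, schedule).ravel()

    if t_grid.size == 1:  # only t = 0 requested
        counts = y0[:, :, None].copy()
        return TrajectoryGrid(times=t_grid, counts=counts, params=params)

    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid[-1])),
        y0.ravel(),
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover - surfaced with diagnostics
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    counts = sol.y.reshape(shape + (t_grid.size,))
    return TrajectoryGrid(times=t_grid, counts=counts, params=params)


# ----------------------------------------------------------------------
# closed forms
# ----------------------------------------------------------------------
def closed_form_grid(params: HierarchyParams, i: int, k: int) -> ExpPoly:
    """Exact solution ``N_i^k(t)`` as an :class:`ExpPoly`.

    Built by recursive variation of constants down the (i, k) chain; for
    constant parameters this reproduces the Bateman-type closed form with the
    combinatoric (psi) coefficients generated for any mutation count.
    Repeated proliferation rates (e.g. ``gamma = 1``) are handled exactly by
    the resonant (secular) branch.
    """
    params = validate_params(params)
    if not 1 <= i <= params.n_compartments:
        raise ValueError(f"compartment {i} out of range")
    if not 0 <= k <= params.k_max:
        raise ValueError(f"mutation count {k} exceeds k_max = {params.k_max}")
    schedule = params.rate_schedule()
    eps = params.eps_table
    u = params.u
    f = params.founder_compartment

    cache: dict[tuple[int, int], ExpPoly] = {}

    def solve(ci: int, ck: int) -> ExpPoly:
        if ci < f:
            return ExpPoly()
        key = (ci, ck)
        if key in cache:
            return cache[key]
        r_i = schedule.rate(ci)
        lam = (2.0 * (eps[ci - 1, ck] + u) - 1.0) * r_i
        source = ExpPoly()
        if ci > f:
            upstream = solve(ci - 1, ck)
            coeff = 2.0 * eps[ci - 2, ck] * schedule.rate(ci - 1)
            source = source + upstream.scaled(coeff)
        if ck > 0:
            below = solve(ci, ck - 1)
            source = source + below.scaled(u * r_i)
        y0 = params.n0 if (ci == f and ck == 0) else 0.0
        result = source.solve_linear_ode(lam, y0)
        cache[key] = result
        return result

    return solve(i, k)


def closed_form_unmutated(params: HierarchyParams, i: int, t) -> float | np.ndarray:
    """Expected number of unmutated cells in compartment ``i`` at time ``t``
    (the k = 0 Bateman chain)."""
    return closed_form_grid(params, i, 0)(t)


def closed_form_multimutant(
    params: HierarchyParams, i: int, k: int, t
) -> float | np.ndarray:
    """Expected number of ``k``-mutant cells in compartment ``i`` at ``t``."""
    return closed_form_grid(params, i, k)(t)


# ----------------------------------------------------------------------
# wave peak in the founder compartment
# ----------------------------------------------------------------------
def _founder_alpha_rate(params: HierarchyParams, k: int) -> tuple[float, float]:
    f = params.founder_compartment
    alpha = float(params.alpha_table[f - 1, min(k, params.k_max)])
    r_f = params.rate_schedule().rate(f)
    return alpha, r_f


def peak_summary(params: HierarchyParams, k: int) -> PeakSummary:
    """Time and size of the k-mutant wave maximum in the founder compartment.

    In the founder compartment the k-mutant class is
    ``N(t) = n0 (u r t)^k e^{-(2a-1) r t} / k!``, so the maximum sits at
    ``t_peak = k / ((2 alpha - 1) r)`` — equally spaced in ``k`` — with

        n_peak_exact = n0 (u k / (2 alpha - 1))^k e^{-k} / k!
        n_peak       = n0 (u / (2 alpha - 1))^k / sqrt(2 pi k)   (Stirling)

    the latter exposing the ``u^k`` suppression per extra mutation.
    """
    params = validate_params(params)
    if k < 0:
        raise ValueError("k must be non-negative")
    alpha, r_f = _founder_alpha_rate(params, k)
    if alpha <= 0.5:
        raise AccumulationRegimeError(
            "no finite peak: founder compartment is in the accumulation regime"
        )
    s = 2.0 * alpha - 1.0
    if k == 0:
        return PeakSummary(k=0, t_peak=0.0, n_peak=params.n0, n_peak_exact=params.n0)
    t_peak = k / (s * r_f)
    log_exact = (
        math.log(params.n0)
        + k * (math.log(params.u) + math.log(k) - math.log(s) - 1.0)
        - math.lgamma(k + 1)
    )
    n_exact = math.exp(log_exact)
    n_stirling = params.n0 * (params.u / s) ** k / math.sqrt(2.0 * math.pi * k)
    return PeakSummary(k=k, t_peak=t_peak, n_peak=n_stirling, n_peak_exact=n_exact)


def peak_numeric(
    params: HierarchyParams, k: int, n_grid: int = 4001
) -> tuple[float, float]:
    """Numerically located maximum of the founder-compartment k-mutant wave
    (grid search refined by golden-section), for validating the formulas."""
    params = validate_params(params)
    alpha, r_f = _founder_alpha_rate(params, k)
    if alpha <= 0.5:
        raise AccumulationRegimeError("no finite peak in the accumulation regime")
    fn = closed_form_grid(params, params.founder_compartment, k)
    t_hi = max(4.0 * (k + 1) / ((2 * alpha - 1) * r_f), 1.0 / r_f)
    ts = np.linspace(0.0, t_hi, n_grid)
    vals = fn(ts)
    j = int(np.argmax(vals))
    lo, hi = ts[max(j - 1, 0)], ts[min(j + 1, n_grid - 1)]
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    for _ in range(80):
        if fn(c) > fn(d):
            b, d = d, c
            c = b - invphi * (b - a)
        else:
            a, c = c, d
            d = a + invphi * (b - a)
    t_star = 0.5 * (a + b)
    return float(t_star), float(fn(t_star))


# ----------------------------------------------------------------------
# cumulative production
# ----------------------------------------------------------------------
def cumulative_count(
    params: HierarchyParams, i: int, k: int, t: float | None = None
) -> float:
    """Cells of class ``(i, k)`` produced (departures) up to time ``t``.

    The departure flux is ``alpha_i^k * r_i * N_i^k`` — each division sends
    the cell out of its class with probability ``alpha = eps + u`` — and the
    integral is evaluated exactly from the closed form.  ``t = None`` takes
    the infinite-time limit, which equals the reproductive capacity
    ``W_i^k``; in the accumulation regime that limit is flagged infinite.
    """
    params = validate_params(params)
    if t is not None and t < 0:
        raise ValueError("t must be non-negative")
    fn = closed_form_grid(params, i, k)
    alpha = float(params.alpha_table[i - 1, k])
    r_i = params.rate_schedule().rate(i)
    value = fn.integral(t)
    if math.isinf(value):
        warnings.warn(
            "cumulative count diverges (accumulation regime)", RuntimeWarning
        )
        return math.inf
    return alpha * r_i * value
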