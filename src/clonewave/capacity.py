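"""Reproductive capacity of a single founder cell in the hierarchy.

``W_i^k`` is the expected number of cells of the founder's lineage that ever
depart compartment ``i`` carrying ``k`` mutations (departure = differentiation
or mutation).  For the founder compartment a geometric sum over the number of
self-renewals before departure gives

    W_f^0 = sum_{l>=1} 2^{l-1} (eps+u) (1-eps-u)^{l-1} = alpha / (2*alpha - 1),

finite only in the wave regime ``alpha > 1/2``.  Downstream and mutant
classes follow from the recursion: arrivals into ``(i, k)`` are two cells per
differentiation departure of ``(i-1, k)`` plus one cell per mutation
departure of ``(i, k-1)``, and each arrival founds ``alpha/(2*alpha-1)``
departures of its own:

    W_i^k = [ 2 eps_{i-1}^k W_{i-1}^k + u W_i^{k-1} ] / (2 alpha - 1)   (neutral)

with the general per-class form implemented in :func:`capacity_general`.
With constant ``eps`` and ``u`` the recursion has the closed form

    W_i^k = c * C(i - f + k, k) * a^(i-f) * b^k,
    a = 2 eps/(2 alpha - 1),  b = u/(2 alpha - 1),  c = alpha/(2 alpha - 1),

independent of the proliferation rates: the lineage's composition does not
depend on how fast it unfolds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import HierarchyParams, validate_params

__all__ = [
    "CapacityTable",
    "founder_capacity",
    "capacity_general",
    "capacity_neutral",
    "hierarchy_ratios",
    "neutral_coefficients",
    "DivergentCapacityError",
]


class DivergentCapacityError(ValueError):
    """Raised when a finite capacity is requested for alpha <= 1/2."""


@dataclass
class CapacityTable:
    """Reproductive capacities ``W[i - 1, k]`` with per-class divergence flags.

    A divergent entry (some contributing class has ``alpha <= 1/2``) is stored
    as ``inf`` and flagged; divergence propagates to every class downstream
    of, or mutationally above, the divergent one.
    """

    W: np.ndarray
    divergent: np.ndarray
    params: HierarchyParams = None

    def value(self, compartment: int, k: int) -> float:
        return float(self.W[compartment - 1, k])

    def is_divergent(self, compartment: int, k: int) -> bool:
        return bool(self.divergent[compartment - 1, k])


def neutral_coefficients(params: HierarchyParams) -> tuple[float, float, float]:
    """Return ``(a, b, c)`` for a neutral (constant-epsilon) parameter set."""
    eps = params.epsilon_scalar
    alpha = eps + params.u
    s = 2.0 * alpha - 1.0
    if s <= 0:
        raise DivergentCapacityError(
            "capacity diverges: alpha = eps + u <= 1/2 (accumulation regime)"
        )
    return 2.0 * eps / s, params.u / s, alpha / s


def founder_capacity(epsilon: float, u: float) -> float:
    """Reproductive capacity of one cell in its own compartment.

    Closed value of ``sum_{l>=1} 2^(l-1) (eps+u)(1-eps-u)^(l-1)``
    = ``alpha/(2 alpha - 1)``.  Raises :class:`DivergentCapacityError` when
    ``alpha <= 1/2`` (the sum is infinite) and equals 1 when ``eps + u = 1``
    (the cell departs at its first division).
    """
    alpha = epsilon + u
    if not 0 < alpha <= 1:
        raise ValueError("epsilon + u must lie in (0, 1]")
    if alpha <= 0.5:
        raise DivergentCapacityError(
            "the geometric series diverges for alpha = eps + u <= 1/2"
        )
    return alpha / (2.0 * alpha - 1.0)


def capacity_general(params: HierarchyParams) -> CapacityTable:
    """Capacity table from the recursion, for arbitrary per-class epsilon.

    Evaluation is k-major then i-outward from the founder, so the
    dependencies ``(i-1, k)`` and ``(i, k-1)`` are final when each entry is
    filled.  Entries whose own class or any contributing class has
    ``alpha <= 1/2`` are flagged divergent and propagate.
    """
    params = validate_params(params)
    n, km = params.n_compartments, params.k_max
    f = params.founder_compartment
    eps = params.eps_table
    u = params.u
    alpha = params.alpha_table
    W = np.zeros((n, km + 1))
    div = np.zeros((n, km + 1), dtype=bool)
    for k in range(km + 1):
        for i in range(f, n + 1):
            ii = i - 1
            arrivals = 0.0
            bad = False
            if i == f and k == 0:
                arrivals = 1.0
            if i > f:
                up_alpha = alpha[ii - 1, k]
                if div[ii - 1, k]:
                    bad = True
                elif W[ii - 1, k] > 0:
                    arrivals += 2.0 * (eps[ii - 1, k] / up_alpha) * W[ii - 1, k]
            if k > 0:
                if div[ii, k - 1]:
                    bad = True
                elif W[ii, k - 1] > 0:
                    arrivals += (u / alpha[ii, k - 1]) * W[ii, k - 1]
            if arrivals == 0.0 and not bad:
                continue
            s = 2.0 * alpha[ii, k] - 1.0
            if bad or s <= 0:
                W[ii, k] = math.inf
                div[ii, k] = True
            else:
                W[ii, k] = arrivals * alpha[ii, k] / s
    return CapacityTable(W=W, divergent=div, params=params)


def capacity_neutral(params: HierarchyParams, i: int, k: int) -> float:
    """Closed-form capacity for constant ``eps`` and ``u`` (neutral mutants).

    Evaluated in log space so compartment numbers up to 31 and beyond stay
    finite; independent of ``gamma`` and ``r0`` by construction.
    """
    params = validate_params(params)
    if not 1 <= i <= params.n_compartments:
        raise ValueError(f"compartment {i} out of range")
    if k < 0:
        raise ValueError("k must be non-negative")
    f = params.founder_compartment
    if i < f:
        return 0.0
    a, b, c = neutral_coefficients(params)
    if k > 0 and params.u == 0.0:
        return 0.0
    m = i - f
    log_w = (
        math.log(c)
        + math.lgamma(m + k + 1)
        - math.lgamma(k + 1)
        - math.lgamma(m + 1)
        + m * math.log(a)
        + (k * math.log(b) if k else 0.0)
    )
    return math.exp(log_w)


def hierarchy_ratios(params: HierarchyParams, i: int, k: int) -> tuple[float, float]:
    """Suppression/amplification ratios of the neutral capacity table.

    Returns ``(W_i^k / W_i^{k-1}, W_{i+1}^k / W_i^k)``:

    * mutation-load ratio ``b * (i - f + k) / k`` — constant in ``k`` at the
      founder compartment, increasing with compartment number but flattening
      as ``k`` grows;
    * compartment-growth ratio ``a * (i - f + 1 + k) / (i - f + 1)`` —
      constant (= ``a``) for ``k = 0`` and suppressed like ``1/i`` in the
      hierarchy for ``k > 0``.
    """
    params = validate_params(params)
    if k < 1:
        raise ValueError("mutation-load ratio undefined for k = 0")
    f = params.founder_compartment
    if i < f:
        raise ValueError("ratios undefined upstream of the founder compartment")
    if i + 1 > params.n_compartments:
        raise ValueError("compartment i + 1 out of range")
    a, b, _c = neutral_coefficients(params)
    m = i - f
    load_ratio = b * (m + k) / k
    growth_ratio = a * (m + 1 + k) / (m + 1)
    return load_ratio, growth_ratio
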