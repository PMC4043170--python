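"""Parameter containers and presets for the hierarchical compartment model.

The tissue is modelled as a chain of proliferating non-stem compartments
``i = 1..n_compartments``.  A dividing cell in compartment ``i`` carrying
``k`` mutations either

* differentiates with probability ``eps[i, k]`` (both daughters move to
  compartment ``i + 1``),
* mutates with probability ``u`` (one cell with ``k + 1`` mutations replaces
  it in compartment ``i``), or
* self-renews with probability ``1 - eps[i, k] - u`` (an additional cell in
  compartment ``i``).

Cells proliferate at per-cell rate ``r_i = gamma**i * r0``.  The quantity
``alpha = eps + u`` (the probability of leaving the current class) governs
the qualitative behaviour: ``alpha > 1/2`` produces a transient clonal wave
that washes out of the hierarchy, ``alpha < 1/2`` produces unbounded
accumulation.

Stem cells (compartment 0) are not modelled dynamically; the founder clone
is placed directly into ``founder_compartment`` (default 1), matching the
initial condition of the deterministic system.

Time unit: one unit is ``1/r0`` of a stem-cell generation.  With the
haematopoietic default ``r0 = 1/400`` and one stem-cell division per year,
400 time units correspond to one year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Union

import numpy as np

__all__ = [
    "HierarchyParams",
    "RateSchedule",
    "build_rate_schedule",
    "validate_params",
    "preset",
    "PRESETS",
    "UNITS_PER_YEAR",
    "UNITS_PER_MONTH",
    "months_to_units",
    "units_to_months",
    "years_to_units",
    "units_to_years",
]

#: model time units per calendar year (one stem-cell division per year at
#: r0 = 1/400 means 400 units elapse per year).
UNITS_PER_YEAR = 400.0
UNITS_PER_MONTH = UNITS_PER_YEAR / 12.0


def months_to_units(months: float) -> float:
    return months * UNITS_PER_MONTH


def units_to_months(units: float) -> float:
    return units / UNITS_PER_MONTH


def years_to_units(years: float) -> float:
    return years * UNITS_PER_YEAR


def units_to_years(units: float) -> float:
    return units / UNITS_PER_YEAR


class ParameterError(ValueError):
    """Raised when a parameter set violates a model invariant."""


EpsilonSpec = Union[float, Mapping, np.ndarray]


@dataclass(frozen=True)
class RateSchedule:
    """Per-compartment proliferation rates ``r_i = gamma**i * r0``.

    ``rates[0]`` corresponds to compartment 1 (stem cells, compartment 0,
    are excluded from the schedule).
    """

    rates: np.ndarray

    def __post_init__(self):
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", rates)
        if rates.ndim != 1 or rates.size < 1:
            raise ParameterError("rate schedule must be a non-empty vector")
        if np.any(rates <= 0):
            raise ParameterError("invalid rate: proliferation rates must be positive")

    def rate(self, compartment: int) -> float:
        """Rate of compartment ``compartment`` (1-based)."""
        return float(self.rates[compartment - 1])

    def __len__(self) -> int:
        return self.rates.size


def build_rate_schedule(gamma: float, r0: float, n_compartments: int) -> RateSchedule:
    """Geometric proliferation-rate schedule ``r_i = gamma**i * r0``.

    Parameters
    ----------
    gamma:
        Per-compartment growth factor of the proliferation rate (> 0).
        ``gamma > 1`` gives strictly increasing rates downstream.
    r0:
        Stem-cell proliferation rate (divisions per time unit, > 0).
    n_compartments:
        Number of non-stem compartments (>= 1).
    """
    if gamma <= 0:
        raise ParameterError("invalid rate: gamma must be positive")
    if r0 <= 0:
        raise ParameterError("invalid rate: r0 must be positive")
    if n_compartments < 1:
        raise ParameterError("invalid rate: need at least one compartment")
    i = np.arange(1, n_compartments + 1)
    return RateSchedule(rates=(gamma ** i) * r0)


@dataclass(frozen=True)
class HierarchyParams:
    """Full parameter set of the hierarchical compartment model.

    Attributes
    ----------
    n_compartments:
        Number of non-stem compartments (haematopoietic default: 31).
    gamma:
        Proliferation-rate growth factor per compartment.
    r0:
        Stem-cell proliferation rate (divisions per time unit).
    u:
        Mutation probability per cell division.
    epsilon:
        Differentiation probability.  A scalar is broadcast to every
        compartment and mutation class; a ``(n_compartments, k_max + 1)``
        array (or nested mapping ``{compartment: {k: eps}}``) gives the
        general per-class parametrization.
    n0:
        Founder cell count.
    founder_compartment:
        1-based compartment in which the founder clone starts.
    k_max:
        Truncation of the mutation-count ladder for numerics.  Mass arriving
        in class ``k_max`` is reported so truncation leakage is observable.
    """

    n_compartments: int = 31
    gamma: float = 1.26
    r0: float = 1.0 / 400.0
    u: float = 1e-6
    epsilon: EpsilonSpec = 0.85
    n0: float = 1.0
    founder_compartment: int = 1
    k_max: int = 5

    # filled by validate_params
    _eps_table: np.ndarray = field(default=None, repr=False, compare=False)

    # ------------------------------------------------------------------
    # derived quantities
    # ------------------------------------------------------------------
    @property
    def eps_table(self) -> np.ndarray:
        """Differentiation probabilities, shape (n_compartments, k_max + 1)."""
        if self._eps_table is None:
            return _broadcast_epsilon(self)
        return self._eps_table

    @property
    def alpha_table(self) -> np.ndarray:
        """alpha[i, k] = eps[i, k] + u, the probability of leaving class (i, k)."""
        return self.eps_table + self.u

    @property
    def is_neutral(self) -> bool:
        """True when every class shares one differentiation probability."""
        t = self.eps_table
        return bool(np.all(t == t.flat[0]))

    @property
    def epsilon_scalar(self) -> float:
        """The common differentiation probability (neutral parameters only)."""
        if not self.is_neutral:
            raise ParameterError("parameter set is not neutral (epsilon varies)")
        return float(self.eps_table.flat[0])

    @property
    def accumulation_regime(self) -> bool:
        """True if any class has alpha <= 1/2 (unbounded accumulation)."""
        return bool(np.any(self.alpha_table <= 0.5))

    def rate_schedule(self) -> RateSchedule:
        return build_rate_schedule(self.gamma, self.r0, self.n_compartments)

    def with_(self, **kwargs) -> "HierarchyParams":
        """Copy with replaced fields, re-validated."""
        return validate_params(replace(self, _eps_table=None, **kwargs))


def _broadcast_epsilon(params: HierarchyParams) -> np.ndarray:
    shape = (params.n_compartments, params.k_max + 1)
    eps = params.epsilon
    if np.isscalar(eps):
        return np.full(shape, float(eps))
    if isinstance(eps, Mapping):
        table = np.full(shape, np.nan)
        try:
            for comp, row in eps.items():
                ci = int(comp)
                if not 1 <= ci <= params.n_compartments:
                    raise ParameterError(
                        f"invalid epsilon table: compartment {ci} out of range"
                    )
                if np.isscalar(row):
                    table[ci - 1, :] = float(row)
                else:
                    for k, val in row.items():
                        ki = int(k)
                        if not 0 <= ki <= params.k_max:
                            raise ParameterError(
                                f"invalid epsilon table: mutation count {ki} out of range"
                            )
                        table[ci - 1, ki] = float(val)
        except (TypeError, ValueError) as exc:
            raise ParameterError(f"invalid epsilon table: {exc}") from exc
        if np.any(np.isnan(table)):
            raise ParameterError(
                "invalid epsilon table: every (compartment, k) entry must be set"
            )
        return table
    arr = np.asarray(eps, dtype=float)
    if arr.shape != shape:
        raise ParameterError(
            f"invalid epsilon table: expected shape {shape}, got {arr.shape}"
        )
    return arr.copy()


def validate_params(params: HierarchyParams) -> HierarchyParams:
    """Check all model invariants and tabulate the epsilon/alpha tables.

    Raises
    ------
    ParameterError
        If probabilities fall outside (0, 1], ``eps + u > 1``, rates are
        non-positive, or index bounds are violated.
    """
    if params.n_compartments < 1:
        raise ParameterError("invalid rate: need at least one compartment")
    if params.k_max < 0:
        raise ParameterError("invalid truncation: k_max must be >= 0")
    if not 0 <= params.u < 1:
        raise ParameterError("probabilities exceed one: u must lie in [0, 1)")
    if params.r0 <= 0 or params.gamma <= 0:
        raise ParameterError("invalid rate: r0 and gamma must be positive")
    if params.n0 < 1:
        raise ParameterError("founder cell count n0 must be >= 1")
    if not 1 <= params.founder_compartment <= params.n_compartments:
        raise ParameterError(
            "founder_compartment must lie between 1 and n_compartments"
        )
    table = _broadcast_epsilon(params)
    if np.any(table <= 0):
        raise ParameterError("invalid epsilon: differentiation probability must be > 0")
    if np.any(table + params.u > 1.0 + 1e-15):
        raise ParameterError("probabilities exceed one: epsilon + u > 1")
    validated = replace(params, _eps_table=table)
    return validated


# ----------------------------------------------------------------------
# presets
# ----------------------------------------------------------------------
def _haematopoiesis() -> HierarchyParams:
    """Human haematopoiesis: 31 compartments, eps = 0.85, gamma = 1.26,
    u = 1e-6, r0 = 1/400 (one stem-cell division per year)."""
    return HierarchyParams(
        n_compartments=31,
        gamma=1.26,
        r0=1.0 / 400.0,
        u=1e-6,
        epsilon=0.85,
        n0=1.0,
        founder_compartment=1,
        k_max=5,
    )


def _test_small() -> HierarchyParams:
    """Five-compartment hierarchy with inflated mutation rate for fast
    stochastic tests; stays in the wave regime (alpha > 1/2)."""
    return HierarchyParams(
        n_compartments=5,
        gamma=1.26,
        r0=1.0,
        u=1e-3,
        epsilon=0.85,
        n0=1.0,
        founder_compartment=1,
        k_max=3,
    )


PRESETS = {
    "haematopoiesis": _haematopoiesis,
    "test-small": _test_small,
}


def preset(name: str) -> HierarchyParams:
    """Return a validated preset parameter set.

    Known presets: ``haematopoiesis`` and ``test-small``.
    """
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    return validate_params(factory())
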