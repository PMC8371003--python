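"""Core model types and right-hand sides for the reef/no-take-zone fishery model.

The system couples fish biomass and open-access fishing effort in two
patches: a no-take zone containing an artificial reef (AR) of volume ``V``
and a surrounding open-access fishing area.  Fish move fast between the
patches toward an ideal free distribution (IFD), perturbed by an attraction
effect of the reef; effort redistributes fast according to the illegal
fishing rate ``gamma``.  Slow dynamics are logistic growth, harvesting and
profit-driven effort adjustment (Gordon-Schaefer).  A singular-perturbation
reduction on the fast manifold yields an aggregated two-variable system for
total biomass ``n`` and total effort ``E``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Callable, NamedTuple

__all__ = [
    "Parameters",
    "ZoneState",
    "AggregateState",
    "ZoneCapacities",
    "ConfigurationError",
    "attraction",
    "register_attraction",
    "attraction_forms",
    "zone_capacities",
    "nu1_star",
    "full_rhs",
    "reduced_rhs",
]


class ConfigurationError(ValueError):
    """Invalid parameter value or unknown configuration key/form."""


# --------------------------------------------------------------------------
# attraction-function registry
#
# beta(V) is the perturbation of fish immigration into the no-take zone
# beyond the IFD; it must vanish at V=0 and be non-decreasing in V.
# The default multiplicative-saturating form scales the baseline
# immigration rate a/((1-alpha)K), saturating at beta0 times that rate.

_ATTRACTION_FORMS: dict[str, Callable[[float, "Parameters"], float]] = {}


def register_attraction(name: str, fn: Callable[[float, "Parameters"], float]) -> None:
    """Register an attraction closed form ``fn(V, params) -> rate increment``.

    Registered forms become selectable through ``Parameters.attraction_form``.
    """
    _ATTRACTION_FORMS[name] = fn


def attraction_forms() -> tuple[str, ...]:
    """Names of all registered attraction forms."""
    return tuple(_ATTRACTION_FORMS)


def _beta_multiplicative(V: float, p: "Parameters") -> float:
    base = p.a / ((1.0 - p.alpha) * p.K)
    return p.beta0 * base * (1.0 - math.exp(-p.sigma * V))


def _beta_absolute(V: float, p: "Parameters") -> float:
    return p.beta0 * (1.0 - math.exp(-p.sigma * V))


def _beta_linear(V: float, p: "Parameters") -> float:
    return p.beta0 * p.sigma * V


register_attraction("multiplicative_saturating", _beta_multiplicative)
register_attraction("absolute_saturating", _beta_absolute)
register_attraction("linear", _beta_linear)

DEFAULT_ATTRACTION_FORM = "multiplicative_saturating"


# --------------------------------------------------------------------------
# parameter container


@dataclass(frozen=True)
class Parameters:
    """All model constants.

    Required fields are the scenario-dependent quantities (reef volume,
    illegal-fishing rate, and the two reef-effect parameters, for which the
    reference configuration lists two alternative values each); the rest
    default to the reference parameter set.

    Units: biomass in tons, reef volume in m^3, money in price units; rates
    are per slow-time unit except ``a`` and ``mu`` (per fast-time unit).
    """

    V: float
    gamma: float
    beta0: float
    delta_k: float
    r: float = 0.5
    K: float = 100.0
    a: float = 2.0
    c: float = 1.0
    p: float = 1.0
    q1: float = 1.0
    q2: float = 1.0
    alpha: float = 0.2
    sigma: float = 0.1
    epsilon: float = 0.1
    mu: float = 1.0
    attraction_form: str = DEFAULT_ATTRACTION_FORM

    def __post_init__(self) -> None:
        pos = ("r", "K", "a", "c", "p", "q1", "q2", "sigma", "mu", "beta0", "delta_k")
        for name in pos:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ConfigurationError(f"parameter {name!r} must be finite and >= 0, got {v}")
        for name in ("r", "K", "a", "c", "p", "q1", "q2", "mu"):
            if getattr(self, name) == 0:
                raise ConfigurationError(f"parameter {name!r} must be strictly positive")
        # both zone capacities must stay strictly positive
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must lie strictly in (0, 1), got {self.alpha}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigurationError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.V < 0:
            raise ConfigurationError(f"V must be >= 0, got {self.V}")
        # epsilon = 0 is the pure-movement (fast-subsystem) limit
        if not 0.0 <= self.epsilon <= 1.0:
            raise ConfigurationError(f"epsilon must lie in [0, 1], got {self.epsilon}")
        if self.attraction_form not in _ATTRACTION_FORMS:
            raise ConfigurationError(
                f"unknown attraction_form {self.attraction_form!r}; "
                f"registered: {sorted(_ATTRACTION_FORMS)}"
            )

    # -- derived quantities (never cached: recomputed on each access) ------

    @property
    def q(self) -> float:
        """Common catchability; defined only when q1 == q2."""
        if self.q1 != self.q2:
            raise ConfigurationError("q is ambiguous: q1 != q2")
        return self.q1

    @property
    def m1(self) -> float:
        """Fast effort-migration rate into the no-take zone."""
        return self.gamma * self.mu

    @property
    def m2(self) -> float:
        """Fast effort-migration rate out of the no-take zone."""
        return (1.0 - self.gamma) * self.mu

    def evolve(self, **changes: float | str) -> "Parameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    def to_dict(self) -> dict[str, float | str]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class ZoneState(NamedTuple):
    """Per-zone state: biomass and effort in the no-take zone (1) and fishing area (2)."""

    n1: float
    n2: float
    E1: float
    E2: float


class AggregateState(NamedTuple):
    """Aggregated state: total biomass and total effort."""

    n: float
    E: float


class ZoneCapacities(NamedTuple):
    """Carrying capacities of the no-take zone (incl. reef production) and fishing area."""

    K1: float
    K2: float


# --------------------------------------------------------------------------
# operations


def attraction(V: float, params: Parameters) -> float:
    """Attraction-driven increment to the fish immigration rate into zone 1.

    Vanishes without a reef and saturates (or grows linearly, depending on
    the selected form) with reef volume.
    """
    if V < 0:
        raise ConfigurationError(f"V must be >= 0, got {V}")
    return _ATTRACTION_FORMS[params.attraction_form](V, params)


def zone_capacities(params: Parameters) -> ZoneCapacities:
    """K1 = alpha*K + V*delta_k (no-take zone plus reef production), K2 = (1-alpha)*K."""
    return ZoneCapacities(
        K1=params.alpha * params.K + params.V * params.delta_k,
        K2=(1.0 - params.alpha) * params.K,
    )


def _migration_rates(params: Parameters) -> tuple[float, float]:
    """(A, B): fish emigration rate from zone 1, immigration rate into zone 1."""
    K1, K2 = zone_capacities(params)
    A = params.a / K1
    B = params.a / K2 + attraction(params.V, params)
    return A, B


def nu1_star(params: Parameters) -> float:
    """Equilibrium fraction of fish biomass in the no-take zone.

    Balance point of the fast movement subsystem: B*n2 = A*n1 with
    A = a/K1 and B = a/K2 + beta(V), giving nu1* = B/(A+B).  Without
    attraction this is the IFD fraction K1/(K1+K2).
    """
    A, B = _migration_rates(params)
    return B / (A + B)


def full_rhs(state: ZoneState, params: Parameters) -> tuple[float, float, float, float]:
    """Time derivatives of (n1, n2, E1, E2) in fast time.

    Fast terms: fish migration at rates B (into zone 1) and A (out of it),
    effort redistribution at rates m1 = gamma*mu (into) and m2 = (1-gamma)*mu
    (out).  Slow terms, scaled by epsilon: logistic growth against the zone
    capacity, harvest q_i*n_i*E_i, and profit-driven effort adjustment
    (p*q_i*n_i - c)*E_i.
    """
    n1, n2, E1, E2 = state
    if min(n1, n2, E1, E2) < 0:
        raise ValueError(f"state components must be >= 0, got {tuple(state)}")
    K1, K2 = zone_capacities(params)
    A, B = _migration_rates(params)
    eps = params.epsilon
    m1, m2 = params.m1, params.m2
    dn1 = B * n2 - A * n1 + eps * (
        params.r * n1 * (1.0 - n1 / K1) - params.q1 * n1 * E1
    )
    dn2 = A * n1 - B * n2 + eps * (
        params.r * n2 * (1.0 - n2 / K2) - params.q2 * n2 * E2
    )
    dE1 = m1 * E2 - m2 * E1 + eps * (params.p * params.q1 * n1 - params.c) * E1
    dE2 = m2 * E1 - m1 * E2 + eps * (params.p * params.q2 * n2 - params.c) * E2
    return (dn1, dn2, dE1, dE2)


def reduced_rhs(state: AggregateState, params: Parameters) -> tuple[float, float]:
    """Time derivatives of (n, E) in slow time, on the fast manifold.

    With nu1* the fast-equilibrium biomass fraction in the no-take zone and
    gamma the effort fraction applied there:

        dn/dt = r n (1 - nu1*^2 n / K1 - (1-nu1*)^2 n / K2)
                - q gamma nu1* n E - q (1-gamma)(1-nu1*) n E
        dE/dt = (p q gamma nu1* n + p q (1-gamma)(1-nu1*) n - c) E

    Uses the common catchability q (requires q1 == q2).
    """
    n, E = state
    if n < 0 or E < 0:
        raise ValueError(f"state components must be >= 0, got {tuple(state)}")
    K1, K2 = zone_capacities(params)
    nu = nu1_star(params)
    q = params.q
    harvest_weight = params.gamma * nu + (1.0 - params.gamma) * (1.0 - nu)
    dn = (
        params.r * n * (1.0 - nu * nu * n / K1 - (1.0 - nu) ** 2 * n / K2)
        - q * harvest_weight * n * E
    )
    dE = (params.p * q * harvest_weight * n - params.c) * E
    return (dn, dE)
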