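"""Closed-form equilibrium of the reduced model and catch decomposition.

At an interior (bionomic) equilibrium of the aggregated system, profit per
unit effort is zero, pinning the stock at n* = c/(p q Q) with
Q = gamma*nu1* + (1-gamma)(1-nu1*) the effective harvest weight; the
logistic balance then gives the effort E*.  When n* would exceed the
aggregate carrying capacity K_eff the fishery is not economically viable
and the system settles on the boundary equilibrium (K_eff, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model_core import Parameters, nu1_star, zone_capacities

__all__ = [
    "Equilibrium",
    "DegeneratePolicyError",
    "interior_equilibrium",
    "catch_crossing_gamma",
    "k_eff",
    "EQUILIBRIUM_COLUMNS",
]

# fixed serialization order for equilibrium records
EQUILIBRIUM_COLUMNS = (
    "V",
    "gamma",
    "beta0",
    "sigma",
    "delta_k",
    "nu1_star",
    "Q",
    "K_eff",
    "n_star",
    "E_star",
    "catch_total",
    "catch_ar",
    "catch_fish",
    "viable",
)

# relative slack keeping float ties out of the viability classification
_VIABILITY_TIE_TOL = 1e-12


class DegeneratePolicyError(ValueError):
    """Harvest weight Q = 0: no stock is exposed to any effort."""


@dataclass(frozen=True)
class Equilibrium:
    """Equilibrium of the reduced model with its catch decomposition.

    ``catch_ar`` and ``catch_fish`` are the equilibrium harvest rates taken
    on the reef/no-take zone and in the open-access fishing area; ``viable``
    is True iff a positive-effort equilibrium exists.
    """

    nu1_star: float
    Q: float
    K_eff: float
    n_star: float
    E_star: float
    catch_total: float
    catch_ar: float
    catch_fish: float
    viable: bool

    def to_record(self, params: Parameters) -> dict[str, float | bool]:
        """Flat record (fixed column order) for tabular export."""
        rec = {
            "V": params.V,
            "gamma": params.gamma,
            "beta0": params.beta0,
            "sigma": params.sigma,
            "delta_k": params.delta_k,
        }
        for name in EQUILIBRIUM_COLUMNS[5:]:
            rec[name] = getattr(self, name)
        return rec


def k_eff(params: Parameters) -> float:
    """Aggregate carrying capacity 1 / (nu1*^2/K1 + (1-nu1*)^2/K2).

    Equals K1 + K2 exactly in the pure-IFD limit (no attraction).
    """
    K1, K2 = zone_capacities(params)
    nu = nu1_star(params)
    return 1.0 / (nu * nu / K1 + (1.0 - nu) ** 2 / K2)


def harvest_weight(params: Parameters) -> float:
    """Q = gamma*nu1* + (1-gamma)(1-nu1*): stock fraction effectively fished."""
    nu = nu1_star(params)
    return params.gamma * nu + (1.0 - params.gamma) * (1.0 - nu)


def interior_equilibrium(params: Parameters) -> Equilibrium:
    """Equilibrium stock, effort and catch decomposition of the reduced model.

    Zero-profit gives n* = c/(p q Q); the biomass balance gives
    E* = r (1 - n*/K_eff) / (q Q).  If n* >= K_eff no positive effort can
    break even and the boundary equilibrium (n, E) = (K_eff, 0) is returned
    with ``viable=False`` (a complete record, not an error, so parameter
    sweeps stay total).
    """
    nu = nu1_star(params)
    Q = harvest_weight(params)
    if Q == 0.0:
        raise DegeneratePolicyError(
            f"harvest weight Q = 0 (gamma={params.gamma}, nu1*={nu}): "
            "all effort is assigned to a zone holding no fish"
        )
    q = params.q
    Keff = k_eff(params)
    n_star = params.c / (params.p * q * Q)
    viable = n_star < Keff * (1.0 - _VIABILITY_TIE_TOL)
    if viable:
        E_star = params.r * (1.0 - n_star / Keff) / (q * Q)
        catch_ar = q * params.gamma * nu * n_star * E_star
        catch_fish = q * (1.0 - params.gamma) * (1.0 - nu) * n_star * E_star
    else:
        n_star = Keff
        E_star = 0.0
        catch_ar = catch_fish = 0.0
    return Equilibrium(
        nu1_star=nu,
        Q=Q,
        K_eff=Keff,
        n_star=n_star,
        E_star=E_star,
        catch_total=catch_ar + catch_fish,
        catch_ar=catch_ar,
        catch_fish=catch_fish,
        viable=viable,
    )


def catch_crossing_gamma(params: Parameters) -> float:
    """Illegal-fishing rate at which reef catch equals fishing-area catch.

    Setting q*gamma*nu1*·n*E = q*(1-gamma)(1-nu1*)·n*E gives the closed form
    gamma = 1 - nu1*, independent of the equilibrium stock and effort.
    """
    nu = nu1_star(params)
    if nu <= 0.0 or nu >= 1.0:
        raise DegeneratePolicyError(f"catch crossing undefined for nu1* = {nu}")
    return 1.0 - nu
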