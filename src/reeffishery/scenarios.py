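"""Parameter sweeps and feature finders over reef volume and illegal fishing.

Every sweep row is a fresh equilibrium computation; tables are tidy pandas
DataFrames with the fixed equilibrium column set plus the swept values and
a scenario label, so they serialize deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .equilibrium import DegeneratePolicyError, interior_equilibrium
from .model_core import Parameters

__all__ = [
    "sweep_volume",
    "sweep_gamma",
    "grid_attraction_production",
    "find_optimal_volume",
    "find_viability_threshold",
    "sensitivity_suite",
    "annulus_width",
    "OptimumResult",
    "ThresholdResult",
    "DEFAULT_GAMMA_LEVELS",
]

# effort levels highlighted in the volume sweep: 0..75% of total effort
DEFAULT_GAMMA_LEVELS = (0.0, 0.05, 0.10, 0.15, 0.25, 0.50, 0.75)

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _equilibrium_row(params: Parameters, label: str) -> dict:
    try:
        rec = interior_equilibrium(params).to_record(params)
        rec["error"] = ""
    except DegeneratePolicyError as exc:
        rec = {
            "V": params.V,
            "gamma": params.gamma,
            "beta0": params.beta0,
            "sigma": params.sigma,
            "delta_k": params.delta_k,
            "nu1_star": math.nan,
            "Q": math.nan,
            "K_eff": math.nan,
            "n_star": math.nan,
            "E_star": math.nan,
            "catch_total": math.nan,
            "catch_ar": math.nan,
            "catch_fish": math.nan,
            "viable": False,
            "error": str(exc),
        }
    rec["scenario"] = label
    return rec


def sweep_volume(
    params: Parameters,
    V_grid: Sequence[float],
    gamma_list: Sequence[float] = DEFAULT_GAMMA_LEVELS,
    label: str = "volume_sweep",
) -> pd.DataFrame:
    """Equilibrium record per (V, gamma) over the full Cartesian product."""
    if len(V_grid) == 0 or len(gamma_list) == 0:
        raise ValueError("V_grid and gamma_list must be non-empty")
    rows = [
        _equilibrium_row(params.evolve(V=float(V), gamma=float(g)), label)
        for g in gamma_list
        for V in V_grid
    ]
    return pd.DataFrame(rows)


def sweep_gamma(
    params: Parameters,
    gamma_grid: Sequence[float],
    V: float | None = None,
    label: str = "gamma_sweep",
) -> pd.DataFrame:
    """Equilibrium record per gamma at fixed reef volume."""
    if len(gamma_grid) == 0:
        raise ValueError("gamma_grid must be non-empty")
    base = params if V is None else params.evolve(V=float(V))
    rows = [_equilibrium_row(base.evolve(gamma=float(g)), label) for g in gamma_grid]
    return pd.DataFrame(rows)


def grid_attraction_production(
    params: Parameters,
    beta0_list: Sequence[float],
    delta_k_list: Sequence[float],
    gamma_grid: Sequence[float],
    V: float = 200.0,
    label: str = "attraction_production_grid",
) -> pd.DataFrame:
    """Equilibrium records over beta0 x delta_k x gamma at fixed reef volume."""
    rows = [
        _equilibrium_row(
            params.evolve(V=float(V), beta0=float(b), delta_k=float(dk), gamma=float(g)),
            label,
        )
        for b in beta0_list
        for dk in delta_k_list
        for g in gamma_grid
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OptimumResult:
    """Outcome of a 1-D catch maximisation over reef volume.

    ``kind`` is 'interior' when a genuine interior maximum was refined,
    'monotone_increasing' / 'monotone_decreasing' when catch is monotone
    over the bracket (no interior optimum exists there), or 'boundary' when
    the maximum sits at a bracket endpoint without overall monotonicity.
    """

    kind: str
    V_opt: float | None
    catch: float | None


def _catch_at_V(params: Parameters, gamma: float):
    def f(V: float) -> float:
        return interior_equilibrium(params.evolve(V=float(V), gamma=gamma)).catch_total

    return f


def find_optimal_volume(
    params: Parameters,
    gamma: float,
    V_bracket: tuple[float, float] = (0.0, 600.0),
    coarse_points: int = 121,
    tol: float = 1e-6,
) -> OptimumResult:
    """Reef volume maximising equilibrium total catch, or a monotonicity verdict.

    A coarse grid locates the maximum; an interior peak is refined by
    golden-section search.  If catch is monotone across the bracket the
    verdict is returned instead of an endpoint masquerading as an optimum.
    Plateau ties break to the smallest volume.
    """
    lo, hi = V_bracket
    if not (0.0 <= lo < hi):
        raise ValueError(f"invalid bracket {V_bracket}")
    f = _catch_at_V(params, gamma)
    grid = np.linspace(lo, hi, coarse_points)
    vals = np.array([f(V) for V in grid])
    i_max = int(np.argmax(vals))  # argmax takes the first (smallest-V) tie
    diffs = np.diff(vals)
    mono_tol = 1e-12 * max(1.0, float(np.abs(vals).max()))
    if i_max == len(grid) - 1 and np.all(diffs >= -mono_tol):
        return OptimumResult("monotone_increasing", None, float(vals[-1]))
    if i_max == 0 and np.all(diffs <= mono_tol):
        return OptimumResult("monotone_decreasing", None, float(vals[0]))
    if i_max in (0, len(grid) - 1):
        return OptimumResult("boundary", float(grid[i_max]), float(vals[i_max]))
    # golden-section refinement inside the bracketing triple
    a, b = float(grid[i_max - 1]), float(grid[i_max + 1])
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1, f2 = f(x1), f(x2)
    while b - a > tol:
        if f1 < f2:
            a, x1, f1 = x1, x2, f2
            x2 = a + _GOLDEN * (b - a)
            f2 = f(x2)
        else:
            b, x2, f2 = x2, x1, f1
            x1 = b - _GOLDEN * (b - a)
            f1 = f(x1)
    V_opt = 0.5 * (a + b)
    return OptimumResult("interior", V_opt, f(V_opt))


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a 1-D viability-boundary search."""

    found: bool
    axis: str
    value: float | None


def _viability_margin(params: Parameters, axis: str, x: float) -> float:
    """K_eff - n_star: positive where the fishery is viable."""
    p = params.evolve(**{("V" if axis == "V" else "gamma"): float(x)})
    eq = interior_equilibrium(p)
    # boundary records overwrite n_star with K_eff; recompute the margin
    n_star = p.c / (p.p * p.q * eq.Q)
    return eq.K_eff - n_star


def find_viability_threshold(
    params: Parameters,
    axis: str,
    bracket: tuple[float, float],
    coarse_points: int = 61,
    rel_tol: float = 1e-6,
) -> ThresholdResult:
    """Parameter value where economic viability flips, found by bisection.

    Scans ``axis`` ('V' or 'gamma') over the bracket for a sign change of
    K_eff - n*, then bisects to relative precision.  Returns
    ``found=False`` ('no transition') when the whole bracket is on one side.
    """
    if axis not in ("V", "gamma"):
        raise ValueError(f"axis must be 'V' or 'gamma', got {axis!r}")
    lo, hi = bracket
    if not lo < hi:
        raise ValueError(f"invalid bracket {bracket}")
    grid = np.linspace(lo, hi, coarse_points)
    margins = np.array([_viability_margin(params, axis, x) for x in grid])
    signs = np.sign(margins)
    flips = np.nonzero(np.diff(signs) != 0)[0]
    if len(flips) == 0:
        return ThresholdResult(found=False, axis=axis, value=None)
    a, b = float(grid[flips[0]]), float(grid[flips[0] + 1])
    fa = _viability_margin(params, axis, a)
    scale = max(abs(a), abs(b), 1e-12)
    while b - a > rel_tol * scale:
        mid = 0.5 * (a + b)
        fm = _viability_margin(params, axis, mid)
        if (fa < 0) == (fm < 0):
            a, fa = mid, fm
        else:
            b = mid
    return ThresholdResult(found=True, axis=axis, value=0.5 * (a + b))


_SENSITIVITY_PARAMS = frozenset({"r", "K", "c", "p", "q", "a"})


def sensitivity_suite(
    base: Parameters,
    spec: Mapping[str, Iterable[float]],
    label: str = "sensitivity",
) -> pd.DataFrame:
    """One-at-a-time sweeps of the biological/economic constants.

    ``spec`` maps a parameter name in {r, K, c, p, q, a} to the values to
    try; each row is an equilibrium record tagged with the varied parameter.
    """
    bad = set(spec) - _SENSITIVITY_PARAMS
    if bad:
        raise ValueError(f"sensitivity restricted to {sorted(_SENSITIVITY_PARAMS)}; got {sorted(bad)}")
    rows = []
    for name, values in spec.items():
        for v in values:
            changes = {"q1": float(v), "q2": float(v)} if name == "q" else {name: float(v)}
            rec = _equilibrium_row(base.evolve(**changes), label)
            rec["param"] = name
            rec["value"] = float(v)
            rows.append(rec)
    return pd.DataFrame(rows)


def annulus_width(ntz_radius: float, alpha: float) -> float:
    """Width of the fishing annulus making a circular no-take zone an alpha fraction.

    A disc of radius R is an alpha fraction of a disc of radius
    R/sqrt(alpha); the surrounding ring is R*(1/sqrt(alpha) - 1) wide.
    """
    if ntz_radius <= 0:
        raise ValueError(f"radius must be > 0, got {ntz_radius}")
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    return ntz_radius * (1.0 / math.sqrt(alpha) - 1.0)
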