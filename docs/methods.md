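# Methods

## Model structure and assumptions

The package models a coastal fishery managed by an artificial reef (AR)
placed in a circular no-take zone surrounded by an open-access fishing
annulus. Four standing assumptions define the scope:

1. fish population growth is logistic;
2. landings are catchability × biomass × effort (Schaefer harvest);
3. effort follows profit (open-access Gordon dynamics): it grows where
   revenue `p·q·n_i` exceeds cost `c` per unit effort and shrinks otherwise;
4. the reef has both a *production* effect (extra carrying capacity
   `V·δk` added to the no-take zone) and an *attraction* effect (a
   perturbation `β(V)` of fish movement toward the reef beyond the ideal
   free distribution).

Movement of fish and boats between the two patches is fast relative to
growth and capital dynamics. The full system is written in fast time with
the slow terms scaled by ε; aggregation of variables (the singular
perturbation limit ε → 0) replaces the four-dimensional system with a
two-dimensional one on the fast manifold, where the biomass fraction in
the no-take zone is `ν₁* = B/(A+B)` (`A = a/K1`, `B = a/K2 + β(V)`) and
the effort fraction there is γ. The model is single-species (a community
aggregate), closed (no migration across the domain boundary), and
two-patch; none of those restrictions can be lifted without structural
changes.

A note on the full system's effort equations: pure redistribution must
conserve total effort, so the two effort migration terms are exact mirrors
(`m1·E2 − m2·E1` and `m2·E1 − m1·E2`). With `m1 = γμ`, `m2 = (1−γ)μ` the
fast effort equilibrium allocates exactly the fraction γ of effort to the
no-take zone, which is what γ means in the reduced model.

## Parameters

| symbol | meaning | unit | default |
|---|---|---|---|
| r | intrinsic growth rate | 1/slow-time | 0.5 |
| K | baseline carrying capacity of the whole area | tons | 100 |
| a | fish mobility (IFD relaxation) | 1/fast-time | 2 |
| c | cost per unit effort | money/effort | 1 |
| p | fish price | money/ton | 1 |
| q1, q2 | catchability per zone | 1/(effort·slow-time) | 1 |
| α | no-take fraction of the area | — | 0.2 |
| V | reef volume | m³ | scenario |
| δk | extra capacity per reef volume | tons/m³ | 0.1 or 5, per scenario |
| β0 | attraction strength | — | 0.1 or 1, per scenario |
| σ | attraction saturation rate | 1/m³ | 0.1 |
| γ | illegal-effort fraction | — | scenario, 0–1 |
| ε | timescale separation | — | 0.1 |
| μ | effort redistribution speed | 1/fast-time | 1 |

The two-valued entries (β0, δk) are deliberately never defaulted in config
loading: a scenario must choose the weak or strong variant. The reduced
model and all equilibrium quantities are independent of ε and μ; they only
shape full-model transients. ε = 0 is allowed and gives the pure-movement
(fast subsystem) limit used for conservation checks.

Scenario presets bundle the reference scenarios: a volume sweep at
γ ∈ {0, 0.05, 0.10, 0.15, 0.25, 0.50, 0.75} (fig2a), γ-sweeps at fixed
V = 120, 200 and 500 m³ (fig2b, fig2c, fig2d), and the β0 × δk grid at
V = 200 m³ (fig3).

## The attraction function

The closed form of β(V) is not pinned down by the model's defining
equations, only its properties: β(0) = 0, non-negative, non-decreasing.
The package ships a registry of three forms:

- `multiplicative_saturating` (default):
  `β(V) = β0 · (a/((1−α)K)) · (1 − e^{−σV})` — an increment proportional
  to the baseline immigration rate `a/((1−α)K)`, which is the slot the
  term occupies in the equations. With the reference parameters this form
  reproduces the 6%-of-effort catch crossing at V = 120 m³ exactly
  (γ_cross = 1 − ν₁* = 0.0606).
- `absolute_saturating`: `β0·(1 − e^{−σV})`.
- `linear`: `β0·σ·V`.

Custom forms can be registered (`register_attraction`), which the test
suite uses to manufacture interior optima for validating the finders.

Under all three shipped forms, equilibrium catch at γ = 0 is monotone
increasing in V (production raises `K_eff` faster than attraction starves
the fishing area), so the model as shipped does **not** produce an interior
optimal reef volume near 120 m³, a viability cutoff near 256 m³, or an
optimal illegal-fishing rate of 1–3% at large V. These features evidently
require a different attraction closed form; the finders therefore return
an explicit "monotone" verdict rather than an endpoint dressed up as an
optimum, and the package makes no claim about those three numbers.
Likewise, with β ≡ 0 the model here shows production strongly increasing
catch, so no claim is made that production alone "minimally affects"
catch.

## Equilibrium and viability

`interior_equilibrium` evaluates the closed forms `n* = c/(pqQ)`,
`E* = r(1 − n*/K_eff)/(qQ)`; viability is `n* < K_eff·(1 − 1e−12)` (the
tolerance avoids float ties). Non-viable parameter sets return the
boundary equilibrium (n = K_eff, E = 0) as a complete record so sweep
tables have no holes. Stability is established numerically (long-time
integration converges to the analytic point), not symbolically.

`catch_crossing_gamma` uses the closed form γ = 1 − ν₁*; the acceptance
script deliberately recomputes the same quantity by bisection on the
equilibrium catch difference so the two routes stay independent.

## Numerical choices

- Integration uses LSODA (adaptive, stiffness-switching) with rtol 1e−9
  and atol 1e−12 by default, in 20 chunks with early exit once the
  relative RHS norm stays below 1e−8 at two successive checkpoints.
  Effort below 1e−10 with a quiet RHS counts as the boundary equilibrium.
- States are clipped to zero only for excursions smaller than 1e−9
  (logged); anything larger raises an integration error.
- The open-access equilibrium is a weakly damped spiral with decay time
  ≈ 2K_eff/(r·n*) — thousands of slow-time units for large reefs — so
  convergence-sensitive tests integrate horizons of 1e4–1.5e5 slow units
  rather than trusting a fixed short window. The default horizon of 2000
  slow units suits moderate scenarios; callers needing tight convergence
  at large K_eff should raise `t_end`.
- `find_optimal_volume` scans a 121-point coarse grid then refines an
  interior peak by golden-section search; ties break to the smallest
  volume. `find_viability_threshold` bisects the sign of `K_eff − n*` to
  relative 1e−6 after a 61-point scan.
- The full-model/reduced-model consistency check compares worst-case
  trajectory gaps at ε ∈ {0.02, 0.01, 0.005} and asserts the O(ε) scaling,
  because the dominant error is an O(ε) phase drift of the oscillation
  whose constant depends on the trajectory; far-from-equilibrium starts
  drive the stock through near-zero crashes where that constant blows up.

## Known limitations

- Single aggregated species; no trophic structure, recruitment lags, or
  seasonal forcing.
- Two spatial patches only; the geometry helper (annulus width
  `R(1/√α − 1)`, e.g. 618 m for R = 500 m, α = 0.2) is bookkeeping, not a
  spatially explicit model.
- Open-access effort dynamics exclude management instruments other than
  the no-take boundary itself (no quotas, licences, or discounting).
- Equilibrium tables describe long-run outcomes; transient catch is
  available through `integrate` but is not a management metric here.
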