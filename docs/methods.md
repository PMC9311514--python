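# Methods

## Model structure

The package implements a standard-DEB individual model: energy assimilated
from food enters a reserve compartment; mobilized reserve (the catabolic
flux `p_C`) is split by the κ rule, with the fraction κ paying
volume-proportional somatic maintenance and then growth of structure at cost
`[E_G]` per cm³, and the fraction 1−κ paying maturity maintenance and then
maturation (below the puberty threshold `E_Hp`) or the reproduction buffer
(above it). Life stages follow the maturity thresholds: embryos
(`E_H < E_Hb`) do not feed; first feeding starts at birth; metamorphosis at
`E_Hj` and puberty at `E_Hp` only relabel the stage under the default
configuration (see acceleration, below). All rates share one Arrhenius
temperature factor

```
kT(T) = exp(T_A/T_1 − T_A/T) / (1 + exp(T_AL/T − T_AL/T_L) + exp(T_AH/T_H − T_AH/T))
```

implemented exactly in this form. Note the factor is ≈ 0.811, not 1, at the
reference temperature `T_1` = 293 K, because the tolerance-range terms do
not vanish there; a variant normalized to 1 at `T_1` is available via
`temp_correction(..., normalized=True)` but is not used by the dynamics.
All quantities that scale a parameter set's rates inherit kT linearly, so
state-space trajectories (e.g. maturity against structure) are independent
of temperature; only the time axis stretches.

## Parameters

The default set (`data/default_params.yaml`) is the estimated kuruma shrimp
parameterization at 20 °C. Two constants required by the observation
equations are not part of that set and are derived once at load time:

- **μ_E (reserve energy content, J g⁻¹).** The wet-weight equation
  `W_w = (E + κ_R·E_R)/μ_E + ρ·V` needs the energy-to-mass conversion of
  reserve. It is back-calculated from the ultimate-state identity using the
  anchor pair (ultimate female length 19.83 cm, ultimate wet weight
  135.9 g) with `V_∞ = (19.83·δ_M)³`, `E_∞ = [E_m]·V_∞`, `E_R = 0`:
  μ_E ≈ 3919 J g⁻¹. This keeps the parameter set internally consistent; it
  can be overridden in the parameter file.
- **V_P (structure at puberty, cm³).** The maturity-maintenance clamp
  `min(V, V_P)` needs the structural volume at which puberty is reached.
  It is computed per parameter set by integrating maturity against
  structure along the reference (f = 1, equilibrium-reserve) trajectory
  until `E_H = E_Hp`; for the default set V_P ≈ 25.9 cm³. If the maturity
  asymptote stays below `E_Hp` (which happens for, e.g., +20% `[p_M]`),
  V_P is infinite and the clamp never binds.

Two redundancies in the printed set are resolved as follows:

- **Energy conductance.** The stored `v_dot` = 0.0336 cm d⁻¹ is not equal
  to `{p_Am}/[E_m]` = 0.1377 cm d⁻¹, but the catabolic-flux equation uses
  `{p_Am}/[E_m]` explicitly, so the dynamics follow the flux equations and
  `v_dot` is kept for reference only. This choice is what reproduces the
  ultimate sizes and the observed pond growth timescale (~12 cm in 180
  days at f = 0.62); the slower printed conductance would roughly triple
  the growth time constant.
- **Zoom factors.** `z` and `zm` are used only as the male/female ratio:
  males carry `{p_Am}·zm/z` (in both assimilation and mobilization, i.e.
  the male conductance scales the same way), everything else shared. The
  female ultimate structural length is exactly `κ·{p_Am}/[p_M]`
  independent of `[E_m]`, so the male/female length ratio is exactly
  `zm/z`.

## Numerical choices

- **Integrator.** Fixed-step classical RK4, default `dt` = 0.1 d
  (reproducible, and the dynamics are smooth); an explicit Euler option
  exists for comparison. Halving `dt` moves a 120-day trajectory's final
  length by < 0.01%. Forcing is linearly interpolated in time for both
  temperature and f.
- **Threshold crossings** (birth, puberty) are located by linear
  interpolation inside the step that crosses.
- **Initial egg reserve E0** solves the maternal-effect condition
  `E(birth)/V(birth) = [E_m]` by bracketing plus Brent root finding
  (relative tolerance 1e-5); embryo integration uses `dt` = 0.005 d from a
  vanishing initial structure (1e-9 cm³).
- **Starvation.** When `κ·p_C` cannot cover somatic maintenance the
  deficit is paid first from the reproduction buffer, then by mobilizing
  structure at `[E_G]` per unit volume; maturity never regresses. Death is
  declared when the scaled reserve density falls below 1e-6, the buffer is
  empty and structure has shrunk below 80% of its maximum — the density
  threshold is needed because reserve decays exponentially and never
  reaches zero exactly. Note a freshly starved but well-provisioned
  juvenile keeps growing transiently off its reserve; "no food ⇒ no
  growth" only holds once reserve density has fallen to the maintenance
  boundary (or immediately at the ultimate size).
- **Aging.** The Weibull/Gompertz damage-induction pair
  `dq/dt = (q·(V/V_m)·s_G + h_a)·e·(v/L − r) − r·q`, `dh/dt = q − r·h`
  (e: scaled reserve density, r: specific growth rate, v: mobilization
  conductance). These equations are imported standard-DEB theory — the
  parameter set provides `h_a` and `s_G` but no aging equations — and life
  span is reported as the mean of the survival curve
  `S(t) = exp(−∫h dt)`. Setting `h_a` = 0 freezes aging.
- **Acceleration.** An abj-style option (assimilation scaled by `L/L_b`
  between birth and metamorphosis, frozen at `L_j/L_b` after) is available
  behind `SimConfig(acceleration=True)` but off by default: the flux
  equations contain no acceleration term, and the ultimate-size
  predictions are reproduced without it.
- **Optimization.** Nelder–Mead simplex with the Lagarias et al.
  coefficients (reflection 1, expansion 2, contraction 0.5, shrink 0.5),
  initial simplex edge 5% of each coordinate (0.0025 absolute at zero),
  box bounds enforced by reflecting trial points into the box; it is
  cross-checked against an independent simplex implementation and a grid
  search in the tests. The scalar f fit uses golden-section search on
  [0, 1] with tolerance 1e-4. During estimation, a candidate parameter set
  for which a bundle entry has no prediction (e.g. puberty unreachable) is
  charged a large finite relative error (1e3) for that entry, so the rest
  of the bundle still steers the simplex back to feasibility.
- **Estimation loss.** Weighted MRE; the reported SMSE uses the bounded
  per-datum form `(p−d)²/(p²+d²)` (an interpretation — the name alone does
  not fix a formula). Pseudo-data priors and per-survey weighting are out
  of scope; weights default to 1.

## Synthetic pond scenario

The generator emulates a 180-day integrated-pond grow-out: stocking at
1.02 cm total length (initial reserve at the equilibrium density of the
feeding level, maturity at the metamorphosis threshold, reflecting stocked
post-larvae), sampling every 15 days (13 sampling rows including day 0),
30 individuals per sampling, constant true f = 0.62, and a seasonal
temperature stand-in (sinusoid, mean 24 °C, amplitude 6 °C, peak near day
75, daily Gaussian noise SD 0.8 °C — the real recorded series is
unpublished). Individual lengths and weights get mean-preserving
multiplicative lognormal noise at 5% CV by default; the table reports mean
and SD per sampling day. One integer seed drives separate reproducible
streams for temperature and observation noise. The generator's stated
initial *weight* (8.7 mg) is recorded for reference; the simulated initial
weight follows from the initial length and reserve convention and is
slightly higher — the length, not the weight, anchors the initial state.

What passing the round-trip tests shows: the estimator recovers the
feeding level (±0.005 noiseless, ±0.05 across 50 noisy replicates) and
perturbed rate parameters (`{p_Am}`, `[p_M]` within 5% from +20% starts)
when the data-generating process is the model itself. It does not show
robustness to real-pond features the generator omits: molting
discontinuities, size-dependent mortality and sampling bias, density
effects, non-constant feeding level, or model misspecification.

## Known limitations

- **Age-based life-history predictions disagree with the reference
  records under this parameter set.** With mobilization at
  `{p_Am}/[E_m]`, predicted age at birth at 27 °C is ~0.52 d (reference
  prediction 2.05 d) — the 2.05 d figure is recovered almost exactly if
  and only if the embryo mobilizes reserve at the slow printed `v_dot`,
  which would in turn destroy the juvenile/adult growth timescale, so the
  printed set cannot satisfy both. Similarly, time to puberty at 26 °C
  comes out ~241 d (reference 70 d) and the ultimate reproduction rate
  ~228 d⁻¹ (reference 1510 d⁻¹): with κ = 0.98 and the
  `min(V, V_P)·[p_M]·(1−κ)/κ` maturity maintenance at the derived V_P,
  the 1−κ branch nearly cancels at large sizes. These are internal
  inconsistencies of the parameter set as printed, not integration error;
  the package reproduces the sizes and growth dynamics and documents the
  age/rate discrepancies rather than silently re-tuning constants.

- Mean life span at 22 °C evaluates to ~974 d against the 728–730 d
  reference — plausible given the imported aging formulation, but the
  exact aging convention behind the reference value is unknown.

- Molting is not modelled (growth is continuous), there is no population
  layer, and the temperature series of the emulated pond is a stand-in.

## Problem sizes used by the shipped checks

The packaged validation runs use 400-day trajectories at `dt` = 0.1 d for
the von Bertalanffy identity, a 3000-day run for the ultimate-length
asymptote confirmation, 50 seeded replicates for noisy f recovery, and a
~150-iteration simplex for the two-parameter recovery; all sizes are set in
the tests/scripts themselves and chosen so the full pipeline demonstrates
convergence comfortably.
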