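# Methods

This note documents the model implemented by `codeal`, its assumptions,
the default parameterization, the synthetic testbed, and the numerical
choices a user should know before trusting (or extending) results.

## State variables and units

Time is in days. Pools are per kilogram of dry soil:

| symbol | meaning | units |
|--------|---------|-------|
| `N_1..N_6` | inorganic N pools, fixed order `NH4, NO3, NO2, NO, N2O, N2` | mg N kg⁻¹ |
| `E_1..E_6` | enzyme pools, aligned to the substrate each group consumes: `amo, nar, nir, nor, nos, fix` | mg enzyme-C kg⁻¹ |
| `ON` | organic N | mg N kg⁻¹ |
| `cumIn`, `cumOut` | cumulative boundary imports/exports | mg N kg⁻¹ |

Enzyme pools carry carbon and are deliberately excluded from the nitrogen
balance: converting the (small) N content of enzymes is ignored. This is a
loud simplification — conservation statements in this package are about
the seven N pools only.

## Allocation

At every instant the synthesis flux `pEP·B(t)` is divided among the six
groups by normalized weights:

* `A0`: `w_i = N_i` — raw concentration;
* `A1`: `w_i = N_i/Ks_i` — relative availability, the same quantity that
  orders the Michaelis–Menten saturation levels `N_i/(N_i+Ks_i)`;
* `A2`: `w_i = Ks_i/N_i` — the inverse, favoring scarce substrates and
  tending to equalize realized fluxes.

Coefficients are recomputed at every solver evaluation (no smoothing or
lag). Before weighting, each concentration is floored at a configurable
minimum so the inverse weighting stays finite at zero concentration. The
*function default* floor is 1e-10 mg N kg⁻¹, a pure numerical guard. The
*frozen testbed* uses 0.01 mg N kg⁻¹ instead, read as a microbial sensing
threshold: with the bare numerical guard, `A2` weights span ten orders of
magnitude and allocation degenerates to delta spikes on effectively empty
trace-gas pools, which no organism could express.

Because the coefficients sum to one, total gross enzyme production is
`∫ pEP·B dt` under **every** scheme. Consequently both Enz-Ninorg
readings — cumulative production, and the integrated standing pool (whose
total obeys `d(ΣE)/dt = pEP·B − rE·ΣE`) — are exactly scheme-invariant in
this reduced model. Allocation changes *where* enzymes go, never their
total cost; scheme contrasts in enzymatic efficiency therefore live in the
flux-per-production ratio. A host model with carbon–nitrogen feedback on
biomass could break this invariance; prescribing `B(t)` is what enforces
it here.

The static core of enzyme cost minimization is a rearrangement
(Chebyshev-type) inequality: for any state, the saturation-weighted
capacity `Σ f_i·sat_i` under `A1` is at least that under `A2`, with
equality exactly when all `N_i/Ks_i` coincide, because `A1`'s weights are
comonotone with the saturation levels and `A2`'s are anti-comonotone. The
property suite checks this on randomized inputs.

## Network topology (a reduced form)

* Nitrification is lumped into a single NH4 → NO3 step catalyzed by
  ammonia oxidases; NO2 arises only inside the denitrification chain
  NO3 → NO2 → NO → N2O → N2. This matches fitting the combined NO3+NO2
  observed pool and keeps one enzyme group per substrate.
* Fixation N2 → NH4 is inhibited by the factor `1 − NH4/(NH4+Ks_NH4)`;
  the multiplicative saturation-complement is this package's choice of
  functional form for ammonium inhibition.
* Mineralization ON → NH4 is first-order (`kmin·ON`); litter input `L(t)`
  feeds ON.
* Plant uptake of NH4 and NO3 is Michaelis–Menten scaled by a prescribed
  plant-activity factor `fplant(t) ∈ [0,1]` — plants are forcing, not
  state.
* NO and N2O escape as gases at first-order rates `gNO`, `gN2O`.
* Dinitrogen is by default a fixed boundary pool (soil N2 is effectively
  unlimited); fixation then imports N across the boundary and the final
  denitrification step exports it, both tracked by the accumulators. A
  `dynamic` switch closes the N2 pool for conservation audits:
  `total N − total N(0) = cumIn − cumOut` holds for the exact solution in
  both modes, and to integrator tolerance numerically.
* Microbial biomass `B(t)` is prescribed forcing; carbon dynamics are out
  of scope.

## Default parameters (the frozen testbed)

`scenarios.default_params()` pins the canonical testbed. Values are
order-of-magnitude realistic for a temperate grassland topsoil and are
frozen in version control; they are **not** a field calibration.

| parameter | value | units | rationale |
|-----------|-------|-------|-----------|
| `Vmax` (amo,nar,nir,nor,nos,fix) | 2.0, 1.5, 2.5, 4.0, 3.0, **0.3** | mg N (mg C)⁻¹ d⁻¹ | reductases fast; fixation slow — nitrogenase is metabolically expensive, keeping BNF a real but secondary flux |
| `Ks` (NH4,NO3,NO2,NO,N2O,N2) | 0.5, 8.0, 0.5, 0.3, 0.5, 50.0 | mg N kg⁻¹ | high NH4 affinity, weak NO3 affinity, moderate trace-gas affinities; N2 pool (150) well above its Ks |
| `pEP` | 2e-3 | d⁻¹ | with `B = 100` mg C kg⁻¹: 0.2 mg C kg⁻¹ d⁻¹ synthesis |
| `rE` | 0.02 | d⁻¹ | 50-day enzyme lifetime; equilibrium ΣE ≈ 10 mg C kg⁻¹ |
| `kmin` | 8e-4 | d⁻¹ | with ON ≈ 120: ≈ 0.1 mg N kg⁻¹ d⁻¹ mineralization |
| `Vup`, `Kup` | 0.3 / 0.3; 1.0 / 2.0 | mg N kg⁻¹ d⁻¹; mg N kg⁻¹ | seasonal plant sink comparable to mineralization |
| `gNO`, `gN2O` | 1.0, 0.5 | d⁻¹ | reactive trace gases vent quickly, keeping those pools source-limited |
| `n2_boundary` | 150 | mg N kg⁻¹ | fixed dinitrogen reservoir |

The deliberate regime: enzymatic processing capacity sits in modest excess
over the mineralization-fed N supply, so most transformations are
substrate-limited (as in real soil), while fixation — fed by the unlimited
N2 reservoir — is rate-limited and inhibited. In this regime the scenario
contrasts are non-degenerate: `A1` routes capacity where saturation is
high and achieves the largest Flux-Ninorg; `A0` over-allocates to the
huge-but-slow N2 substrate and bottlenecks at ammonia oxidation; `A2`
starves nitrogenase (N2 is the most saturated substrate, hence the
smallest inverse weight) and drives fixation to near zero. The six
saturation levels stay strongly heterogeneous (CV > 0.3 at mid-horizon),
which the test suite asserts.

## Synthetic scenarios and observations

`make_forcing` builds daily forcing over the horizon (default 12 years):
sinusoidal plant activity and litter input with a 365-day period peaking
in the growing season, constant biomass, constant (or pulsed) mineral-N
inputs. `make_observations` runs the noise-free model, samples six
observables (NH4 pool, combined NO3+NO2 pool, fixation, net N
mineralization, nitrification, plant uptake) on a 30-day grid, and applies
independent mean-one multiplicative lognormal noise per replicate,
observable and time (default CV 20 %, 24 replicates). Paired scheme
comparisons perturb the forcing series (one mean-one lognormal factor per
series per replicate — a between-replicate fertility difference) and reuse
each replicate forcing across all schemes.

What the generator does **not** emulate: weather variability, treatment
structure of a real fertilization experiment, spatially correlated errors,
autocorrelated noise, or carbon–nitrogen feedback on biomass. Passing
tests therefore demonstrate that the algorithms and the qualitative
scheme contrasts behave as designed under the stated assumptions — not
that the model reproduces any particular field dataset. The "24 paired
replicates" are a structural stand-in for replicated field plots.

## Statistics

* **Flux-Ninorg**: trapezoidal time integral of the six enzymatic fluxes.
* **Enz-Ninorg**: by default cumulative gross production (matching "total
  production of enzymes"); the integrated standing pool is exposed as an
  alternative reading since either aggregate is defensible.
* **Percent bias**: `100·(mean(sim) − mean(obs))/mean(obs)`.
* **NSE**: `1 − SSE/SS_obs`, the standard goodness-of-fit companion.
* **ReUn**: `(p95 − p5)/mean` of an ensemble output; percentiles by linear
  interpolation of order statistics (the numpy default convention). The
  90 % interval is operationalized as the p5–p95 inter-percentile width.
* **Wilcoxon signed-rank**: zero differences dropped (classical
  convention; a Pratt variant is available), average ranks on ties; exact
  p by convolution over all 2^m sign assignments when m ≤ 25 with no
  ties/zeros, else normal approximation with tie and continuity
  corrections. Compact letter display by insert-and-absorb: two labels
  share a letter iff their pairwise p ≥ α (default α = 0.001).
* **Calibration objective**: per observable
  `0.5·min(|PBIAS|/100, 1) + 0.25·(1 − max(NSE, −1))`, summed with
  weights (default equal); zero iff every observable fits perfectly.
  Simulated series are linearly interpolated to observation times; NO3
  and NO2 are compared only as their sum. The optimizer is seeded
  differential evolution (population recombination within bounds, fixed
  evaluation budget, no polish step), so runs are reproducible.
* **Ensembles**: seeded Latin-hypercube factors (one stratum draw per
  parameter per member) applied multiplicatively to a base set; default
  ranges ±25 % on all `Vmax`, all `Ks`, `pEP` and `rE`. The supplementary
  ranges behind the published uncertainty analysis are not available;
  ±25 % is this package's declared convention.

## Numerics

* Default integrator: LSODA, `rtol 1e-8`, `atol 1e-10`, dense output;
  the output grid is decoupled from solver steps. The frozen testbed
  relaxes to `1e-6`/`1e-9`, which changes its aggregate metrics by far
  less than scenario noise while making 100-member ensembles cheap.
* A fixed-step RK4 path exists for convergence checks; it limits each
  pool's consuming fluxes within a step so no pool is driven negative
  (scaling fluxes, unlike clipping states, preserves the conservation
  audit).
* In the adaptive path, Michaelis–Menten forms vanish smoothly at zero
  substrate, so negativity can only be tolerance-level; flux evaluation
  treats sub-zero excursions as zero and the simulator rejects any state
  significantly below zero.
* Aggregate horizons: the shipped testbed is 12 years at daily forcing
  resolution with 5-day output sampling; unit tests use 1–3-year
  variants of the same frozen scenario.

## Known limitations

* No carbon cycle, no temperature/moisture rate modifiers, no microbial
  dormancy, no isotopes, no spatial structure.
* The scheme-invariance of total enzyme cost is a *feature of prescribed
  biomass*; interpreting Enz-Ninorg contrasts between schemes requires a
  host model with growth feedback.
* The lumped nitrification step means NO2 dynamics reflect only the
  denitrification chain.
* ReUn magnitudes depend strongly on the chosen perturbation ranges; only
  orderings between schemes are meaningful under the default ±25 % bands.
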