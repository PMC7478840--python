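# Model and methods

This note documents the simulator's equations, the synthetic-data
calibration, and the numerical conventions. Everything quantitative stated
here is either a definition or is checked by the test suite or the
acceptance script; no empirical claims beyond those computations are made.

## 1. State, time and space

Time steps are seasons: summer `s = 0`, winter `s = 1`, step
`t = 2·y + s` with `y` elapsed years (the first summer is `t = 0`). The
default arena has 15 SSMUs in three subareas (48.1: units 1–8, 48.2: 9–12,
48.3: 13–15); the first unit of each subarea is *pelagic* (large area, low
krill density), the rest are *coastal*. State per step: krill biomass
`K_i` (g) per SSMU, mean individual krill mass `w̄_i` (g), adult count per
predator population, and each population's queue of not-yet-mature cohorts.

## 2. The seasonal step

Operations in fixed order:

1. **Mass trend** — `w̄_i(y) = w̄_i(0) · max(0.01, 1 + τ_i y)`, the linear
   climate-driven decline with a floor.
2. **Recruitment** (summer only) — `R_i = ρ_i K_i ε_i`, `ε` lognormal with
   median 1, log-SD σ, drawn per SSMU; σ = 0 gives ε = 1 exactly but still
   consumes the draw so paired runs share streams.
3. **Movement** — `K′ = K M_s` with row-stochastic `M_s`.
4. **Threshold** — SSMUs whose pre-harvest density `K′_i / A_i` is below
   15 g·m⁻² suspend fishing this season (a *violation* where catch was
   allocated).
5. **Demand** — predator demand per SSMU via foraging distributions
   (`D = Σ_j adults_j · percap_{j,s} · F_{j,s}`); fishery demand
   `Θ_{s,i} · w̄_i` for open, non-violating SSMUs, where
   `Θ = B0 · γ · p′ / w̄(0 or last reassessment)` is the catch limit in
   individuals.
6. **Rationing** — all consumers receive the same fraction
   `λ_i = min(1, v K′_i / total demand_i)` of their demand: predators and
   the fishery compete symmetrically for the accessible fraction `v` of the
   stock (`krill_availability`).
7. **Krill survival** — `K ← S_{s,i} (K′_i − catch_i − predation_i)`.
8. **Predators** — foraging success `x_j = F_{j,s} · λ`; in summer the
   cohort `adults · e(x) · maxR` joins the maturation queue and the queue
   front joins the adult class after adult survival; `e(x) = x` (linear) or
   `x(1+c)/(x+c)` (hyperstable, c = 0.5).

### Why `krill_availability` exists

With linear recruitment and demand capped only by the whole stock, the
annual krill map has slope `S² (1+ρ) > 1` whenever consumption is
demand-limited, and a one-step collapse when demand exceeds the stock: there
is no stable interior state and no persistent competition regime. Making
only a fraction `v` of the local stock accessible per season bounds seasonal
consumption at `v K′` and creates a *chronic competition* regime in which
the annual krill map is `K → S² (1+ρ) (1−v)² K` — exactly neutral for the
calibrated rates below. Fishing then reallocates the fixed accessible
consumption from predators to the fishery without changing krill itself,
which is the mechanism the management comparison needs.

## 3. Management strategies

The overall annual limit `γ B0` (γ = 0.093, `B0` = initial arena biomass)
is never changed, only distributed. `p′` fractions per SSMU × season sum
to 1; within an SSMU the baseline summer/winter split is retained.

* **none** — the baseline Dirichlet-drawn distribution, fixed.
* **fbm_krill** — every 5 years, per-SSMU fractions ∝ current summer krill
  density `K_i/A_i`.
* **fbm_pengs** — fractions from penguin-abundance changes
  `ΔP_i = P_{i,t} − P_{i,t−10}` over penguin-resident SSMUs, remapped to
  `p_i = ΔP_i + α |min ΔP|` (α = 1 default) and normalized; when
  `min ΔP < 0` the arg-min SSMU(s) get weight 0 and are closed until the
  next reassessment; α < 1 with a negative minimum is rejected.
* **mpa** — masked SSMUs closed for the whole run; their share is
  redistributed over open cells ∝ the baseline distribution (fixed at t=0).

Catch limits in individuals are recomputed from the current (trended) mean
mass at t = 0 and at each FBM reassessment; between reassessments `Θ` is
fixed, so in the base and MPA cases the *biomass* value of the limit erodes
with the mass trend while FBM arms periodically restore it.

## 4. Synthetic generator and its equilibrium

The generator emulates the regional structure: occupancy (penguins in 12 of
15 SSMUs, seals in 5, whales in the two northern pelagic units, fish
everywhere), coastal densities U(28.5, 45) g·m⁻² strictly above pelagic
U(12, 20.25) (the latter near the 15 g·m⁻² threshold so fishing
suspensions occur), areas ~2.5·10¹¹ m² pelagic vs 2–6·10¹⁰ m² coastal,
mass-trend τ ~ U(−0.003, −0.001)/yr (a material 10–30% century decline),
and a coastal-concentrated Dirichlet catch distribution with a
summer-heavy split.

The generated system is an exact deterministic fixed point by construction:

* **Krill neutrality.** `S = 0.9` per season, `v = 0.2`, and
  `ρ = 1/(S²(1−v)²) − 1 ≈ 0.929` make the annual map slope exactly 1 in
  the chronic-competition regime. Drift-mode movement matrices are balanced
  exchanges between adjacent SSMUs (rate 0.1 of the smaller neighbour)
  whose stationary distribution is the initial biomass vector, so movement
  preserves the standing spatial structure exactly.
* **Uniform rationing.** Per-SSMU aggregate demand is set to `β v K̃` each
  season (β = 3), so every rationing factor is exactly `1/β = 1/3`. The
  mobile groups are placed first (share-based, capped at 75% of any SSMU's
  target); the locally foraging fish populations absorb the exact residual,
  which is what makes the per-SSMU targets attainable in both seasons.
* **Predator replacement.** A cohort matures after its summer's adult
  survival and then overwinters, so the stationary cohort is
  `a (1−s²)/s` and replacement fecundity is `maxR = β (1−s²)/s` per
  group (seasonal survivals: penguins 0.92, seals 0.94, whales 0.98, fish
  0.93; maturation lags 3/4/8/2 years). At `x = 1/3` and linear response,
  production is exactly replacement. Winter per-capita demand divides by
  the winter-phase adult count `a/s`.

`equilibrate()` burns the residual in (deterministic, unfished) and then
*verifies* stationarity: an unfished 100-year run must leave every krill
stock and population within 5% of its start, else it raises. On the default
generator the residual drift is at machine precision (~1e-15).

Reference-set members toggle movement {identity, exchange} and breeder
response {linear, hyperstable} around the shared stocks. The hyperstable
members are not at their own fixed point (`e(1/3) = 0.6 > 1/3`), so their
predators share a common upward transient toward `x = 1/7`; it is identical
in scenario and base arms and cancels in ratios.

## 5. Ensembles, pairing and evaluation

A trial is one stochastic 100-year projection; ensembles run `n` trials for
each of the four reference-set members. Trial streams derive from
`SeedSequence(entropy=base_seed, spawn_key=(member, trial))` (unpaired runs
prepend an arm index); scenario and base arms share streams, so a strategy
that changes nothing reproduces the base bitwise and every ratio is exactly
1.0. Ensemble summaries are fixed-order sums divided by trial counts, so
results do not depend on execution interleaving; non-finite trajectories
abort loudly.

Outcomes are counterfactual ratios scenario/base of ensemble means. Arena
ratios are ratios of summed totals, never means of per-SSMU ratios. Time
slices are the summer steps of years 30 and 100; annual catch sums the
year's two seasons; violation probability is the share of *fished*
trial-seasons (allocated catch > 0) below the threshold, with two arena
aggregations (any-fished-SSMU probability; catch-weighted mean of per-SSMU
probabilities). Signed deltas (ratio − 1) are classed: |δ| < 0.01 none,
≤ 0.10 small, ≤ 0.50 medium, > 0.50 large. Conventions for degenerate
ratios: 0/0 → 1.0 with a warning; positive/0 → NaN with a warning;
never-fished SSMUs report violation probability 0 with a warning.

## 6. Numerical choices and problem sizes

Float64 throughout; no hidden global RNG (every stochastic call takes a
generator). Validation is total (all violations reported at once); the
on-disk format is schema-tagged YAML + delimited movement matrices and
round-trips byte-identically. Default study sizes in this package: 100
trials × 4 parameterizations per arm in `scripts/acceptance.py` (~1 minute;
Monte-Carlo noise on arena ratios is well below the 0.01 "none" boundary at
that size), 20–50 trials in tests. Larger ensembles (e.g. 1001 trials) are
a command-line knob, not a code change.

## 7. Limitations

* The ensemble *mean* krill grows slowly over a century in all arms: the
  specified median-1 lognormal recruitment deviates have mean
  `exp(σ²/2) > 1` and the krill map is deliberately neutral, so the mean of
  the multiplicative walk drifts up (the median is flat). All reported
  outcomes are paired ratios, so this common-mode drift cancels; absolute
  trajectories should be read as medians-of-effect, not stock forecasts.
* Krill has no intrinsic density dependence; regulation comes entirely from
  the neutral calibration and the accessibility cap.
* Feedback rules read the true simulated state (no observation error), so
  FBM performance here is an upper bound on monitoring-limited practice.
* Predator groups are aggregates with constant adult survival; all
  krill-dependence is through breeding output, so responses to food stress
  are slower and smoother than species-level dynamics might be.
* The synthetic arena is structurally, not empirically, calibrated: it
  reproduces occupancy, geometry, density ordering and fishery
  concentration patterns, and its absolute scales (≈30 Mt arena biomass,
  ≈0.5–3 Mt annual limits) are order-of-magnitude plausible only.
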