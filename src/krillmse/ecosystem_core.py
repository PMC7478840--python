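"""Seasonal delay-difference dynamics of krill, predators and the fishery.

One time step is one season.  Within a step the operations are applied in a
fixed order:

1. climate trend on mean individual krill mass (linear in elapsed years,
   floored at a small positive fraction of the initial mass);
2. krill recruitment (summer only) with a median-1 lognormal deviate per SSMU;
3. krill movement along the season's row-stochastic matrix;
4. density-threshold check: SSMUs whose krill density is below the threshold
   at the (pre-harvest) start of the season suspend fishing for that season;
5. demand assembly: predator demand per SSMU through the foraging
   distributions, fishery demand as catch limit (individuals) times current
   mean mass for open, non-violating SSMUs;
6. proportional rationing of the accessible krill biomass among all consumers;
7. krill natural mortality on the post-consumption biomass;
8. predator demography: foraging success -> effective breeder fraction ->
   summer cohort production, delayed maturation, adult survival.

Krill is tracked as biomass per SSMU.  Predators are resident populations
(one SSMU each) whose foraging spreads over several SSMUs; their foraging
success is the demand-weighted mean of the rationing factors they encounter,
and it drives breeding output only -- adult survival is constant.

With recruitment noise switched off (``sigma = 0``) every operation is
deterministic and runs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters_io import (
    SUMMER,
    WINTER,
    ModelParameterization,
    PredatorPopulation,
    ScenarioSpec,
)
from .management_strategies import FisheryControls

# Mean mass never drops below this fraction of its initial value, whatever the
# trend; keeps the numbers<->biomass conversion defined over any horizon.
MASS_TREND_FLOOR = 0.01

_ROW_SUM_TOL = 1e-9


@dataclass
class EcosystemState:
    """Per-time-step state: krill biomass and mass per SSMU, predator adults
    per population, and each population's queue of not-yet-mature cohorts.

    ``pending_recruits[j]`` has one entry per year of ``recruit_lag`` for
    population ``j``; the front entry matures at the next summer step.
    """

    t: int
    krill_biomass: np.ndarray  # g per SSMU
    mean_mass: np.ndarray  # g per individual per SSMU
    predator_adults: np.ndarray  # count per population
    pending_recruits: list[list[float]]

    def copy(self) -> "EcosystemState":
        return EcosystemState(
            t=self.t,
            krill_biomass=self.krill_biomass.copy(),
            mean_mass=self.mean_mass.copy(),
            predator_adults=self.predator_adults.copy(),
            pending_recruits=[list(q) for q in self.pending_recruits],
        )

    @property
    def season(self) -> int:
        return self.t % 2

    @property
    def year(self) -> int:
        """Whole elapsed years."""
        return self.t // 2


@dataclass
class SeasonOutcome:
    """What happened during one season."""

    realized_catch: np.ndarray  # g per SSMU
    realized_predation: np.ndarray  # g per SSMU
    foraging_success: np.ndarray  # x_j in [0, 1] per population
    violations: np.ndarray  # bool per SSMU: density below threshold at season start
    allocated_catch: np.ndarray  # g per SSMU: catch-limit biomass before suspension
    rationing: np.ndarray  # lambda in [0, 1] per SSMU


def initial_state(p: ModelParameterization) -> EcosystemState:
    """State at t = 0, with pending cohorts filled at their stationary value.

    A cohort maturing in a summer joins after that season's adult survival
    and then overwinters, so the annual map is
    ``a -> s_summer * s_winter * a + s_winter * m``; the stationary cohort is
    ``m = adults * (1 - annual survival) / winter survival``, and each queue
    entry is set to it so a population at its demographic equilibrium starts
    without a maturation transient.
    """
    adults = np.array([pp.initial_adults for pp in p.predator_populations], dtype=float)
    queues = [
        [pp.initial_adults * (1.0 - pp.annual_survival()) / pp.adult_survival[WINTER]
         if pp.adult_survival[WINTER] > 0 else 0.0] * int(pp.recruit_lag)
        for pp in p.predator_populations
    ]
    return EcosystemState(
        t=0,
        krill_biomass=p.initial_krill_biomass.astype(float).copy(),
        mean_mass=p.initial_mean_mass.astype(float).copy(),
        predator_adults=adults,
        pending_recruits=queues,
    )


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def apply_mass_trend(mass0: np.ndarray, trend: np.ndarray, year: int) -> np.ndarray:
    """Mean individual krill mass after ``year`` elapsed years of linear trend.

    ``w(year) = mass0 * max(floor, 1 + trend * year)`` elementwise; the floor
    prevents non-positive mass under a strong negative trend.
    """
    mass0 = np.asarray(mass0, dtype=float)
    if np.any(mass0 <= 0):
        raise ValueError("mass0 must be strictly positive")
    factor = np.maximum(MASS_TREND_FLOOR, 1.0 + np.asarray(trend, dtype=float) * year)
    return mass0 * factor


def krill_density(K: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Krill density in g m^-2: biomass over SSMU surface area."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("SSMU areas must be strictly positive")
    return np.asarray(K, dtype=float) / A


def recruit_krill(state: EcosystemState, p: ModelParameterization,
                  rng: np.random.Generator) -> np.ndarray:
    """Summer recruitment biomass per SSMU.

    ``R_i = rate_i * K_i * eps_i`` with ``eps`` lognormal, median 1
    (log-SD ``krill_recruit_sigma``), drawn independently per SSMU.  A draw
    is consumed even when sigma is 0, so paired runs stay on a common random
    number stream; with sigma = 0 the deviate is exactly 1.
    """
    n = p.n_ssmu
    z = rng.standard_normal(n)
    eps = np.exp(p.krill_recruit_sigma * z)
    return p.krill_recruit_rate[SUMMER] * state.krill_biomass * eps


def move_krill(K: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Redistribute biomass along the rows of a row-stochastic matrix.

    ``K'_j = sum_i K_i M_ij``; total biomass is conserved.
    """
    M = np.asarray(M, dtype=float)
    rows = M.sum(axis=1)
    if np.any(M < 0) or np.any(np.abs(rows - 1.0) > _ROW_SUM_TOL):
        raise ValueError("movement matrix must be row-stochastic")
    return np.asarray(K, dtype=float) @ M


@dataclass
class CompetitionResult:
    rationing: np.ndarray  # lambda per SSMU
    realized_predation: np.ndarray  # g per SSMU
    realized_catch: np.ndarray  # g per SSMU


def resolve_competition(available: np.ndarray, predator_demand: np.ndarray,
                        fishery_demand: np.ndarray) -> CompetitionResult:
    """Proportional rationing of accessible krill among predators and fishery.

    ``lambda_i = min(1, available_i / (predator_demand_i + fishery_demand_i))``
    (1 where total demand is zero); every consumer realizes ``lambda`` times
    its demand, so predators and the fishery are treated symmetrically and
    total consumption never exceeds availability.
    """
    available = np.asarray(available, dtype=float)
    pd_ = np.asarray(predator_demand, dtype=float)
    fd = np.asarray(fishery_demand, dtype=float)
    total = pd_ + fd
    lam = np.ones_like(total)
    busy = total > 0
    lam[busy] = np.minimum(1.0, available[busy] / total[busy])
    return CompetitionResult(rationing=lam, realized_predation=lam * pd_,
                             realized_catch=lam * fd)


def foraging_success(population: PredatorPopulation, rationing: np.ndarray,
                     season: int) -> float:
    """Foraging success of one population: its foraging-distribution-weighted
    mean of the per-SSMU rationing factors."""
    return float(population.foraging_dist[season] @ np.asarray(rationing, dtype=float))


def effective_breeder_fraction(x, mode: str, c: float = 1.0):
    """Fraction of adults that breed effectively at foraging success ``x``.

    linear: ``e = x``; hyperstable: ``e = x (1 + c) / (x + c)`` with
    half-saturation ``c > 0``.  Both satisfy e(0) = 0, e(1) = 1 and are
    monotone; the hyperstable curve lies above the linear one on (0, 1),
    i.e. breeding output is buffered against declining foraging success.
    """
    x = np.asarray(x, dtype=float)
    if mode == "linear":
        out = x
    elif mode == "hyperstable":
        if not c > 0:
            raise ValueError("hyperstable half-saturation must be > 0")
        out = x * (1.0 + c) / (x + c)
    else:
        raise ValueError(f"unknown breeder response {mode!r}")
    return float(out) if out.ndim == 0 else out


def update_predators(state: EcosystemState, x: np.ndarray,
                     p: ModelParameterization) -> None:
    """Advance predator demography by one season, in place.

    Every season adults survive at the season's constant rate.  In summer a
    new cohort ``adults * e(x) * max_recruits_per_breeder`` enters the pending
    queue and the cohort at the queue front (produced ``recruit_lag`` years
    ago) matures into the adult class.
    """
    season = state.season
    for j, pp in enumerate(p.predator_populations):
        adults = state.predator_adults[j]
        matured = 0.0
        if season == SUMMER:
            e = effective_breeder_fraction(x[j], p.breeder_response, p.hyperstable_halfsat)
            cohort = adults * e * pp.max_recruits_per_breeder
            q = state.pending_recruits[j]
            if pp.recruit_lag == 0:
                matured = cohort
            else:
                matured = q.pop(0)
                q.append(cohort)
        state.predator_adults[j] = pp.adult_survival[season] * adults + matured


# ---------------------------------------------------------------------------
# Demand assembly and the full seasonal step
# ---------------------------------------------------------------------------


def predator_demand_matrix(p: ModelParameterization, season: int) -> np.ndarray:
    """Foraging matrix F (n_pop x n_ssmu) for one season."""
    return np.stack([pp.foraging_dist[season] for pp in p.predator_populations])


def assemble_predator_demand(state: EcosystemState, p: ModelParameterization,
                             season: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-population total demand (g/season) and its per-SSMU spread."""
    percap = np.array([pp.per_capita_demand[season] for pp in p.predator_populations])
    totals = state.predator_adults * percap
    F = predator_demand_matrix(p, season)
    return totals, totals @ F


def step_season(state: EcosystemState, p: ModelParameterization,
                controls: FisheryControls, spec: ScenarioSpec,
                rng: np.random.Generator) -> tuple[EcosystemState, SeasonOutcome]:
    """Advance the ecosystem by one season.

    Returns the new state (a copy; the input is untouched) and the season's
    outcome.  Deterministic given state, controls, and RNG stream position.
    """
    state = state.copy()
    season = state.season

    # 1. climate trend on mean mass
    if spec.climate_trend:
        state.mean_mass = apply_mass_trend(p.initial_mean_mass, p.mass_trend, state.year)
    else:
        state.mean_mass = p.initial_mean_mass.astype(float).copy()

    # 2. summer recruitment (the RNG is consumed only in summer)
    K = state.krill_biomass
    if season == SUMMER:
        K = K + recruit_krill(state, p, rng)

    # 3. movement
    K = move_krill(K, p.movement_matrices[season])

    # 4. threshold check on pre-harvest density
    density = krill_density(K, p.ssmu_map.areas)
    violations = density < spec.density_threshold

    # 5. demand assembly
    _, pred_demand = assemble_predator_demand(state, p, season)
    allocated = controls.catch_limits[season] * state.mean_mass  # g, limit as biomass
    fish_demand = np.where(violations | controls.closed, 0.0, allocated)

    # 6. rationing of the accessible biomass
    available = p.krill_availability * K
    comp = resolve_competition(available, pred_demand, fish_demand)

    # 7. krill natural mortality on the post-consumption stock
    state.krill_biomass = p.krill_survival[season] * (
        K - comp.realized_catch - comp.realized_predation)

    # 8. predator demography
    F = predator_demand_matrix(p, season)
    x = F @ comp.rationing
    update_predators(state, x, p)

    state.t += 1
    return state, SeasonOutcome(
        realized_catch=comp.realized_catch,
        realized_predation=comp.realized_predation,
        foraging_success=x,
        violations=violations,
        allocated_catch=allocated,
        rationing=comp.rationing,
    )
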