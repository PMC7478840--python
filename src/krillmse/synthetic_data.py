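"""Synthetic parameterizations emulating the Antarctic Peninsula / Scotia Sea
krill arena.

The generator builds complete, validator-passing ecosystem instances with the
structure the analysis assumes: 15 SSMUs across three statistical subareas
(48.1: 1-8, 48.2: 9-12, 48.3: 13-15), a pelagic (offshore, large, low krill
density) first SSMU per subarea and coastal SSMUs elsewhere, predator groups
resident per the Antarctic occupancy pattern (penguins in 12 SSMUs, seals in
5, whales in the two northern pelagic units, fish everywhere), mostly-local
foraging, a fishery concentrated on coastal SSMUs, and a climate-driven
decline in mean individual krill mass.

The generated system is placed at an approximate joint equilibrium by
construction:

* the krill production/mortality/accessibility rates are chosen so that, in
  the chronic-competition regime (aggregate demand exceeding the accessible
  fraction of the stock), the deterministic annual krill map is exactly
  neutral -- consumption removes precisely the seasonal surplus;
* predator fecundity is a fixed multiple ``BETA`` of adult replacement, so a
  population is stationary exactly when its foraging success sits where the
  effective-breeder curve equals ``1/BETA``;
* per-population demands are fitted (iterative proportional fitting through
  the foraging matrices) so each SSMU's aggregate demand is ``BETA`` times
  the accessible krill, putting every rationing factor at ``1/BETA``;
* drift-mode movement matrices are balanced exchanges between adjacent SSMUs
  constructed so the initial krill distribution is their stationary
  distribution, which keeps the coastal-over-pelagic density structure.

:func:`equilibrate` then burns in the residual predator transient with the
deterministic, unfished model and verifies the stationarity it claims.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .ecosystem_core import initial_state, step_season
from .management_strategies import initial_controls
from .parameters_io import (
    ModelParameterization,
    PredatorPopulation,
    SSMUMap,
    ScenarioSpec,
    validate_or_raise,
)

SUBAREA_CODES = ("48.1", "48.2", "48.3")

# 1-based Antarctic residency pattern (penguins absent from the pelagic SSMUs
# 1, 9 and 13; seals on the coastal shelves; whales in the two northern
# pelagic units; fish throughout).
TABLE1_OCCUPANCY = {
    "penguins": (2, 3, 4, 5, 6, 7, 8, 10, 11, 12, 14, 15),
    "seals": (3, 4, 7, 14, 15),
    "whales": (1, 9),
    "fish": tuple(range(1, 16)),
}

# Demographics per predator group: seasonal adult survival, years to
# maturity, plausible resident-population sizes, and the group's share of an
# SSMU's krill demand when splitting among resident groups.
GROUP_PARAMS = {
    "penguins": dict(survival=0.92, lag=3, adults=(2e5, 8e5), demand_share=0.40),
    "seals": dict(survival=0.94, lag=4, adults=(3e4, 1e5), demand_share=0.15),
    "whales": dict(survival=0.98, lag=8, adults=(3e3, 8e3), demand_share=0.10),
    "fish": dict(survival=0.93, lag=2, adults=(2e7, 8e7), demand_share=0.35),
}

# Fecundity as a multiple of adult replacement: stationarity at effective
# breeder fraction 1/BETA, i.e. foraging success 1/BETA under the linear
# response.  BETA > 1 gives populations headroom to grow when krill is
# plentiful and to decline under fishing-induced competition.
BETA = 3.0

KRILL_SEASON_SURVIVAL = 0.9
KRILL_AVAILABILITY = 0.2  # accessible fraction of the local stock per season
KRILL_RECRUIT_SIGMA = 0.15
MEAN_KRILL_MASS_G = 0.46
EXCHANGE_RATE = 0.1  # drift-mode biomass exchange between adjacent SSMUs


def neutral_recruit_rate(survival: float = KRILL_SEASON_SURVIVAL,
                         availability: float = KRILL_AVAILABILITY) -> float:
    """Summer production fraction that makes the chronic-competition annual
    krill map exactly neutral: ``S^2 (1+r) (1-v)^2 = 1``."""
    return 1.0 / (survival ** 2 * (1.0 - availability) ** 2) - 1.0


@dataclass
class GeneratorOptions:
    """Knobs of the synthetic arena.

    ``krill_density_range`` (g m^-2) spans the pelagic (lower part, straddling
    the 15 g m^-2 fishing threshold) and coastal (upper part) initial
    densities; ``trend_range`` (per year) is the climate-driven fractional
    decline in mean individual mass; ``fishery_concentration`` is the
    Dirichlet concentration placed on coastal SSMUs when drawing the baseline
    catch distribution; ``predator_occupancy`` is ``"table1"`` (the Antarctic
    pattern, 15 SSMUs) or ``"random"`` (any arena size).
    """

    n_ssmus: int = 15
    seed: int = 0
    coastal_fraction: float = 0.8
    fishery_concentration: float = 6.0
    krill_density_range: tuple[float, float] = (12.0, 45.0)
    trend_range: tuple[float, float] = (-0.003, -0.001)
    predator_occupancy: str = "table1"

    def __post_init__(self) -> None:
        if self.n_ssmus < 2:
            raise ValueError("need at least 2 SSMUs")
        if not self.krill_density_range[0] < self.krill_density_range[1]:
            raise ValueError("krill_density_range must be ordered")
        if not self.trend_range[0] <= self.trend_range[1]:
            raise ValueError("trend_range must be ordered")
        if self.predator_occupancy not in ("table1", "random"):
            raise ValueError("predator_occupancy must be 'table1' or 'random'")
        if self.predator_occupancy == "table1" and self.n_ssmus != 15:
            raise ValueError("the Antarctic occupancy pattern requires 15 SSMUs")


# ---------------------------------------------------------------------------
# Arena layout
# ---------------------------------------------------------------------------


def _subarea_assignment(n: int) -> list[str]:
    if n == 15:
        return ["48.1"] * 8 + ["48.2"] * 4 + ["48.3"] * 3
    sizes = [n // 3 + (1 if k < n % 3 else 0) for k in range(3)]
    out: list[str] = []
    for code, size in zip(SUBAREA_CODES, sizes):
        out += [code] * size
    return out or ["48.1"] * n


def pelagic_mask(n: int, subarea: list[str], coastal_fraction: float = 0.8) -> np.ndarray:
    """Offshore SSMUs: the first unit of each subarea (plus more, round-robin,
    if ``coastal_fraction`` asks for fewer coastal units)."""
    n_pelagic = max(0, n - int(round(coastal_fraction * n)))
    firsts = [i for i in range(n) if i == 0 or subarea[i] != subarea[i - 1]]
    n_pelagic = max(n_pelagic, 0)
    chosen = list(firsts[: max(n_pelagic, len(firsts))]) if n_pelagic else list(firsts)
    # always treat subarea-leading units as pelagic; extend if more requested
    extra = [i for i in range(n) if i not in chosen]
    while len(chosen) < n_pelagic and extra:
        chosen.append(extra.pop())
    mask = np.zeros(n, dtype=bool)
    mask[chosen] = True
    if mask.all():  # keep at least one coastal unit
        mask[-1] = False
    return mask


def _occupancy(opts: GeneratorOptions, subarea: list[str],
               pelagic: np.ndarray) -> dict[str, list[int]]:
    n = opts.n_ssmus
    if opts.predator_occupancy == "table1":
        return {g: [i - 1 for i in idx] for g, idx in TABLE1_OCCUPANCY.items()}
    coastal = [i for i in range(n) if not pelagic[i]]
    pel = [i for i in range(n) if pelagic[i]]
    return {
        "penguins": coastal,
        "seals": coastal[::2],
        "whales": pel if pel else [0],
        "fish": list(range(n)),
    }


def _foraging_dist(n: int, res: int, subarea: list[str], resident_w: float,
                   reach: int, decay: float) -> np.ndarray:
    w = np.zeros(n)
    for i in range(n):
        d = abs(i - res)
        if 0 < d <= reach and subarea[i] == subarea[res]:
            w[i] = np.exp(-d / decay)
    out = np.zeros(n)
    if w.sum() > 0:
        out = (1.0 - resident_w) * w / w.sum()
        out[res] += resident_w
    else:
        out[res] = 1.0
    return out / out.sum()


def _exchange_matrix(stock: np.ndarray, rate: float) -> np.ndarray:
    """Row-stochastic exchange between adjacent SSMUs whose stationary
    distribution is ``stock`` (balanced symmetric flows)."""
    n = len(stock)
    M = np.zeros((n, n))
    for i in range(n - 1):
        flow = rate * min(stock[i], stock[i + 1])
        M[i, i + 1] = flow / stock[i]
        M[i + 1, i] = flow / stock[i + 1]
    for i in range(n):
        M[i, i] = 1.0 - M[i].sum()
    return M


# ---------------------------------------------------------------------------
# Demand fitting
# ---------------------------------------------------------------------------

# Cap on the demand share the mobile groups (penguins, seals, whales) may
# place in any single SSMU; the locally foraging fish populations absorb the
# remainder, so per-SSMU aggregate demand hits its target exactly.
_MOBILE_DEMAND_CAP = 0.75


def _fit_demands(targets: np.ndarray, F_mobile: np.ndarray,
                 mobile_init: np.ndarray,
                 fish_res: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-population demand totals hitting ``targets`` per SSMU exactly.

    Mobile populations start from a share-based split of their resident
    SSMU's target, are scaled down uniformly if their spread foraging would
    exceed ``_MOBILE_DEMAND_CAP`` of any SSMU's target, and the resident-only
    fish populations take up the exact residual.  Returns
    ``(t_mobile, t_fish)``; ``fish_res`` maps fish populations to their
    resident SSMU index (one fish population per SSMU required).
    """
    t_mobile = mobile_init.copy()
    if len(t_mobile):
        achieved = t_mobile @ F_mobile
        with np.errstate(divide="ignore"):
            scale = np.min(np.where(achieved > 0,
                                    _MOBILE_DEMAND_CAP * targets / np.maximum(achieved, 1e-300),
                                    np.inf))
        if scale < 1.0:
            t_mobile = t_mobile * scale
        achieved = t_mobile @ F_mobile
    else:
        achieved = np.zeros_like(targets)
    residual = targets - achieved
    if np.any(residual <= 0):
        raise RuntimeError("mobile demand exceeds an SSMU target after capping")
    t_fish = np.zeros(len(fish_res))
    for j, i in enumerate(fish_res):
        t_fish[j] = residual[i]
    return t_mobile, t_fish


def generate_parameterization(opts: GeneratorOptions | None = None) -> ModelParameterization:
    """Draw one complete parameterization near its joint equilibrium.

    Deterministic for a fixed ``opts.seed``; always passes the full
    validator.
    """
    opts = opts or GeneratorOptions()
    rng = np.random.default_rng(opts.seed)
    n = opts.n_ssmus
    subarea = _subarea_assignment(n)
    pelagic = pelagic_mask(n, subarea, opts.coastal_fraction)
    ssmu_ids = [f"SSMU{i + 1:02d}" for i in range(n)]

    # Areas: offshore units an order of magnitude larger than shelf units.
    areas = np.where(pelagic,
                     2.5e11 * rng.uniform(0.8, 1.2, n),
                     rng.uniform(2e10, 6e10, n))

    # Initial densities: pelagic in the low part of the range (straddling the
    # fishing threshold), coastal strictly above.
    lo, hi = opts.krill_density_range
    pel_hi = min(lo + 0.25 * (hi - lo), hi)
    coast_lo = lo + 0.5 * (hi - lo)
    density = np.where(pelagic,
                       rng.uniform(lo, pel_hi, n),
                       rng.uniform(coast_lo, hi, n))
    K0 = density * areas

    S = KRILL_SEASON_SURVIVAL
    v = KRILL_AVAILABILITY
    r = neutral_recruit_rate(S, v)
    recruit_rate = np.vstack([np.full(n, r), np.zeros(n)])
    survival = np.full((2, n), S)
    mass_trend = rng.uniform(opts.trend_range[0], opts.trend_range[1], n)

    movement = np.stack([_exchange_matrix(K0, EXCHANGE_RATE)] * 2)

    # Baseline catch distribution: Dirichlet concentrated on coastal SSMUs,
    # split into a summer-heavy seasonal pattern per SSMU.
    conc = np.where(pelagic, 0.5, opts.fishery_concentration)
    annual = rng.dirichlet(conc)
    summer_share = rng.uniform(0.5, 0.7, n)
    base_catch = np.vstack([annual * summer_share, annual * (1.0 - summer_share)])
    base_catch /= base_catch.sum()

    # Predator populations at the designed equilibrium: aggregate demand per
    # SSMU equal to BETA times the accessible krill each season.  The mobile
    # groups (penguins, seals, whales) forage over neighbouring SSMUs; the
    # fish populations feed locally and absorb each SSMU's residual demand,
    # which makes the per-SSMU targets attainable exactly in both seasons.
    occupancy = _occupancy(opts, subarea, pelagic)
    if sorted(occupancy["fish"]) != list(range(n)):
        raise RuntimeError("generator requires one fish population per SSMU")
    # seasonal accessible stock at the rationing point (movement leaves the
    # equilibrium distribution unchanged by construction)
    Ks_tilde = (1.0 + r) * K0
    K1 = S * (1.0 - v) * Ks_tilde
    targets = np.vstack([BETA * v * Ks_tilde, BETA * v * K1])

    mobile_meta = []  # (group, resident index)
    F_mobile = [[], []]
    mobile_share = []
    for g in ("penguins", "seals", "whales"):
        gp = GROUP_PARAMS[g]
        for i in occupancy[g]:
            mobile_meta.append((g, i))
            F_mobile[0].append(_foraging_dist(n, i, subarea, 0.7, 2, 1.0))
            F_mobile[1].append(_foraging_dist(n, i, subarea, 0.5, 3, 2.0))
            mobile_share.append(gp["demand_share"])
    fish_res = np.array(sorted(occupancy["fish"]), dtype=int)
    mobile_share = np.asarray(mobile_share)
    res_idx = np.array([i for _, i in mobile_meta], dtype=int)

    t_mobile, t_fish = [], []
    for s in (0, 1):
        Fm = np.stack(F_mobile[s]) if mobile_meta else np.zeros((0, n))
        init = mobile_share * targets[s][res_idx] if mobile_meta else np.zeros(0)
        tm, tf = _fit_demands(targets[s], Fm, init, fish_res)
        t_mobile.append(tm)
        t_fish.append(tf)

    pops: list[PredatorPopulation] = []

    def make_pop(g, i, demand_s, demand_w, F2):
        gp = GROUP_PARAMS[g]
        adults = rng.uniform(*gp["adults"])
        sv = gp["survival"]
        # At the stationary annual cycle the winter adult count is adults/sv
        # (summer survivors plus the matured replacement cohort), so the
        # winter per-capita rate converts the winter demand total at that
        # phase, keeping both seasonal demand targets exact.
        adults_winter = adults / sv
        return PredatorPopulation(
            group=g, resident_ssmu=ssmu_ids[i], initial_adults=adults,
            per_capita_demand=(demand_s / adults, demand_w / adults_winter),
            foraging_dist=F2, adult_survival=(sv, sv),
            # a cohort matures after its summer's adult survival and then
            # overwinters, so replacement fecundity carries a 1/sv factor
            max_recruits_per_breeder=BETA * (1.0 - sv ** 2) / sv,
            recruit_lag=gp["lag"])

    for j, (g, i) in enumerate(mobile_meta):
        pops.append(make_pop(g, i, t_mobile[0][j], t_mobile[1][j],
                             np.vstack([F_mobile[0][j], F_mobile[1][j]])))
    for j, i in enumerate(fish_res):
        local = np.zeros(n)
        local[i] = 1.0
        pops.append(make_pop("fish", i, t_fish[0][j], t_fish[1][j],
                             np.vstack([local, local])))

    p = ModelParameterization(
        ssmu_map=SSMUMap(ssmu_ids=ssmu_ids, areas=areas, subarea=subarea,
                         mpa_mask=np.zeros(n, dtype=bool)),
        initial_krill_biomass=K0,
        initial_mean_mass=np.full(n, MEAN_KRILL_MASS_G),
        mass_trend=mass_trend,
        krill_recruit_rate=recruit_rate,
        krill_recruit_sigma=KRILL_RECRUIT_SIGMA,
        krill_survival=survival,
        movement_matrices=movement,
        movement_mode="drift",
        predator_populations=pops,
        breeder_response="linear",
        hyperstable_halfsat=0.5,
        base_catch_fractions=base_catch,
        krill_availability=v,
        parameterization_id=f"synthetic-seed{opts.seed}",
    )
    validate_or_raise(p)
    return p


# ---------------------------------------------------------------------------
# Reference set, MPA mask, equilibration
# ---------------------------------------------------------------------------


def generate_reference_set(base: ModelParameterization) -> list[ModelParameterization]:
    """The 2x2 reference set bracketing movement (none vs. passive drift) and
    breeder response (linear vs. hyperstable); all members share the base
    parameterization's stocks and rates."""
    members = []
    n = base.n_ssmu
    identity = np.stack([np.eye(n)] * 2)
    drift = base.movement_matrices if base.movement_mode == "drift" \
        else np.stack([_exchange_matrix(base.initial_krill_biomass, EXCHANGE_RATE)] * 2)
    for move in ("none", "drift"):
        for response in ("linear", "hyperstable"):
            m = base.copy()
            m.movement_mode = move
            m.movement_matrices = (identity if move == "none" else drift).copy()
            m.breeder_response = response
            m.parameterization_id = f"{base.parameterization_id}/{move}-{response}"
            validate_or_raise(m)
            members.append(m)
    return members


def generate_mpa_mask(p: ModelParameterization, coverage: float) -> np.ndarray:
    """No-take mask confined to subareas 48.1 and 48.2, preferring coastal
    SSMUs, closing ``coverage`` of the coastal candidates there."""
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    n = p.n_ssmu
    sub = p.ssmu_map.subarea
    pel = pelagic_mask(n, sub)
    candidates = [i for i in range(n) if sub[i] in ("48.1", "48.2") and not pel[i]]
    n_close = int(round(coverage * len(candidates)))
    mask = np.zeros(n, dtype=bool)
    mask[candidates[:n_close]] = True
    if mask.all():
        raise ValueError("MPA coverage would close every SSMU")
    return mask


def _final_state(p: ModelParameterization, years: int):
    """End state of a deterministic, unfished, trend-free run."""
    spec = ScenarioSpec(strategy="none", horizon_years=max(years, 1), gamma=0.0,
                        climate_trend=False, n_trials=1, seed=0)
    q = p.copy()
    q.krill_recruit_sigma = 0.0
    controls = initial_controls(q, spec)
    state = initial_state(q)
    rng = np.random.default_rng(0)
    for _ in range(2 * years):
        state, _ = step_season(state, q, controls, spec, rng)
    return state


def equilibrate(p: ModelParameterization, burn_in_years: int = 300,
                check_years: int = 100, tol: float = 0.05) -> ModelParameterization:
    """Burn in the deterministic, unfished model and reset initial stocks to
    the end state, so base-case drift cannot masquerade as a strategy effect.

    After the reset, an unfished deterministic run of ``check_years`` must
    leave every krill stock and predator population within ``tol`` relative
    of its start; otherwise the parameterization has no usable stationary
    state and an error asks for parameter adjustment.
    """
    end = _final_state(p, burn_in_years)
    q = p.copy()
    q.initial_krill_biomass = end.krill_biomass.copy()
    for j, pp in enumerate(q.predator_populations):
        pp.initial_adults = float(end.predator_adults[j])
    validate_or_raise(q)

    check = _final_state(q, check_years)
    start_stocks = np.concatenate([q.initial_krill_biomass,
                                   [pp.initial_adults for pp in q.predator_populations]])
    end_stocks = np.concatenate([check.krill_biomass, check.predator_adults])
    scale = np.maximum(np.abs(start_stocks), 1e-12)
    drift = np.abs(end_stocks - start_stocks) / scale
    if drift.max() > tol:
        raise RuntimeError(
            f"equilibration failed: residual drift {drift.max():.3f} over "
            f"{check_years} years exceeds {tol}; adjust demographic or krill "
            "rates (no stationary state reachable)")
    return q
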