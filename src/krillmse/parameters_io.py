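"""Parameterization and result I/O for the krill-predator-fishery simulator.

A *parameterization* bundles everything that defines one ecosystem instance:
the spatial units (SSMUs) with their areas and subarea labels, initial krill
stocks and mean individual mass, demographic and movement rates, the resident
predator populations with their foraging distributions, and the baseline
spatial/seasonal distribution of fishery catches.

On disk a parameterization is a directory holding one human-readable YAML
document (``parameterization.yaml``) plus one delimited table per movement
matrix.  All fractions are stored as decimals, never percent, and every file
carries a schema version tag so silent unit or layout drift fails loudly.

Time convention used throughout the package: the year has two seasons,
summer (``s = 0``) and winter (``s = 1``); the integer time step is
``t = 2 * y + s`` where ``y`` is the number of whole elapsed years, so the
first summer of a run is ``t = 0`` and a five-year reassessment interval is
exactly ten time steps.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

SCHEMA_VERSION = "krillmse-parameterization-1"
SCENARIO_SCHEMA_VERSION = "krillmse-scenario-1"

SUMMER, WINTER = 0, 1
N_SEASONS = 2
SEASON_NAMES = ("summer", "winter")

PREDATOR_GROUPS = ("penguins", "seals", "whales", "fish")
STRATEGIES = ("none", "fbm_krill", "fbm_pengs", "mpa")

RESULT_COLUMNS = ["scenario", "parameterization_id", "ssmu", "time_step", "variable", "value"]

_FRACTION_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when a parameterization violates a structural invariant.

    Carries the full list of violations so a config can be fixed in one pass.
    """

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        msg = "invalid parameterization:\n" + "\n".join(f"  - {v}" for v in self.violations)
        super().__init__(msg)


class FormatError(ValueError):
    """Raised when a config file cannot be parsed into the documented schema."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SSMUMap:
    """Geometry of the small-scale management units (SSMUs).

    Parameters
    ----------
    ssmu_ids
        Ordered unique identifiers, one per SSMU.
    areas
        Surface area of each SSMU in m^2 (strictly positive).
    subarea
        Statistical-subarea label per SSMU (three codes in the default
        Antarctic arena: ``"48.1"``, ``"48.2"``, ``"48.3"``).
    mpa_mask
        Boolean per SSMU; True marks units inside the no-take protected area.
    """

    ssmu_ids: list[str]
    areas: np.ndarray
    subarea: list[str]
    mpa_mask: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        self.mpa_mask = np.asarray(self.mpa_mask, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.ssmu_ids)


@dataclass
class PredatorPopulation:
    """One resident predator population.

    Each population lives in a single SSMU but forages across several,
    with a season-specific foraging distribution over all SSMUs.
    ``per_capita_demand`` and ``adult_survival`` are (summer, winter) pairs;
    demand is grams of krill per adult per season.  A cohort produced in a
    summer enters the adult class ``recruit_lag`` whole years later.
    """

    group: str
    resident_ssmu: str
    initial_adults: float
    per_capita_demand: tuple[float, float]
    foraging_dist: np.ndarray  # (2, n_ssmu)
    adult_survival: tuple[float, float]
    max_recruits_per_breeder: float
    recruit_lag: int

    def __post_init__(self) -> None:
        self.foraging_dist = np.asarray(self.foraging_dist, dtype=float)
        self.per_capita_demand = tuple(float(x) for x in self.per_capita_demand)
        self.adult_survival = tuple(float(x) for x in self.adult_survival)

    def annual_survival(self) -> float:
        return self.adult_survival[0] * self.adult_survival[1]


@dataclass
class ModelParameterization:
    """Everything defining one ecosystem instance.

    Seasonal arrays are stored season-major: shape ``(2, n_ssmu)`` with row 0
    summer and row 1 winter; movement matrices are ``(2, n, n)`` row-stochastic.
    ``krill_availability`` is the fraction of local krill biomass accessible to
    predators and the fishery within one season (swarms at foragable/fishable
    depth); consumption in an SSMU can never exceed it.
    """

    ssmu_map: SSMUMap
    initial_krill_biomass: np.ndarray  # g per SSMU
    initial_mean_mass: np.ndarray  # g per individual per SSMU
    mass_trend: np.ndarray  # fractional change per year per SSMU
    krill_recruit_rate: np.ndarray  # (2, n) production fraction per season
    krill_recruit_sigma: float  # log-SD of lognormal recruitment deviates
    krill_survival: np.ndarray  # (2, n) per-season survival fraction
    movement_matrices: np.ndarray  # (2, n, n) row-stochastic
    movement_mode: str  # "none" | "drift"
    predator_populations: list[PredatorPopulation]
    breeder_response: str  # "linear" | "hyperstable"
    hyperstable_halfsat: float
    base_catch_fractions: np.ndarray  # (2, n), sums to 1 overall
    krill_availability: float = 1.0
    parameterization_id: str = "default"

    def __post_init__(self) -> None:
        for name in ("initial_krill_biomass", "initial_mean_mass", "mass_trend",
                     "krill_recruit_rate", "krill_survival", "movement_matrices",
                     "base_catch_fractions"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def n_ssmu(self) -> int:
        return self.ssmu_map.n

    def copy(self) -> "ModelParameterization":
        pops = [dataclasses.replace(pp, foraging_dist=pp.foraging_dist.copy())
                for pp in self.predator_populations]
        return dataclasses.replace(
            self,
            ssmu_map=dataclasses.replace(
                self.ssmu_map,
                ssmu_ids=list(self.ssmu_map.ssmu_ids),
                areas=self.ssmu_map.areas.copy(),
                subarea=list(self.ssmu_map.subarea),
                mpa_mask=self.ssmu_map.mpa_mask.copy(),
            ),
            initial_krill_biomass=self.initial_krill_biomass.copy(),
            initial_mean_mass=self.initial_mean_mass.copy(),
            mass_trend=self.mass_trend.copy(),
            krill_recruit_rate=self.krill_recruit_rate.copy(),
            krill_survival=self.krill_survival.copy(),
            movement_matrices=self.movement_matrices.copy(),
            predator_populations=pops,
            base_catch_fractions=self.base_catch_fractions.copy(),
        )


@dataclass
class ScenarioSpec:
    """Configuration of one management scenario.

    ``gamma`` is the harvest rate applied to the initial arena krill biomass
    to set the overall annual catch limit (0.093 for the fully developed
    fishery); ``density_threshold`` is the krill density (g m^-2) below which
    the fishery suspends operations in an SSMU for the season; FBM strategies
    reassess the spatial allocation every ``reassess_interval_years`` years
    with sensitivity scalar ``alpha`` in the penguin rule.
    """

    strategy: str = "none"
    horizon_years: int = 100
    reassess_interval_years: int = 5
    alpha: float = 1.0
    density_threshold: float = 15.0
    gamma: float = 0.093
    climate_trend: bool = True
    n_trials: int = 1001
    seed: int = 0

    def __post_init__(self) -> None:
        errs = []
        if self.strategy not in STRATEGIES:
            errs.append(f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")
        if not (self.horizon_years >= self.reassess_interval_years >= 1):
            errs.append("require horizon_years >= reassess_interval_years >= 1")
        if not (0.0 <= self.gamma <= 1.0):
            errs.append("gamma must lie in [0, 1]")
        if self.density_threshold < 0:
            errs.append("density_threshold must be >= 0")
        if errs:
            raise ValidationError(errs)

    @property
    def n_steps(self) -> int:
        return 2 * self.horizon_years


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check_fraction_array(errs: list[str], arr: np.ndarray, name: str) -> None:
    if np.any(~np.isfinite(arr)):
        errs.append(f"{name} contains non-finite values")
    elif np.any(arr < 0) or np.any(arr > 1):
        errs.append(f"{name} must lie in [0, 1]")


def validate(p: ModelParameterization) -> list[str]:
    """Return the full list of invariant violations (empty when valid).

    Validation is total: every declared invariant is checked and reported,
    never silently repaired.
    """
    errs: list[str] = []
    m = p.ssmu_map
    n = m.n
    if len(set(m.ssmu_ids)) != n:
        errs.append("ssmu_ids are not unique")
    if m.areas.shape != (n,):
        errs.append(f"areas has shape {m.areas.shape}, expected ({n},)")
    elif np.any(~np.isfinite(m.areas)) or np.any(m.areas <= 0):
        errs.append("areas must be finite and strictly positive")
    if len(m.subarea) != n:
        errs.append("subarea labels must match the number of SSMUs")
    if m.mpa_mask.shape != (n,):
        errs.append(f"mpa_mask has length {m.mpa_mask.shape}, expected ({n},)")

    shape_bad = False
    for name, shape in (("initial_krill_biomass", (n,)),
                        ("initial_mean_mass", (n,)),
                        ("mass_trend", (n,)),
                        ("krill_recruit_rate", (N_SEASONS, n)),
                        ("krill_survival", (N_SEASONS, n)),
                        ("base_catch_fractions", (N_SEASONS, n)),
                        ("movement_matrices", (N_SEASONS, n, n))):
        arr = getattr(p, name)
        if arr.shape != shape:
            errs.append(f"{name} has shape {arr.shape}, expected {shape}")
            shape_bad = True
    if shape_bad or m.areas.shape != (n,) or m.mpa_mask.shape != (n,):
        return errs  # shape errors make the remaining checks meaningless

    if np.any(~np.isfinite(p.initial_krill_biomass)) or np.any(p.initial_krill_biomass < 0):
        errs.append("initial_krill_biomass must be finite and >= 0")
    if np.any(~np.isfinite(p.initial_mean_mass)) or np.any(p.initial_mean_mass <= 0):
        errs.append("initial_mean_mass must be finite and > 0")
    if np.any(~np.isfinite(p.mass_trend)):
        errs.append("mass_trend contains non-finite values")
    _check_fraction_array(errs, p.krill_recruit_rate, "krill_recruit_rate")
    _check_fraction_array(errs, p.krill_survival, "krill_survival")
    _check_fraction_array(errs, p.base_catch_fractions, "base_catch_fractions")
    if not (0.0 < p.krill_availability <= 1.0):
        errs.append("krill_availability must lie in (0, 1]")
    if p.krill_recruit_sigma < 0:
        errs.append("krill_recruit_sigma must be >= 0")

    total = float(p.base_catch_fractions.sum())
    if abs(total - 1.0) > _FRACTION_TOL:
        errs.append(f"base_catch_fractions sum to {total!r}, expected 1 over all SSMU x season cells")

    if p.movement_mode not in ("none", "drift"):
        errs.append(f"movement_mode must be 'none' or 'drift', got {p.movement_mode!r}")
    for s in range(N_SEASONS):
        M = p.movement_matrices[s]
        if np.any(~np.isfinite(M)) or np.any(M < 0):
            errs.append(f"movement matrix ({SEASON_NAMES[s]}) has negative or non-finite entries")
            continue
        rows = M.sum(axis=1)
        bad = np.where(np.abs(rows - 1.0) > _FRACTION_TOL)[0]
        for i in bad:
            errs.append(
                f"movement matrix ({SEASON_NAMES[s]}) row {m.ssmu_ids[i]} sums to {rows[i]!r}, expected 1"
            )
        if p.movement_mode == "none" and not np.allclose(M, np.eye(n), atol=_FRACTION_TOL):
            errs.append(f"movement_mode 'none' requires identity matrices ({SEASON_NAMES[s]})")

    if p.breeder_response not in ("linear", "hyperstable"):
        errs.append(f"breeder_response must be 'linear' or 'hyperstable', got {p.breeder_response!r}")
    if p.breeder_response == "hyperstable" and not p.hyperstable_halfsat > 0:
        errs.append("hyperstable_halfsat must be > 0 in hyperstable mode")

    ids = set(m.ssmu_ids)
    for k, pp in enumerate(p.predator_populations):
        tag = f"predator_populations[{k}] ({pp.group}@{pp.resident_ssmu})"
        if pp.group not in PREDATOR_GROUPS:
            errs.append(f"{tag}: unknown group {pp.group!r}")
        if pp.resident_ssmu not in ids:
            errs.append(f"{tag}: resident_ssmu not among ssmu_ids")
        if not np.isfinite(pp.initial_adults) or pp.initial_adults < 0:
            errs.append(f"{tag}: initial_adults must be finite and >= 0")
        if any(d < 0 or not np.isfinite(d) for d in pp.per_capita_demand):
            errs.append(f"{tag}: per_capita_demand must be finite and >= 0")
        if pp.foraging_dist.shape != (N_SEASONS, n):
            errs.append(f"{tag}: foraging_dist has shape {pp.foraging_dist.shape}, expected ({N_SEASONS}, {n})")
        else:
            if np.any(pp.foraging_dist < 0):
                errs.append(f"{tag}: foraging_dist has negative entries")
            sums = pp.foraging_dist.sum(axis=1)
            for s in range(N_SEASONS):
                if abs(sums[s] - 1.0) > _FRACTION_TOL:
                    errs.append(f"{tag}: foraging_dist ({SEASON_NAMES[s]}) sums to {sums[s]!r}, expected 1")
        if any(not (0.0 <= sv <= 1.0) for sv in pp.adult_survival):
            errs.append(f"{tag}: adult_survival must lie in [0, 1]")
        if pp.max_recruits_per_breeder < 0:
            errs.append(f"{tag}: max_recruits_per_breeder must be >= 0")
        if pp.recruit_lag < 0 or int(pp.recruit_lag) != pp.recruit_lag:
            errs.append(f"{tag}: recruit_lag must be a whole number of years >= 0")
    return errs


def validate_or_raise(p: ModelParameterization) -> None:
    errs = validate(p)
    if errs:
        raise ValidationError(errs)


# ---------------------------------------------------------------------------
# Parameterization save / load
# ---------------------------------------------------------------------------


def _matrix_filename(season: int) -> str:
    return f"movement_{SEASON_NAMES[season]}.csv"


def save_parameterization(p: ModelParameterization, path: str | Path) -> None:
    """Write ``p`` to directory ``path`` (YAML document + movement-matrix CSVs).

    Refuses to write an invalid parameterization; the output round-trips
    byte-identically through :func:`load_parameterization`.
    """
    validate_or_raise(p)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    doc = {
        "schema_version": SCHEMA_VERSION,
        "parameterization_id": p.parameterization_id,
        "ssmu": {
            "ids": list(p.ssmu_map.ssmu_ids),
            "areas_m2": [float(x) for x in p.ssmu_map.areas],
            "subarea": list(p.ssmu_map.subarea),
            "mpa_mask": [bool(x) for x in p.ssmu_map.mpa_mask],
        },
        "krill": {
            "initial_biomass_g": [float(x) for x in p.initial_krill_biomass],
            "initial_mean_mass_g": [float(x) for x in p.initial_mean_mass],
            "mass_trend_per_year": [float(x) for x in p.mass_trend],
            "recruit_rate": [[float(x) for x in row] for row in p.krill_recruit_rate],
            "recruit_sigma": float(p.krill_recruit_sigma),
            "survival": [[float(x) for x in row] for row in p.krill_survival],
            "availability": float(p.krill_availability),
            "movement_mode": p.movement_mode,
        },
        "breeder_response": p.breeder_response,
        "hyperstable_halfsat": float(p.hyperstable_halfsat),
        "base_catch_fractions": [[float(x) for x in row] for row in p.base_catch_fractions],
        "predator_populations": [
            {
                "group": pp.group,
                "resident_ssmu": pp.resident_ssmu,
                "initial_adults": float(pp.initial_adults),
                "per_capita_demand_g": [float(x) for x in pp.per_capita_demand],
                "foraging_dist": [[float(x) for x in row] for row in pp.foraging_dist],
                "adult_survival": [float(x) for x in pp.adult_survival],
                "max_recruits_per_breeder": float(pp.max_recruits_per_breeder),
                "recruit_lag_years": int(pp.recruit_lag),
            }
            for pp in p.predator_populations
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=True, default_flow_style=None, width=100)
    (path / "parameterization.yaml").write_text(text)
    for s in range(N_SEASONS):
        np.savetxt(path / _matrix_filename(s), p.movement_matrices[s],
                   delimiter=",", fmt="%.17g")


def load_parameterization(path: str | Path) -> ModelParameterization:
    """Load and validate a parameterization directory written by
    :func:`save_parameterization`."""
    path = Path(path)
    yml = path / "parameterization.yaml"
    if not yml.exists():
        raise FormatError(f"no parameterization.yaml under {path}")
    try:
        doc = yaml.safe_load(yml.read_text())
    except yaml.YAMLError as e:  # pragma: no cover - parser detail
        raise FormatError(f"cannot parse {yml}: {e}") from e
    if not isinstance(doc, dict):
        raise FormatError(f"{yml} does not contain a mapping")
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(
            f"schema_version is {doc.get('schema_version')!r}, expected {SCHEMA_VERSION!r}")

    def need(d: dict, key: str, where: str = "document"):
        if key not in d:
            raise FormatError(f"missing key {key!r} in {where}")
        return d[key]

    ssmu = need(doc, "ssmu")
    krill = need(doc, "krill")
    try:
        mats = np.stack([
            np.atleast_2d(np.loadtxt(path / _matrix_filename(s), delimiter=","))
            for s in range(N_SEASONS)
        ])
    except OSError as e:
        raise FormatError(f"missing movement matrix table: {e}") from e

    pops = [
        PredatorPopulation(
            group=need(d, "group", "predator population"),
            resident_ssmu=need(d, "resident_ssmu", "predator population"),
            initial_adults=need(d, "initial_adults", "predator population"),
            per_capita_demand=tuple(need(d, "per_capita_demand_g", "predator population")),
            foraging_dist=np.asarray(need(d, "foraging_dist", "predator population"), dtype=float),
            adult_survival=tuple(need(d, "adult_survival", "predator population")),
            max_recruits_per_breeder=need(d, "max_recruits_per_breeder", "predator population"),
            recruit_lag=int(need(d, "recruit_lag_years", "predator population")),
        )
        for d in need(doc, "predator_populations")
    ]
    p = ModelParameterization(
        ssmu_map=SSMUMap(
            ssmu_ids=[str(x) for x in need(ssmu, "ids", "ssmu")],
            areas=np.asarray(need(ssmu, "areas_m2", "ssmu"), dtype=float),
            subarea=[str(x) for x in need(ssmu, "subarea", "ssmu")],
            mpa_mask=np.asarray(need(ssmu, "mpa_mask", "ssmu"), dtype=bool),
        ),
        initial_krill_biomass=need(krill, "initial_biomass_g", "krill"),
        initial_mean_mass=need(krill, "initial_mean_mass_g", "krill"),
        mass_trend=need(krill, "mass_trend_per_year", "krill"),
        krill_recruit_rate=need(krill, "recruit_rate", "krill"),
        krill_recruit_sigma=float(need(krill, "recruit_sigma", "krill")),
        krill_survival=need(krill, "survival", "krill"),
        movement_matrices=mats,
        movement_mode=need(krill, "movement_mode", "krill"),
        predator_populations=pops,
        breeder_response=need(doc, "breeder_response"),
        hyperstable_halfsat=float(need(doc, "hyperstable_halfsat")),
        base_catch_fractions=need(doc, "base_catch_fractions"),
        krill_availability=float(need(krill, "availability", "krill")),
        parameterization_id=str(doc.get("parameterization_id", "default")),
    )
    validate_or_raise(p)
    return p


def parameterizations_equal(a: ModelParameterization, b: ModelParameterization,
                            rtol: float = 0.0, atol: float = 0.0) -> bool:
    """Field-by-field equality of two parameterizations."""
    if (a.ssmu_map.ssmu_ids != b.ssmu_map.ssmu_ids
            or a.ssmu_map.subarea != b.ssmu_map.subarea
            or not np.array_equal(a.ssmu_map.mpa_mask, b.ssmu_map.mpa_mask)
            or a.movement_mode != b.movement_mode
            or a.breeder_response != b.breeder_response
            or a.parameterization_id != b.parameterization_id
            or len(a.predator_populations) != len(b.predator_populations)):
        return False
    close = lambda x, y: np.allclose(x, y, rtol=rtol, atol=atol)
    if not (close(a.ssmu_map.areas, b.ssmu_map.areas)
            and close(a.initial_krill_biomass, b.initial_krill_biomass)
            and close(a.initial_mean_mass, b.initial_mean_mass)
            and close(a.mass_trend, b.mass_trend)
            and close(a.krill_recruit_rate, b.krill_recruit_rate)
            and close(a.krill_survival, b.krill_survival)
            and close(a.movement_matrices, b.movement_matrices)
            and close(a.base_catch_fractions, b.base_catch_fractions)
            and close(a.krill_recruit_sigma, b.krill_recruit_sigma)
            and close(a.hyperstable_halfsat, b.hyperstable_halfsat)
            and close(a.krill_availability, b.krill_availability)):
        return False
    for pa, pb in zip(a.predator_populations, b.predator_populations):
        if (pa.group != pb.group or pa.resident_ssmu != pb.resident_ssmu
                or pa.recruit_lag != pb.recruit_lag
                or not close(pa.initial_adults, pb.initial_adults)
                or not close(pa.per_capita_demand, pb.per_capita_demand)
                or not close(pa.foraging_dist, pb.foraging_dist)
                or not close(pa.adult_survival, pb.adult_survival)
                or not close(pa.max_recruits_per_breeder, pb.max_recruits_per_breeder)):
            return False
    return True


# ---------------------------------------------------------------------------
# Scenario config
# ---------------------------------------------------------------------------


def save_scenario(spec: ScenarioSpec, path: str | Path) -> None:
    doc = {"schema_version": SCENARIO_SCHEMA_VERSION}
    doc.update({f.name: getattr(spec, f.name) for f in dataclasses.fields(spec)})
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_scenario(path: str | Path) -> ScenarioSpec:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise FormatError(f"{path} does not contain a mapping")
    if doc.get("schema_version") != SCENARIO_SCHEMA_VERSION:
        raise FormatError(
            f"schema_version is {doc.get('schema_version')!r}, expected {SCENARIO_SCHEMA_VERSION!r}")
    doc = {k: v for k, v in doc.items() if k != "schema_version"}
    known = {f.name for f in dataclasses.fields(ScenarioSpec)}
    unknown = set(doc) - known
    if unknown:
        raise FormatError(f"unknown scenario keys: {sorted(unknown)}")
    return ScenarioSpec(**doc)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def write_results(obj, path: str | Path) -> None:
    """Write an ensemble summary or relative-outcome table as delimited text.

    One row per (SSMU or "arena", time step, variable); header columns are
    ``scenario, parameterization_id, ssmu, time_step, variable, value``.
    Refuses to write an empty table.
    """
    frame = obj if isinstance(obj, pd.DataFrame) else obj.to_frame()
    if len(frame) == 0:
        raise ValueError("refusing to write an empty result table")
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"result table lacks columns {missing}")
    frame = frame[RESULT_COLUMNS + [c for c in frame.columns if c not in RESULT_COLUMNS]]
    frame.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"result table lacks columns {missing}")
    return frame
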