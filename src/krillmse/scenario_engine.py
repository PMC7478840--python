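"""Monte-Carlo scenario execution over the reference set.

A *trial* is one stochastic projection of one parameterization under one
management strategy.  An *ensemble* averages many trials over the (typically
four-member) reference set.  Scenario/base-case pairs run on common random
numbers by default: trial ``k`` of parameterization ``m`` uses the RNG stream
``SeedSequence(base_seed, spawn_key=(m, k))`` in both arms, so a strategy that
does nothing reproduces the base case bit for bit and counterfactual ratios
are exactly 1.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .ecosystem_core import EcosystemState, initial_state, step_season
from .management_strategies import (
    FisheryControls,
    ReassessmentRecord,
    apply_strategy,
    initial_controls,
    penguin_abundance_by_ssmu,
    reassessment_times,
)
from .parameters_io import ModelParameterization, ScenarioSpec

logger = logging.getLogger(__name__)


def slice_step(year: int) -> int:
    """Summer time step of calendar year ``year`` of the run (year 1 -> t=0)."""
    if year < 1:
        raise ValueError("years are counted from 1")
    return 2 * (year - 1)


@dataclass
class TrialTrajectory:
    """Per-step series recorded at the start of each season, plus per-step
    realized/allocated catch and violation flags."""

    parameterization_id: str
    trial_seed: tuple
    krill_biomass: np.ndarray  # (T, n) start-of-step
    predator_adults: np.ndarray  # (T, n_pop) start-of-step
    realized_catch: np.ndarray  # (T, n) g taken during the step
    allocated_catch: np.ndarray  # (T, n) g catch-limit biomass for the step
    violations: np.ndarray  # (T, n) bool
    reassessments: list[ReassessmentRecord] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return self.krill_biomass.shape[0]


class _History:
    """Start-of-step state lookups used by the feedback rules."""

    def __init__(self, traj: TrialTrajectory, p: ModelParameterization, spec: ScenarioSpec):
        self._traj = traj
        self._p = p
        self._spec = spec

    def krill_biomass_at(self, t: int) -> np.ndarray:
        return self._traj.krill_biomass[t]

    def penguin_adults_at(self, t: int) -> np.ndarray:
        return penguin_abundance_by_ssmu(self._p, self._traj.predator_adults[t])

    def mean_mass_at(self, t: int) -> np.ndarray:
        from .ecosystem_core import apply_mass_trend

        if not self._spec.climate_trend:
            return self._p.initial_mean_mass
        return apply_mass_trend(self._p.initial_mean_mass, self._p.mass_trend, t // 2)


def run_trial(p: ModelParameterization, spec: ScenarioSpec,
              seed) -> TrialTrajectory:
    """Run one trial; fully reproducible from ``(p, spec, seed)``.

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.  The MPA
    and baseline allocations are fixed at t = 0; FBM strategies reassess at
    summer steps every ``reassess_interval_years`` years.
    """
    rng = np.random.default_rng(seed)
    T, n = spec.n_steps, p.n_ssmu
    npop = len(p.predator_populations)
    traj = TrialTrajectory(
        parameterization_id=p.parameterization_id,
        trial_seed=(seed if isinstance(seed, int) else getattr(seed, "spawn_key", None)),
        krill_biomass=np.empty((T, n)),
        predator_adults=np.empty((T, npop)),
        realized_catch=np.empty((T, n)),
        allocated_catch=np.empty((T, n)),
        violations=np.empty((T, n), dtype=bool),
    )
    controls = initial_controls(p, spec)
    state = initial_state(p)
    history = _History(traj, p, spec)
    reassess = set(reassessment_times(spec.reassess_interval_years, spec.horizon_years)) \
        if spec.strategy in ("fbm_krill", "fbm_pengs") else set()

    for t in range(T):
        traj.krill_biomass[t] = state.krill_biomass
        traj.predator_adults[t] = state.predator_adults
        if t in reassess:
            controls, record = apply_strategy(spec.strategy, history, controls, p, spec, t)
            traj.reassessments.append(record)
        state, outcome = step_season(state, p, controls, spec, rng)
        traj.realized_catch[t] = outcome.realized_catch
        traj.allocated_catch[t] = outcome.allocated_catch
        traj.violations[t] = outcome.violations
    return traj


@dataclass
class EnsembleSummary:
    """Trial-and-parameterization-averaged trajectories for one scenario.

    ``mean_*`` arrays average over all trials of all parameterizations.
    ``fished_violation_share[t, i]`` is the share of trials in which SSMU
    ``i`` had catch allocated *and* was below the density threshold in step
    ``t``; ``fished_share`` is the share with catch allocated at all.
    """

    strategy: str
    spec: ScenarioSpec
    ssmu_ids: list[str]
    population_groups: list[str]
    population_ssmu: list[str]
    n_trials: int
    n_parameterizations: int
    mean_krill_biomass: np.ndarray  # (T, n)
    mean_predator_adults: np.ndarray  # (T, n_pop)
    mean_realized_catch: np.ndarray  # (T, n)
    mean_allocated_catch: np.ndarray  # (T, n)
    fished_violation_share: np.ndarray  # (T, n)
    fished_share: np.ndarray  # (T, n)
    any_fished_violation_share: np.ndarray  # (T,) share of trials with >=1 fished SSMU violating
    any_fished_share: np.ndarray  # (T,) share of trials with >=1 fished SSMU

    @property
    def n_steps(self) -> int:
        return self.mean_krill_biomass.shape[0]

    def violation_frequency(self, up_to_step: int | None = None) -> np.ndarray:
        """Per-SSMU probability that a fishing season (catch allocated)
        violates the density threshold, over steps up to ``up_to_step``
        inclusive.  SSMUs never fished report 0."""
        hi = self.n_steps if up_to_step is None else up_to_step + 1
        flagged = self.fished_violation_share[:hi].sum(axis=0)
        fished = self.fished_share[:hi].sum(axis=0)
        out = np.zeros_like(flagged)
        nz = fished > 0
        out[nz] = flagged[nz] / fished[nz]
        return out

    def arena_violation_probability(self, up_to_step: int | None = None,
                                    how: str = "any") -> float:
        """Arena-scale violation probability over steps up to ``up_to_step``.

        ``how='any'``: probability that at least one fished SSMU violates in a
        season.  ``how='weighted'``: catch-weighted mean of the per-SSMU
        probabilities (weights are allocated catch totals).
        """
        hi = self.n_steps if up_to_step is None else up_to_step + 1
        if how == "any":
            denom = self.any_fished_share[:hi].sum()
            return float(self.any_fished_violation_share[:hi].sum() / denom) if denom > 0 else 0.0
        if how == "weighted":
            probs = self.violation_frequency(up_to_step)
            w = self.mean_allocated_catch[:hi].sum(axis=0)
            return float((probs * w).sum() / w.sum()) if w.sum() > 0 else 0.0
        raise ValueError(f"unknown aggregation {how!r}")

    def abundance_by_group_ssmu(self, t: int) -> dict[str, np.ndarray]:
        """Mean adult abundance per predator group and SSMU at step ``t``."""
        idx = {sid: i for i, sid in enumerate(self.ssmu_ids)}
        out: dict[str, np.ndarray] = {}
        for j, (g, sid) in enumerate(zip(self.population_groups, self.population_ssmu)):
            arr = out.setdefault(g, np.zeros(len(self.ssmu_ids)))
            arr[idx[sid]] += self.mean_predator_adults[t, j]
        return out

    def annual_catch(self, year: int) -> np.ndarray:
        """Mean realized catch (g per SSMU) summed over the two seasons of
        calendar year ``year``."""
        t = slice_step(year)
        return self.mean_realized_catch[t] + self.mean_realized_catch[t + 1]

    def to_frame(self):
        """Long result table (one row per SSMU, step and variable)."""
        import pandas as pd

        T, n = self.mean_krill_biomass.shape
        rows = []
        for name, arr in (("krill_biomass_g", self.mean_krill_biomass),
                          ("realized_catch_g", self.mean_realized_catch),
                          ("allocated_catch_g", self.mean_allocated_catch)):
            for t in range(T):
                for i, sid in enumerate(self.ssmu_ids):
                    rows.append((self.strategy, "mean", sid, t, name, arr[t, i]))
        frame = pd.DataFrame(rows, columns=["scenario", "parameterization_id", "ssmu",
                                            "time_step", "variable", "value"])
        return frame


def trial_seed_sequence(base_seed: int, param_index: int, trial_index: int,
                        arm: int | None = None) -> np.random.SeedSequence:
    """The documented per-trial seed derivation.

    Paired (common-random-number) runs omit ``arm`` so both arms share the
    stream; unpaired runs include the arm index in the spawn key.
    """
    key = (param_index, trial_index) if arm is None else (arm, param_index, trial_index)
    return np.random.SeedSequence(entropy=base_seed, spawn_key=key)


def run_ensemble(reference_set: list[ModelParameterization], spec: ScenarioSpec,
                 n_trials: int, base_seed: int, arm: int | None = None,
                 progress: bool = False) -> EnsembleSummary:
    """Run ``n_trials`` trials of every parameterization and average.

    Summaries are sums over a fixed (parameterization, trial) order divided
    by the trial count, so they do not depend on execution interleaving.
    Any non-finite trajectory aborts with the offending trial identified.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not reference_set:
        raise ValueError("reference set is empty")
    p0 = reference_set[0]
    T, n = spec.n_steps, p0.n_ssmu
    npop = len(p0.predator_populations)
    acc_krill = np.zeros((T, n))
    acc_adults = np.zeros((T, npop))
    acc_catch = np.zeros((T, n))
    acc_alloc = np.zeros((T, n))
    acc_viol = np.zeros((T, n))
    acc_fished = np.zeros((T, n))
    acc_any_viol = np.zeros(T)
    acc_any_fished = np.zeros(T)
    total = 0
    for m, p in enumerate(reference_set):
        for k in range(n_trials):
            seed = trial_seed_sequence(base_seed, m, k, arm)
            traj = run_trial(p, spec, seed)
            if not (np.isfinite(traj.krill_biomass).all()
                    and np.isfinite(traj.predator_adults).all()
                    and np.isfinite(traj.realized_catch).all()):
                raise FloatingPointError(
                    f"non-finite trajectory in trial {k} of parameterization "
                    f"{p.parameterization_id!r}")
            acc_krill += traj.krill_biomass
            acc_adults += traj.predator_adults
            acc_catch += traj.realized_catch
            acc_alloc += traj.allocated_catch
            fished = traj.allocated_catch > 0
            acc_viol += traj.violations & fished
            acc_fished += fished
            acc_any_viol += (traj.violations & fished).any(axis=1)
            acc_any_fished += fished.any(axis=1)
            total += 1
        if progress:
            logger.info("parameterization %s: %d trials done", p.parameterization_id, n_trials)
    return EnsembleSummary(
        strategy=spec.strategy,
        spec=spec,
        ssmu_ids=list(p0.ssmu_map.ssmu_ids),
        population_groups=[pp.group for pp in p0.predator_populations],
        population_ssmu=[pp.resident_ssmu for pp in p0.predator_populations],
        n_trials=n_trials,
        n_parameterizations=len(reference_set),
        mean_krill_biomass=acc_krill / total,
        mean_predator_adults=acc_adults / total,
        mean_realized_catch=acc_catch / total,
        mean_allocated_catch=acc_alloc / total,
        fished_violation_share=acc_viol / total,
        fished_share=acc_fished / total,
        any_fished_violation_share=acc_any_viol / total,
        any_fished_share=acc_any_fished / total,
    )


def run_comparison(p_set: list[ModelParameterization], strategy: str,
                   spec: ScenarioSpec, n_trials: int, base_seed: int,
                   paired: bool = True,
                   progress: bool = False) -> tuple[EnsembleSummary, EnsembleSummary]:
    """Run a strategy scenario and its matching base case.

    The base case is parameterized identically (same reference set, climate
    trend, harvest rate and, when ``paired``, the same random-number streams);
    only the management strategy differs.
    """
    spec_s = dataclasses.replace(spec, strategy=strategy)
    spec_b = dataclasses.replace(spec, strategy="none")
    arm_s, arm_b = (None, None) if paired else (0, 1)
    scenario = run_ensemble(p_set, spec_s, n_trials, base_seed, arm=arm_s, progress=progress)
    base = run_ensemble(p_set, spec_b, n_trials, base_seed, arm=arm_b, progress=progress)
    return scenario, base
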