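"""Counterfactual evaluation of management scenarios.

Every outcome is expressed relative to the matching base case: the ratio of
the scenario's trial-averaged value to the base case's, so 1.0 means the
management action had no effect, > 1 an increase and < 1 a decrease.  Ratios
are reported alongside signed deltas (ratio - 1) and a coarse magnitude
class: an absolute delta below 0.01 is "none", 0.01-0.10 "small",
above 0.10 up to 0.50 "medium", and above 0.50 "large".

Arena-scale outcomes are ratios of summed totals (total arena abundance or
catch), never means of per-SSMU ratios.  Evaluation slices are taken at the
summer step of two calendar years (30 and 100 by default); "catch at year Y"
is the realized catch summed over that year's two seasons, and violation
probabilities accumulate over all steps up to the slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters_io import PREDATOR_GROUPS
from .scenario_engine import EnsembleSummary, slice_step

MAGNITUDE_CLASSES = ("none", "small", "medium", "large")


@dataclass
class RelativeOutcome:
    """One scenario-vs-base outcome."""

    metric: str
    scale: str  # "arena" | "ssmu"
    ssmu: str  # SSMU id or "arena"
    time_slice_year: int
    ratio: float
    delta: float
    magnitude_class: str


def relative_change(scenario_mean: float, base_mean: float) -> float:
    """Counterfactual ratio scenario/base.

    0/0 is 1.0 by convention (no effect, warned); a positive scenario value
    over a zero base is undefined and returned as NaN with a warning.
    """
    if base_mean > 0:
        return float(scenario_mean) / float(base_mean)
    if scenario_mean == 0:
        warnings.warn("0/0 counterfactual ratio reported as 1.0", stacklevel=2)
        return 1.0
    warnings.warn("positive scenario value over zero base: undefined ratio (NaN)",
                  stacklevel=2)
    return float("nan")


def aggregate_arena(scenario_per_ssmu: np.ndarray, base_per_ssmu: np.ndarray) -> float:
    """Arena-scale counterfactual: ratio of summed totals."""
    return relative_change(float(np.sum(scenario_per_ssmu)), float(np.sum(base_per_ssmu)))


def violation_probability(flags: np.ndarray, allocated: np.ndarray) -> np.ndarray:
    """Per-SSMU probability that a fishing season violates the threshold.

    ``flags`` and ``allocated`` have shape (trials, steps, SSMUs); only
    seasons with nonzero allocated catch count.  An SSMU never fished has an
    undefined probability and is reported as 0.
    """
    flags = np.asarray(flags, dtype=bool)
    fished = np.asarray(allocated) > 0
    flagged = (flags & fished).sum(axis=(0, 1)).astype(float)
    denom = fished.sum(axis=(0, 1)).astype(float)
    out = np.zeros_like(flagged)
    nz = denom > 0
    out[nz] = flagged[nz] / denom[nz]
    if np.any(~nz):
        warnings.warn("SSMU(s) with no allocated catch: violation probability "
                      "undefined, reported as 0", stacklevel=2)
    return out


def classify_magnitude(delta: float) -> str:
    """Coarse comparison scale for a signed delta (ratio - 1)."""
    d = abs(delta)
    if d < 0.01:
        return "none"
    if d <= 0.10:
        return "small"
    if d <= 0.50:
        return "medium"
    return "large"


def _ratio_vec(scn: np.ndarray, base: np.ndarray) -> np.ndarray:
    out = np.empty(len(scn))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(len(scn)):
            out[i] = relative_change(scn[i], base[i])
    return out


def compare_summaries(scenario: EnsembleSummary, base: EnsembleSummary,
                      years: tuple[int, ...] = (30, 100)) -> pd.DataFrame:
    """All relative outcomes (abundance per group, catch, violation
    probability) at each evaluation year, at arena and SSMU scale."""
    if scenario.ssmu_ids != base.ssmu_ids:
        raise ValueError("summaries cover different SSMU sets")
    rows: list[RelativeOutcome] = []

    def add(metric, scale, ssmu, year, ratio):
        rows.append(RelativeOutcome(metric, scale, ssmu, year, ratio,
                                    ratio - 1.0, classify_magnitude(ratio - 1.0)))

    for year in years:
        t = slice_step(year)
        ab_s = scenario.abundance_by_group_ssmu(t)
        ab_b = base.abundance_by_group_ssmu(t)
        for g in PREDATOR_GROUPS:
            if g not in ab_s:
                continue
            add(f"abundance_{g}", "arena", "arena", year, aggregate_arena(ab_s[g], ab_b[g]))
            ratios = _ratio_vec(ab_s[g], ab_b[g])
            resident = ab_b[g] > 0
            for i, sid in enumerate(scenario.ssmu_ids):
                if resident[i]:
                    add(f"abundance_{g}", "ssmu", sid, year, ratios[i])
        catch_s, catch_b = scenario.annual_catch(year), base.annual_catch(year)
        add("catch", "arena", "arena", year, aggregate_arena(catch_s, catch_b))
        catch_ratios = _ratio_vec(catch_s, catch_b)
        for i, sid in enumerate(scenario.ssmu_ids):
            if catch_b[i] > 0 or catch_s[i] > 0:
                add("catch", "ssmu", sid, year,
                    catch_ratios[i] if catch_b[i] > 0 else float("nan"))
        vp_s = scenario.violation_frequency(t + 1)
        vp_b = base.violation_frequency(t + 1)
        for how in ("any", "weighted"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = relative_change(scenario.arena_violation_probability(t + 1, how),
                                    base.arena_violation_probability(t + 1, how))
            add(f"violation_probability_{how}", "arena", "arena", year, r)
        ratios = _ratio_vec(vp_s, vp_b)
        for i, sid in enumerate(scenario.ssmu_ids):
            if vp_b[i] > 0 or vp_s[i] > 0:
                add("violation_probability", "ssmu", sid, year,
                    ratios[i] if vp_b[i] > 0 else float("nan"))

    return pd.DataFrame([vars(r) for r in rows])


def tradeoff_records(catch_ratios: np.ndarray, abundance_ratios: dict[str, np.ndarray],
                     ssmu_ids: list[str], strategy: str, time_slice_year: int,
                     open_mask: np.ndarray | None = None) -> pd.DataFrame:
    """Catch-vs-predator trade-off records, one per (open SSMU, group).

    Quadrants are labeled relative to the no-effect point (1, 1).
    """
    n = len(ssmu_ids)
    open_mask = np.ones(n, dtype=bool) if open_mask is None else np.asarray(open_mask, bool)

    def side(v, word_lo, word_hi):
        if np.isnan(v):
            return "undefined"
        if v < 1.0:
            return word_lo
        if v > 1.0:
            return word_hi
        return "same"

    rows = []
    for i in np.flatnonzero(open_mask):
        for g, ab in abundance_ratios.items():
            c, a = float(catch_ratios[i]), float(ab[i])
            cl, al = side(c, "less", "more"), side(a, "fewer", "more")
            if cl == "same" and al == "same":
                label = "no change"
            elif "undefined" in (cl, al):
                label = "undefined"
            else:
                label = f"{cl} catch, {al} predators"
            rows.append({"strategy": strategy, "ssmu": ssmu_ids[i], "group": g,
                         "time_slice_year": time_slice_year, "catch_ratio": c,
                         "abundance_ratio": a, "quadrant": label})
    return pd.DataFrame(rows)


def outcomes_to_results(outcomes: pd.DataFrame, scenario_name: str) -> pd.DataFrame:
    """Reshape a compare_summaries table into the standard long result layout."""
    rows = []
    for r in outcomes.itertuples(index=False):
        t = slice_step(r.time_slice_year)
        rows.append((scenario_name, "mean", r.ssmu, t, f"{r.metric}_ratio", r.ratio))
        rows.append((scenario_name, "mean", r.ssmu, t, f"{r.metric}_delta", r.delta))
    return pd.DataFrame(rows, columns=["scenario", "parameterization_id", "ssmu",
                                       "time_step", "variable", "value"])


# ---------------------------------------------------------------------------
# Optional figures
# ---------------------------------------------------------------------------


def plot_arena_deltas(outcomes: pd.DataFrame, path) -> None:
    """Bar chart of arena-scale deltas per metric and evaluation year."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arena = outcomes[outcomes["scale"] == "arena"]
    fig, ax = plt.subplots(figsize=(8, 4))
    years = sorted(arena["time_slice_year"].unique())
    metrics = list(dict.fromkeys(arena["metric"]))
    width = 0.8 / max(len(years), 1)
    xs = np.arange(len(metrics))
    for k, y in enumerate(years):
        sub = arena[arena["time_slice_year"] == y].set_index("metric")["delta"]
        ax.bar(xs + k * width, [sub.get(m, np.nan) for m in metrics], width, label=f"year {y}")
    ax.axhline(0.0, color="grey", ls="--", lw=0.8)
    ax.set_xticks(xs + width / 2)
    ax.set_xticklabels(metrics, rotation=45, ha="right", fontsize=8)
    ax.set_ylabel("delta (ratio - 1)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tradeoffs(records: pd.DataFrame, path) -> None:
    """Scatter of catch vs abundance ratios with x = 1 / y = 1 reference lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for strat, sub in records.groupby("strategy"):
        ax.scatter(sub["catch_ratio"], sub["abundance_ratio"], s=18, alpha=0.7, label=strat)
    ax.axvline(1.0, color="grey", ls="--", lw=0.8)
    ax.axhline(1.0, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("relative catch (scenario / base)")
    ax.set_ylabel("relative abundance (scenario / base)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
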