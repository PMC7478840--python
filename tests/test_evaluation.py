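import warnings

import numpy as np
import pytest

from krillmse.evaluation import (
    aggregate_arena,
    classify_magnitude,
    compare_summaries,
    outcomes_to_results,
    relative_change,
    tradeoff_records,
    violation_probability,
)
from krillmse.parameters_io import ScenarioSpec
from krillmse.scenario_engine import run_comparison, run_ensemble


def test_ratio_conventions():
    assert relative_change(3.0, 3.0) == 1.0
    assert relative_change(1.35, 1.0) == pytest.approx(1.35)
    with pytest.warns(UserWarning):
        assert relative_change(0.0, 0.0) == 1.0
    with pytest.warns(UserWarning):
        assert np.isnan(relative_change(2.0, 0.0))


def test_arena_ratio_is_ratio_of_sums_not_mean_of_ratios():
    scn = np.array([2.0, 30.0])
    base = np.array([1.0, 30.0])
    # mean of per-SSMU ratios would be 1.5; ratio of sums is 32/31
    assert aggregate_arena(scn, base) == pytest.approx(32 / 31)
    assert aggregate_arena(np.array([5.0]), np.array([4.0])) == pytest.approx(1.25)
    with pytest.warns(UserWarning):
        assert np.isnan(aggregate_arena(np.array([1.0, 1.0]), np.array([0.0, 0.0])))


def test_arena_ratio_between_ssmu_extremes():
    rng = np.random.default_rng(0)
    for _ in range(50):
        base = rng.uniform(0.5, 2.0, 5)
        scn = base * rng.uniform(0.5, 2.0, 5)
        ratios = scn / base
        arena = aggregate_arena(scn, base)
        assert ratios.min() - 1e-12 <= arena <= ratios.max() + 1e-12


def test_violation_probability_conditions_on_fishing():
    flags = np.zeros((4, 5, 2), dtype=bool)
    alloc = np.zeros((4, 5, 2))
    alloc[:, :, 0] = 1.0  # SSMU 0 fished in every trial-season
    flags[0, :3, 0] = True  # 3 flagged of 20 fished trial-seasons
    flags[:, :, 1] = True  # never fished: flags must not count
    with pytest.warns(UserWarning):
        out = violation_probability(flags, alloc)
    assert out[0] == pytest.approx(0.15)
    assert out[1] == 0.0
    flags[:, :, 0] = True
    assert violation_probability(flags[:, :, :1], alloc[:, :, :1])[0] == 1.0


def test_magnitude_boundaries():
    assert classify_magnitude(0.0) == "none"
    assert classify_magnitude(0.009999) == "none"
    assert classify_magnitude(0.01) == "small"
    assert classify_magnitude(-0.04) == "small"
    assert classify_magnitude(0.10) == "small"
    assert classify_magnitude(0.100001) == "medium"
    assert classify_magnitude(-0.30) == "medium"
    assert classify_magnitude(0.50) == "medium"
    assert classify_magnitude(0.6) == "large"
    assert classify_magnitude(-5.0) == "large"


def test_comparison_table_shapes(reference_set):
    spec = ScenarioSpec(strategy="none", horizon_years=20, n_trials=1, seed=0)
    scenario, base = run_comparison(reference_set, "mpa", spec, n_trials=1, base_seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = compare_summaries(scenario, base, years=(10, 20))
    arena = out[out["scale"] == "arena"]
    # per slice: 4 group abundances + catch + 2 violation aggregations
    assert len(arena) == 2 * (4 + 1 + 2)
    peng = out[(out["metric"] == "abundance_penguins") & (out["scale"] == "ssmu")]
    assert len(peng) == 2 * 12  # one row per resident SSMU and slice
    assert set(out["magnitude_class"]) <= {"none", "small", "medium", "large"}


def test_self_comparison_is_exactly_one(reference_set):
    spec = ScenarioSpec(strategy="none", horizon_years=10, n_trials=2, seed=0)
    a = run_ensemble(reference_set, spec, n_trials=2, base_seed=9)
    b = run_ensemble(reference_set, spec, n_trials=2, base_seed=9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = compare_summaries(a, b, years=(5, 10))
    assert (out["ratio"].dropna() == 1.0).all()


def test_tradeoff_quadrants():
    catch = np.array([0.8, 1.0, 1.2, np.nan])
    ab = {"penguins": np.array([1.2, 1.0, 0.9, 1.0])}
    rec = tradeoff_records(catch, ab, ["A", "B", "C", "D"], "mpa", 100)
    assert len(rec) == 4
    q = dict(zip(rec["ssmu"], rec["quadrant"]))
    assert q["A"] == "less catch, more predators"
    assert q["B"] == "no change"
    assert q["C"] == "more catch, fewer predators"
    assert q["D"] == "undefined"


def test_tradeoff_record_count_matches_open_ssmus():
    catch = np.ones(5)
    ab = {"penguins": np.ones(5), "seals": np.ones(5)}
    rec = tradeoff_records(catch, ab, [f"U{i}" for i in range(5)], "mpa", 30,
                           open_mask=np.array([True, True, True, False, False]))
    assert len(rec) == 3 * 2


def test_outcomes_reshape_to_result_layout(reference_set):
    spec = ScenarioSpec(strategy="none", horizon_years=10, n_trials=1, seed=0)
    s, b = run_comparison(reference_set, "mpa", spec, n_trials=1, base_seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = compare_summaries(s, b, years=(10,))
    table = outcomes_to_results(out, "mpa")
    assert list(table.columns) == ["scenario", "parameterization_id", "ssmu",
                                   "time_step", "variable", "value"]
    assert len(table) == 2 * len(out)


def test_plots_write_files(reference_set, tmp_path):
    spec = ScenarioSpec(strategy="none", horizon_years=10, n_trials=1, seed=0)
    s, b = run_comparison(reference_set, "mpa", spec, n_trials=1, base_seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = compare_summaries(s, b, years=(10,))
    from krillmse.evaluation import plot_arena_deltas, plot_tradeoffs
    plot_arena_deltas(out, tmp_path / "deltas.png")
    rec = tradeoff_records(np.ones(3), {"penguins": np.ones(3)}, ["A", "B", "C"], "mpa", 10)
    plot_tradeoffs(rec, tmp_path / "tradeoffs.png")
    assert (tmp_path / "deltas.png").stat().st_size > 0
    assert (tmp_path / "tradeoffs.png").stat().st_size > 0
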