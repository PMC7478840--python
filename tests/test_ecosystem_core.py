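import numpy as np
import pytest

from krillmse.ecosystem_core import (
    EcosystemState,
    apply_mass_trend,
    effective_breeder_fraction,
    foraging_success,
    initial_state,
    krill_density,
    move_krill,
    recruit_krill,
    resolve_competition,
    step_season,
    update_predators,
)
from krillmse.management_strategies import initial_controls
from krillmse.parameters_io import PredatorPopulation, ScenarioSpec

from arena import tiny_param


# --- mass trend -------------------------------------------------------------

def test_zero_trend_leaves_mass_unchanged():
    assert apply_mass_trend(np.array([1.0]), np.array([0.0]), 50) == 1.0


def test_linear_trend_direct_evaluation():
    assert apply_mass_trend(np.array([1.0]), np.array([-0.002]), 100) == pytest.approx(0.8)


def test_strong_trend_hits_floor_not_negative():
    out = apply_mass_trend(np.array([1.0]), np.array([-0.02]), 100)
    assert out[0] == pytest.approx(0.01)
    assert out[0] > 0


# --- density ----------------------------------------------------------------

def test_density_arithmetic():
    assert krill_density(np.array([2000.0]), np.array([100.0])) == 20.0
    assert krill_density(np.array([0.0]), np.array([100.0])) == 0.0
    assert krill_density(np.array([1.5e12]), np.array([1e11])) == 15.0


def test_nonpositive_area_is_error():
    with pytest.raises(ValueError):
        krill_density(np.array([1.0]), np.array([0.0]))


# --- recruitment ------------------------------------------------------------

def test_deterministic_recruitment_limit():
    p = tiny_param()
    st = initial_state(p)
    st.krill_biomass[:] = 100.0
    assert recruit_krill(st, p, np.random.default_rng(0)) == pytest.approx([50.0])


def test_zero_rate_gives_zero_recruitment():
    p = tiny_param()
    p.krill_recruit_rate[:] = 0.0
    st = initial_state(p)
    assert recruit_krill(st, p, np.random.default_rng(0))[0] == 0.0


def test_recruitment_deviate_is_median_one_lognormal():
    # median-1 deviates: E[R] = rate*K*exp(sigma^2/2)
    p = tiny_param()
    p.krill_recruit_sigma = 0.5
    st = initial_state(p)
    st.krill_biomass[:] = 100.0
    rng = np.random.default_rng(42)
    draws = np.array([recruit_krill(st, p, rng)[0] for _ in range(100_000)])
    assert draws.mean() == pytest.approx(50.0 * np.exp(0.5 ** 2 / 2), rel=0.01)
    assert np.median(draws) == pytest.approx(50.0, rel=0.01)


def test_rng_draw_consumed_even_when_sigma_zero():
    # paired deterministic/stochastic runs must stay on a common stream
    p = tiny_param()
    r1, r2 = np.random.default_rng(3), np.random.default_rng(3)
    recruit_krill(initial_state(p), p, r1)
    q = p.copy()
    q.krill_recruit_sigma = 0.2
    recruit_krill(initial_state(q), q, r2)
    assert r1.standard_normal() == r2.standard_normal()


# --- movement ---------------------------------------------------------------

def test_identity_movement_is_noop():
    K = np.array([3.0, 7.0])
    assert np.array_equal(move_krill(K, np.eye(2)), K)


def test_hand_matrix_product():
    out = move_krill(np.array([100.0, 0.0]), np.array([[0.5, 0.5], [0.0, 1.0]]))
    assert out == pytest.approx([50.0, 50.0])


def test_movement_conserves_total():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = rng.integers(1, 6)
        M = rng.random((n, n))
        M /= M.sum(axis=1, keepdims=True)
        K = rng.random(n) * 1e9
        assert move_krill(K, M).sum() == pytest.approx(K.sum(), rel=1e-9)


def test_non_stochastic_matrix_rejected():
    with pytest.raises(ValueError):
        move_krill(np.array([1.0, 1.0]), np.array([[0.5, 0.4], [0.0, 1.0]]))


# --- rationing --------------------------------------------------------------

def test_proportional_rationing():
    res = resolve_competition(np.array([100.0]), np.array([80.0]), np.array([40.0]))
    assert res.rationing[0] == pytest.approx(100 / 120)
    assert res.realized_predation[0] == pytest.approx(66.666667)
    assert res.realized_catch[0] == pytest.approx(33.333333)


def test_no_competition_when_demand_below_availability():
    res = resolve_competition(np.array([100.0]), np.array([30.0]), np.array([20.0]))
    assert res.rationing[0] == 1.0
    assert res.realized_predation[0] == 30.0


def test_zero_demand_degenerate():
    res = resolve_competition(np.array([100.0]), np.array([0.0]), np.array([0.0]))
    assert res.rationing[0] == 1.0
    assert res.realized_catch[0] == 0.0


# --- foraging success and breeder response ----------------------------------

def test_foraging_success_examples():
    pp = PredatorPopulation("penguins", "U0", 1.0, (1.0, 1.0),
                            np.array([[0.5, 0.5], [0.2, 0.8]]), (0.9, 0.9), 0.5, 1)
    assert foraging_success(pp, np.array([1.0, 1.0]), 0) == 1.0
    assert foraging_success(pp, np.array([1.0, 0.0]), 0) == 0.5
    assert foraging_success(pp, np.array([0.5, 0.25]), 1) == pytest.approx(0.3)


def test_breeder_response_shapes():
    assert effective_breeder_fraction(0.5, "linear") == 0.5
    assert effective_breeder_fraction(0.5, "hyperstable", 0.2) == pytest.approx(0.5 * 1.2 / 0.7)
    for mode in ("linear", "hyperstable"):
        assert effective_breeder_fraction(0.0, mode, 0.3) == 0.0
        assert effective_breeder_fraction(1.0, mode, 0.3) == 1.0
    x = np.linspace(0.01, 0.99, 50)
    hyper = effective_breeder_fraction(x, "hyperstable", 0.5)
    assert np.all(hyper >= x)  # buffered breeding output
    assert np.all(np.diff(hyper) > 0)
    with pytest.raises(ValueError):
        effective_breeder_fraction(0.5, "hyperstable", 0.0)
    with pytest.raises(ValueError):
        effective_breeder_fraction(0.5, "sigmoid")


# --- predator demography ----------------------------------------------------

def test_equilibrium_population_is_constant():
    p = tiny_param(survival=(1.0, 1.0))
    p.predator_populations[0].max_recruits_per_breeder = 0.0
    st = initial_state(p)
    before = st.predator_adults.copy()
    for _ in range(4):
        update_predators(st, np.array([1.0]), p)
        st.t += 1
    assert np.array_equal(st.predator_adults, before)


def test_geometric_decay_without_recruitment():
    p = tiny_param(survival=(0.9, 0.9))
    p.predator_populations[0].max_recruits_per_breeder = 0.0
    st = initial_state(p)
    st.pending_recruits = [[0.0] * 1]
    update_predators(st, np.array([0.0]), p); st.t += 1
    update_predators(st, np.array([0.0]), p); st.t += 1
    assert st.predator_adults[0] == pytest.approx(100.0 * 0.81)


def test_cohort_matures_exactly_lag_years_later():
    p = tiny_param(survival=(1.0, 1.0), lag=2)
    pp = p.predator_populations[0]
    pp.max_recruits_per_breeder = 0.1  # adults=100, x=1 -> cohort of 10
    st = initial_state(p)
    st.pending_recruits = [[0.0, 0.0]]
    counts = []
    for step in range(6):
        x = np.array([1.0 if step == 0 else 0.0])
        update_predators(st, x, p)
        st.t += 1
        counts.append(st.predator_adults[0])
    # cohort produced at the summer of step 0 matures at step 4 (2 years later)
    assert counts[:4] == [100.0, 100.0, 100.0, 100.0]
    assert counts[4] == pytest.approx(110.0)
    assert counts[5] == pytest.approx(110.0)


def test_stationary_queue_prevents_maturation_transient():
    # a population at its demographic equilibrium should hold exactly steady
    p = tiny_param(survival=(0.9, 0.9), lag=3)
    pp = p.predator_populations[0]
    pp.max_recruits_per_breeder = (1.0 - 0.81) / 0.9  # replacement at x = 1
    st = initial_state(p)
    for step in range(12):
        update_predators(st, np.array([1.0]), p)
        st.t += 1
    assert st.predator_adults[0] == pytest.approx(100.0, rel=1e-12)


# --- full step --------------------------------------------------------------

def test_step_is_deterministic_given_seed():
    p = tiny_param(demand=1e9)
    spec = ScenarioSpec(strategy="none", horizon_years=10, n_trials=1)
    c = initial_controls(p, spec)
    s1, o1 = step_season(initial_state(p), p, c, spec, np.random.default_rng(5))
    s2, o2 = step_season(initial_state(p), p, c, spec, np.random.default_rng(5))
    assert np.array_equal(s1.krill_biomass, s2.krill_biomass)
    assert np.array_equal(o1.realized_catch, o2.realized_catch)


def test_step_does_not_mutate_input_state():
    p = tiny_param()
    spec = ScenarioSpec(strategy="none", horizon_years=10, n_trials=1)
    st = initial_state(p)
    before = st.krill_biomass.copy()
    step_season(st, p, initial_controls(p, spec), spec, np.random.default_rng(0))
    assert np.array_equal(st.krill_biomass, before)
    assert st.t == 0


def test_below_threshold_suspends_fishing_and_flags_violation():
    p = tiny_param(density=30.0)
    spec = ScenarioSpec(strategy="none", horizon_years=10, n_trials=1)
    c = initial_controls(p, spec)
    st = initial_state(p)
    st.krill_biomass[:] = 9.0 * 1e11  # 9 g/m^2 even after 50% summer recruitment
    _, out = step_season(st, p, c, spec, np.random.default_rng(0))
    assert out.violations[0]
    assert out.realized_catch[0] == 0.0
    assert out.allocated_catch[0] > 0.0  # the limit itself is unchanged
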