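import numpy as np
import pytest

from krillmse.management_strategies import (
    allocate_catch_limits,
    apply_strategy,
    fbm_krill_fractions,
    fbm_pengs_fractions,
    initial_controls,
    mpa_fractions,
    penguin_abundance_by_ssmu,
    penguin_ssmu_indices,
    reassessment_times,
    seasonal_split,
)
from krillmse.parameters_io import ScenarioSpec


class FakeHistory:
    def __init__(self, krill, penguins, mass):
        self._k, self._p, self._m = krill, penguins, mass

    def krill_biomass_at(self, t):
        return self._k

    def penguin_adults_at(self, t):
        return self._p

    def mean_mass_at(self, t):
        return self._m


def test_catch_limit_formula():
    out = allocate_catch_limits(1000.0, 0.1, np.array([0.5, 0.5]), np.array([0.5, 1.0]))
    assert out == pytest.approx([100.0, 50.0])
    assert allocate_catch_limits(1000.0, 0.1, np.array([0.0]), np.array([1.0]))[0] == 0.0
    B0, w = 7.3e12, 0.46
    assert allocate_catch_limits(B0, 0.093, np.array([1.0]), np.array([w]))[0] == \
        pytest.approx(0.093 * B0 / w)


def test_catch_limit_rejects_bad_inputs():
    with pytest.raises(ValueError):
        allocate_catch_limits(1.0, 0.1, np.array([0.5]), np.array([0.0]))
    with pytest.raises(ValueError):
        allocate_catch_limits(1.0, 0.1, np.array([0.7, 0.7]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError):
        allocate_catch_limits(1.0, 0.1, np.array([-0.1, 0.5]), np.array([1.0, 1.0]))


def test_density_rule_normalization():
    assert fbm_krill_fractions(np.array([10.0, 30.0, 60.0])) == pytest.approx([0.1, 0.3, 0.6])
    assert fbm_krill_fractions(np.array([5.0])) == pytest.approx([1.0])
    assert fbm_krill_fractions(np.array([0.0, 0.0, 0.0])) is None


def test_penguin_rule_closure_and_shift():
    p, closed = fbm_pengs_fractions(np.array([0.0, 150.0, 150.0]),
                                    np.array([100.0, 100.0, 100.0]), alpha=1.0)
    assert p == pytest.approx([0.0, 0.5, 0.5])
    assert closed == [0]

    p, closed = fbm_pengs_fractions(np.array([110.0, 120.0, 130.0]),
                                    np.array([100.0, 100.0, 100.0]), alpha=1.0)
    assert p == pytest.approx([2 / 9, 1 / 3, 4 / 9])
    assert closed == []  # closure only emerges from a decline

    p, closed = fbm_pengs_fractions(np.array([95.0, 95.0, 95.0]),
                                    np.array([100.0, 100.0, 100.0]), alpha=1.0)
    assert p is None and closed == []


def test_penguin_rule_rejects_insufficient_alpha():
    with pytest.raises(ValueError):
        fbm_pengs_fractions(np.array([90.0, 150.0]), np.array([100.0, 100.0]), alpha=0.5)


def test_penguin_rule_ties_all_closed():
    p, closed = fbm_pengs_fractions(np.array([90.0, 90.0, 150.0]),
                                    np.array([100.0, 100.0, 100.0]), alpha=1.0)
    assert closed == [0, 1]
    assert p[0] == 0.0 and p[1] == 0.0


def test_mpa_renormalization():
    out = mpa_fractions(np.array([0.2, 0.3, 0.5]), np.array([False, False, True]))
    assert out == pytest.approx([0.4, 0.6, 0.0])


def test_mpa_empty_mask_is_bitwise_identity():
    base = np.array([0.2, 0.3, 0.5])
    out = mpa_fractions(base, np.zeros(3, bool))
    assert np.array_equal(out, base)


def test_mpa_displaced_into_zero_base_spreads_uniformly():
    out = mpa_fractions(np.array([1.0, 0.0]), np.array([True, False]))
    assert out == pytest.approx([0.0, 1.0])


def test_mpa_all_masked_is_error():
    with pytest.raises(ValueError):
        mpa_fractions(np.array([0.5, 0.5]), np.array([True, True]))


def test_reassessment_schedule():
    assert reassessment_times(5, 20) == [10, 20, 30]
    assert reassessment_times(5, 4) == []
    with pytest.raises(ValueError):
        reassessment_times(0, 20)


def test_seasonal_split_handles_zero_columns():
    base = np.array([[0.6, 0.0], [0.2, 0.0]])
    out = seasonal_split(base)
    assert out[:, 0] == pytest.approx([0.75, 0.25])
    assert out[:, 1] == pytest.approx([0.5, 0.5])


def test_none_strategy_is_noop(base_param):
    spec = ScenarioSpec(strategy="none", horizon_years=20, n_trials=1)
    c = initial_controls(base_param, spec)
    hist = FakeHistory(base_param.initial_krill_biomass,
                       np.zeros(base_param.n_ssmu), base_param.initial_mean_mass)
    c2, rec = apply_strategy("none", hist, c, base_param, spec, 10)
    assert np.array_equal(c2.fractions, c.fractions)
    assert not rec.degenerate


def test_density_feedback_is_fixed_point_under_constant_density(base_param):
    spec = ScenarioSpec(strategy="fbm_krill", horizon_years=20, n_trials=1)
    c = initial_controls(base_param, spec)
    hist = FakeHistory(base_param.initial_krill_biomass,
                       np.zeros(base_param.n_ssmu), base_param.initial_mean_mass)
    c1, _ = apply_strategy("fbm_krill", hist, c, base_param, spec, 10)
    c2, _ = apply_strategy("fbm_krill", hist, c1, base_param, spec, 20)
    assert c1.fractions == pytest.approx(c2.fractions, rel=1e-12)
    assert c1.fractions.sum() == pytest.approx(1.0)


def test_declining_ssmu_gets_zero_fraction_and_closure(base_param):
    spec = ScenarioSpec(strategy="fbm_pengs", horizon_years=20, n_trials=1)
    c = initial_controls(base_param, spec)
    pg = penguin_ssmu_indices(base_param)
    now = np.zeros(base_param.n_ssmu)
    prev = np.zeros(base_param.n_ssmu)
    now[pg] = 110.0
    prev[pg] = 100.0
    now[pg[0]] = 80.0  # the one declining penguin SSMU

    class H(FakeHistory):
        def penguin_adults_at(self, t):
            return now if t == 10 else prev

    hist = H(base_param.initial_krill_biomass, None, base_param.initial_mean_mass)
    c2, rec = apply_strategy("fbm_pengs", hist, c, base_param, spec, 10)
    i = pg[0]
    assert c2.closed[i]
    assert c2.fractions[:, i] == pytest.approx([0.0, 0.0])
    assert c2.fractions.sum() == pytest.approx(1.0)
    assert base_param.ssmu_map.ssmu_ids[i] in rec.closed_ssmu


def test_initial_controls_apply_mpa_mask(base_param):
    spec = ScenarioSpec(strategy="mpa", horizon_years=20, n_trials=1)
    c = initial_controls(base_param, spec)
    mask = base_param.ssmu_map.mpa_mask
    assert mask.any()
    assert np.all(c.fractions[:, mask] == 0.0)
    assert np.all(c.catch_limits[:, mask] == 0.0)
    assert c.fractions.sum() == pytest.approx(1.0)


def test_penguin_ssmu_bookkeeping(base_param):
    pg = penguin_ssmu_indices(base_param)
    ids = [base_param.ssmu_map.ssmu_ids[i] for i in pg]
    assert ids == [f"SSMU{k:02d}" for k in (2, 3, 4, 5, 6, 7, 8, 10, 11, 12, 14, 15)]
    adults = np.arange(1, len(base_param.predator_populations) + 1, dtype=float)
    by_ssmu = penguin_abundance_by_ssmu(base_param, adults)
    assert by_ssmu.sum() == sum(a for a, pp in zip(adults, base_param.predator_populations)
                                if pp.group == "penguins")
    assert all(by_ssmu[i] > 0 for i in pg)
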