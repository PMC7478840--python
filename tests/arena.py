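"""Hand-built minimal arenas shared across test modules."""

import numpy as np

from krillmse.parameters_io import (
    ModelParameterization,
    PredatorPopulation,
    SSMUMap,
)


def tiny_param(n=1, density=30.0, demand=0.0, survival=(0.9, 0.9), lag=1,
               trend=0.0, availability=1.0):
    """Symmetric arena of ``n`` identical SSMUs with one local fish
    population each; fully deterministic (sigma = 0), no movement."""
    area = np.full(n, 1e11)
    pops = []
    for i in range(n):
        f = np.zeros(n)
        f[i] = 1.0
        pops.append(PredatorPopulation(
            group="fish", resident_ssmu=f"U{i}", initial_adults=100.0,
            per_capita_demand=(demand, demand), foraging_dist=np.vstack([f, f]),
            adult_survival=survival, max_recruits_per_breeder=0.5, recruit_lag=lag))
    return ModelParameterization(
        ssmu_map=SSMUMap(ssmu_ids=[f"U{i}" for i in range(n)], areas=area,
                         subarea=["48.1"] * n, mpa_mask=np.zeros(n, bool)),
        initial_krill_biomass=np.full(n, density * 1e11),
        initial_mean_mass=np.full(n, 0.46),
        mass_trend=np.full(n, trend),
        krill_recruit_rate=np.vstack([np.full(n, 0.5), np.zeros(n)]),
        krill_recruit_sigma=0.0,
        krill_survival=np.full((2, n), 0.9),
        movement_matrices=np.stack([np.eye(n)] * 2),
        movement_mode="none",
        predator_populations=pops,
        breeder_response="linear",
        hyperstable_halfsat=0.5,
        base_catch_fractions=np.full((2, n), 1.0 / (2 * n)),
        krill_availability=availability,
    )
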