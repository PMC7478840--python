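import pytest

from krillmse import (
    GeneratorOptions,
    equilibrate,
    generate_mpa_mask,
    generate_parameterization,
    generate_reference_set,
)


@pytest.fixture(scope="session")
def base_param():
    """Equilibrated default arena with an MPA mask attached.

    Session-scoped: tests must not mutate it (use ``.copy()``).
    """
    p = equilibrate(generate_parameterization(GeneratorOptions(seed=0)))
    p.ssmu_map.mpa_mask = generate_mpa_mask(p, 0.5)
    return p


@pytest.fixture(scope="session")
def reference_set(base_param):
    return generate_reference_set(base_param)
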