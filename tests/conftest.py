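import pytest

from saltmir.simulate import (
    SyntheticConfig,
    generate_libraries,
    generate_reference,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Desk-scale simulation: a few loci, ~8k reads per library."""
    return SyntheticConfig(
        seed=11,
        n_known_mirnas=8,
        n_novel_mirnas=4,
        n_other_loci=6,
        reads_per_library=8000,
        junk_fraction=0.10,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    sim_ref = generate_reference(small_config)
    libs = generate_libraries(small_config, sim_ref)
    return sim_ref, libs
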