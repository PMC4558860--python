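import pytest

from retroscape.synthio import SimulationConfig, simulate_species


@pytest.fixture(scope="session")
def small_sim():
    """A small two-species clade reused across read-only tests."""
    cfg = SimulationConfig(
        seed=101,
        genome_length=1_000_000,
        n_genes=40,
        n_retrocopies_per_branch={"root": 10, "A": 6, "B": 6},
    )
    return simulate_species(cfg)


@pytest.fixture(scope="session")
def expression_sim():
    """A clade with intragenic insertions and chimeras for expression tests."""
    cfg = SimulationConfig(
        seed=202,
        genome_length=1_000_000,
        n_genes=40,
        n_retrocopies_per_branch={"root": 0, "A": 15, "B": 0},
        intragenic_prob=0.5,
        expressed_fraction=0.8,
        chimeric_prob=0.8,
    )
    return simulate_species(cfg)
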