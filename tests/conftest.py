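import numpy as np
import pytest

from flcdnakit.synthetic_data import SimulationConfig, simulate_transcriptome


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20100618)


@pytest.fixture(scope="session")
def small_sim():
    """A mixed-role simulated transcriptome shared across tests."""
    cfg = SimulationConfig(n_genes=30, seed=11, as_fraction=0.3,
                           nat_fraction=0.1, ssr_probability=0.4)
    return simulate_transcriptome(cfg)


@pytest.fixture(scope="session")
def plain_sim():
    """Plain genes only: no AS/NAT/duplication roles, no planted SSRs."""
    cfg = SimulationConfig(n_genes=40, seed=7, as_fraction=0.0,
                           nat_fraction=0.0, ssr_probability=0.0)
    return simulate_transcriptome(cfg)
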