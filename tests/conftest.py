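import numpy as np
import pytest

import plastmine as pm


@pytest.fixture(scope="session")
def default_sim() -> pm.Simulation:
    """The default stated world: six ~33 kb genotypes, 141 SNPs (Ts:Tv
    88:53), 30 SSR tracts (20 polymorphic), 44 indels, 5 inversions."""
    return pm.simulate(pm.SimulationParams(seed=1))


@pytest.fixture(scope="session")
def default_report(default_sim) -> pm.MarkerReport:
    return pm.analyze(
        default_sim.genotypes,
        default_sim.alignment,
        reference="g01",
        features=default_sim.features,
    )


@pytest.fixture(scope="session")
def tiny_sim() -> pm.Simulation:
    """A small, fast world for structural tests (5 kb, light budget)."""
    return pm.simulate(
        pm.SimulationParams(
            lsc_len=3000, ir_len=500, ssc_len=1000,
            n_genotypes=3, n_snps=10, n_ssr_tracts=3, n_ssr_polymorphic=2,
            n_indels=4, n_inversions=1, seed=11,
        )
    )


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
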