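import numpy as np
import pytest

from gepred.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_population():
    """One shared desk-scale population: 600 birds, 5 generations."""
    cfg = SimConfig(n_individuals=600, n_markers=150, n_generations=5,
                    n_dams=30, missing_rate=0.02, seed=2024)
    G, ped, phen, truth = simulate_dataset(cfg)
    return {"config": cfg, "G": G, "pedigree": ped, "phenotypes": phen,
            "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
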