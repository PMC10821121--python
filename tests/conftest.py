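import numpy as np
import pandas as pd
import pytest

from fmt_engraft import AsvTable, SimulationConfig, Triad, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spec_triad():
    """Handcrafted triad with D={a,b,c,d}, P={a,e}, Q={a,b,e,f}.

    Post counts (4, 3, 2, 1) over (a, b, e, f) give relative abundances
    0.4 / 0.3 / 0.2 / 0.1 for the four provenance classes.
    """
    data = pd.DataFrame(
        {
            "a": [10, 5, 4],
            "b": [10, 0, 3],
            "c": [10, 0, 0],
            "d": [10, 0, 0],
            "e": [0, 5, 2],
            "f": [0, 0, 1],
        },
        index=["donor_s", "pre_s", "post_s"],
    )
    table = AsvTable(data)
    triad = Triad(
        recipient_id="dog1",
        donor_sample="donor_s",
        pre_sample="pre_s",
        post_sample="post_s",
    )
    return triad, table


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across tests."""
    config = SimulationConfig(
        n_triads=8,
        n_donors=3,
        donor_richness=(30, 60),
        recipient_richness=(30, 60),
        depth=(26000, 40000),
        pool_size=250,
        seed=42,
    )
    return simulate_cohort(config)


def random_count_table(rng, n_samples, n_asvs, max_count=50, density=0.7):
    """Random integer AsvTable for property tests."""
    counts = rng.integers(0, max_count + 1, size=(n_samples, n_asvs))
    mask = rng.random((n_samples, n_asvs)) < density
    counts = counts * mask
    counts[:, 0] += 1  # no all-zero samples
    return AsvTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"asv{j}" for j in range(n_asvs)],
        )
    )
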