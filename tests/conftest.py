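import numpy as np
import pytest

from introscan import PopulationMap, ScenarioConfig, VariantTable, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_table():
    """Two populations of 3 diploids, 6 hand-written sites on one scaffold."""
    genotypes = np.array(
        [
            # sites:  1    2    3    4    5    6
            [2, 1, 0, 2, 0, 1],   # a1
            [2, 0, 0, 2, 0, 1],   # a2
            [2, 1, 0, 2, -1, 0],  # a3
            [0, 1, 0, 2, 1, 2],   # b1
            [0, 2, 0, 2, 1, 2],   # b2
            [0, 1, 0, 2, 2, 1],   # b3
        ],
        dtype=np.int8,
    )
    return VariantTable(
        scaffold="scf1",
        positions=np.array([100, 250, 400, 550, 700, 850]),
        ref=np.array(list("ACGTAC")),
        alt=np.array(list("TGCAGA")),
        genotypes=genotypes,
        sample_ids=["a1", "a2", "a3", "b1", "b2", "b3"],
    )


@pytest.fixture
def small_popmap():
    return PopulationMap(
        [("a1", "A"), ("a2", "A"), ("a3", "A"), ("b1", "B"), ("b2", "B"), ("b3", "B")]
    )


@pytest.fixture(scope="session")
def planted_study():
    """A small four-population study with 20 planted swept-introgression windows."""
    scenario = ScenarioConfig(
        n_scaffolds=8,
        windows_per_scaffold=10,
        n_introgressed_swept=20,
        seed=421,
    )
    tables, popmap, truth, index = simulate_study(scenario)
    return scenario, tables, popmap, truth, index


def random_variant_table(rng, n_samples=6, max_sites=40, missing_rate=0.05,
                         scaffold="scf1"):
    """Random VariantTable for oracle comparisons (helper, not a fixture)."""
    n_sites = int(rng.integers(5, max_sites + 1))
    positions = np.sort(rng.choice(10_000, size=n_sites, replace=False)) + 1
    genotypes = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    mask = rng.random(genotypes.shape) < missing_rate
    genotypes = np.where(mask, np.int8(-1), genotypes)
    return VariantTable(
        scaffold=scaffold,
        positions=positions,
        ref=np.full(n_sites, "A"),
        alt=np.full(n_sites, "T"),
        genotypes=genotypes,
        sample_ids=[f"s{i}" for i in range(n_samples)],
    )
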