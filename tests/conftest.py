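import numpy as np
import pytest

from nestkin.genotypes import GenotypeTable, LocusPanel
from nestkin.simulate import SimulationConfig, observe, simulate_breeding_seasons


@pytest.fixture
def rng():
    return np.random.default_rng(20120520)


@pytest.fixture
def two_allele_panel():
    """Single biallelic locus at p = q = 0.5."""
    return LocusPanel(["L01"], [{1: 0.5, 2: 0.5}])


@pytest.fixture
def small_panel():
    """Four loci with uneven frequency spectra."""
    return LocusPanel(
        ["L01", "L02", "L03", "L04"],
        [
            {1: 0.5, 2: 0.5},
            {1: 0.25, 2: 0.25, 3: 0.25, 4: 0.25},
            {1: 0.7, 2: 0.2, 3: 0.1},
            {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1},
        ],
    )


def draw_table(panel: LocusPanel, n: int, rng, prefix="ind") -> GenotypeTable:
    """n Hardy-Weinberg genotypes from a panel."""
    alleles = np.zeros((n, panel.n_loci, 2), dtype=np.int64)
    for j, (labels, p) in enumerate(panel.freq_arrays()):
        alleles[:, j, :] = rng.choice(labels, size=(n, 2), p=p)
    return GenotypeTable([f"{prefix}{i}" for i in range(n)], panel.loci, alleles)


@pytest.fixture(scope="session")
def small_study():
    """A 2-year, 40-nest simulated study shared across tests."""
    cfg = SimulationConfig(nests_per_year=40, n_years=2, rng_seed=99)
    pop = simulate_breeding_seasons(cfg)
    obs = observe(pop, cfg)
    return cfg, pop, obs
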