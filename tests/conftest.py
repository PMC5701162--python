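import numpy as np
import pytest

from eruptpop.genio import GenotypeMatrix
from eruptpop.simgen import (
    Cohort,
    SamplingPlan,
    SimulationConfig,
    draw_samples,
    emulate_study,
    simulate_populations,
)


def make_matrix(dosages, sample_ids=None, regions=None, positions=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain dosage array with synthetic coordinates."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    return GenotypeMatrix(
        dosages=d,
        sample_ids=sample_ids or [f"s{i:02d}" for i in range(n)],
        site_regions=np.asarray(regions if regions is not None else [f"r{j:04d}" for j in range(m)], dtype=object),
        site_positions=np.asarray(positions if positions is not None else np.ones(m, dtype=int)),
    )


def ts_to_matrix(ts) -> GenotypeMatrix:
    """Diploid dosage matrix from a tskit tree sequence (haplotypes paired in order)."""
    g = ts.genotype_matrix()  # sites x haplotypes
    dos = (g[:, 0::2] + g[:, 1::2]).T.astype(np.int8)
    pos = np.asarray([int(s.position) + 1 for s in ts.sites()])
    # collapse coordinate collisions from discretisation
    pos = pos + np.arange(len(pos))  # strictly increasing, order preserved
    return make_matrix(dos, regions=["chr"] * dos.shape[1], positions=pos)


@pytest.fixture(scope="session")
def species_b_dataset():
    """One emulated solitary-species dataset shared across tests."""
    return emulate_study("speciesB", seed=11)


@pytest.fixture(scope="session")
def species_a_dataset():
    return emulate_study("speciesA", seed=7)


@pytest.fixture(scope="session")
def two_pop_dataset():
    """Two weakly differentiated demes, neutral, for structure/scan tests."""
    cfg = SimulationConfig(
        n_loci=400, ne_pre=200, event_generation=4, generations_post=0,
        migration_rate=0.2, n_demes=2, initial_freq_spec="uniform", seed=99,
    )
    history = simulate_populations(cfg)
    plan = SamplingPlan(
        cohorts=(Cohort(0, 4, 20, 20, "P1", "pre"), Cohort(1, 4, 20, 20, "P2", "pre"))
    )
    return draw_samples(history, plan, seed=100)
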