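import numpy as np
import pytest

from demekin.genio import SiteFrequencies
from demekin.simulate import (
    SimConfig,
    simulate_cohort,
    simulate_genotype_likelihoods,
)


def make_sitefreqs(freq: np.ndarray) -> SiteFrequencies:
    """SiteFrequencies from known true frequencies (all sites defined)."""
    freq = np.asarray(freq, dtype=float)
    return SiteFrequencies(
        freq=freq,
        polymorphic=(freq > 0) & (freq < 1),
        defined=np.ones_like(freq, dtype=bool),
    )


def onehot(genos: np.ndarray) -> np.ndarray:
    """(M, 3) one-hot likelihoods from a dosage vector."""
    g = np.asarray(genos, dtype=int).ravel()
    gl = np.zeros((g.size, 3))
    gl[np.arange(g.size), g] = 1.0
    return gl


@pytest.fixture(scope="session")
def small_cohort():
    """Three demes, two generations, modest divergence; shared across tests."""
    cfg = SimConfig(
        seed=11,
        deme_sizes=[8, 8, 8],
        n_generations=2,
        n_sites=400,
        divergence_fst=0.15,
        migration_rate=0.05,
    )
    pedigree, true_g, aln, truth = simulate_cohort(cfg)
    gl = simulate_genotype_likelihoods(true_g, cfg)
    return cfg, pedigree, true_g, aln, truth, gl
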