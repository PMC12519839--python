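import random

import dendropy
import dendropy.simulate
import numpy as np
import pytest

import mungomhc as m


@pytest.fixture(scope="session")
def noise_free_study():
    """Complete synthetic study without artefacts: genotypes must be
    recoverable exactly."""
    cfg = m.SimConfig(seed=11, n_alleles=20, n_individuals=60,
                      error_rate=0.0, artefact_fraction=0.0,
                      pseudo_fraction=0.15, nonclassical_fraction=0.1)
    fasta, truth = m.simulate_allele_pool(cfg)
    gm = m.simulate_population_genotypes(truth, cfg)
    table = m.simulate_amplicon_run(truth, cfg)
    return cfg, truth, gm, table


@pytest.fixture(scope="session")
def noisy_study():
    """Synthetic study with PCR/sequencing artefacts on 30% of alleles."""
    cfg = m.SimConfig(seed=13, n_alleles=20, n_individuals=80,
                      artefact_fraction=0.3,
                      pseudo_fraction=0.15, nonclassical_fraction=0.1)
    fasta, truth = m.simulate_allele_pool(cfg)
    gm = m.simulate_population_genotypes(truth, cfg)
    table = m.simulate_amplicon_run(truth, cfg)
    return cfg, truth, gm, table


@pytest.fixture()
def separable_clusters():
    """Well-separated point clouds in z-descriptor space."""
    def make(k, n_per=6, dim=10, seed=0, noise=1.0):
        rng = np.random.default_rng(seed)
        # rejection-sample centers so clusters are genuinely separable
        while True:
            centers = rng.normal(0, 10, size=(k, dim))
            dists = [np.linalg.norm(a - b)
                     for i, a in enumerate(centers)
                     for b in centers[i + 1:]]
            if not dists or min(dists) >= 15 * noise:
                break
        X = np.vstack([c + noise * rng.standard_normal((n_per, dim))
                       for c in centers])
        labels = np.repeat(np.arange(k), n_per)
        return X, labels
    return make


@pytest.fixture()
def birth_death_tree():
    def make(n_tips=39, seed=1):
        tns = dendropy.TaxonNamespace([f"sp{i:02d}" for i in range(n_tips)])
        return dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
            taxon_namespace=tns, rng=random.Random(seed))
    return make
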