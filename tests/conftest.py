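"""Shared fixtures: small synthetic populations built once per session."""

import numpy as np
import pytest

import clonalmate as cm
from clonalmate.pipeline import ExperimentConfig, generate_training_population
from clonalmate.synthetic import subset_map


@pytest.fixture(scope="session")
def small_map():
    return cm.generate_map(3, 60, 1.5, seed=11)


@pytest.fixture(scope="session")
def small_founders(small_map):
    """80 unrelated clones x ~180 markers (marker-wise sampling)."""
    founders = cm.generate_founders(80, small_map, seed=12)
    gmap = subset_map(small_map, founders.marker_id)
    return founders, gmap


@pytest.fixture(scope="session")
def related_pop():
    """200 clones from one round of random mating of 16 ancestors.

    The relatedness (full-/half-sib network) is what gives the
    relationship matrices usable off-diagonal structure.
    """
    cfg = ExperimentConfig(n_training_clones=200, n_ancestors=16,
                           founder_family_size=4, n_chromosomes=5,
                           markers_per_chromosome=120, seed=21)
    pop, gmap = generate_training_population(cfg, 211, 212, 213)
    return pop, gmap


@pytest.fixture(scope="session")
def related_grms(related_pop):
    pop, _ = related_pop
    freqs = cm.allele_frequencies(pop)
    return cm.GRMSet.from_genotypes(pop, freqs)


@pytest.fixture(scope="session")
def related_het(related_pop, related_grms):
    pop, _ = related_pop
    return cm.genomewide_heterozygosity(pop, related_grms.frequencies)


@pytest.fixture(scope="session")
def mvn_fit_pair(related_pop, related_grms, related_het):
    """Phenotypes drawn from the exact 3-GRM model plus both fits."""
    pop, _ = related_pop
    g = related_grms
    het = related_het
    y = cm.mvn_phenotypes([g.g_additive, g.g_dominance, g.g_epistatic],
                          (15.82, 3.08, 22.94, 46.10), het, 92.84, seed=77)
    vc1, fit1 = cm.fit_reml(y, None, [g.g_additive])
    x = np.column_stack([np.ones(len(y)), het - het.mean()])
    vc3, fit3 = cm.fit_reml(y, x, [g.g_additive, g.g_dominance,
                                   g.g_epistatic])
    return {"y": y, "gblup": (vc1, fit1), "egblup": (vc3, fit3)}


@pytest.fixture(scope="session")
def balanced_p_half_pop():
    """56 clones whose markers all have allele frequency exactly 1/2.

    Each marker column is a permutation of 14 x code0, 28 x code1,
    14 x code2 — exact Hardy-Weinberg counts at p = 0.5, where the
    additive and dominance marker encodings are exactly orthogonal and
    the cross-product and unbiased GRM diagonals coincide.
    """
    rng = np.random.default_rng(31)
    n, m = 56, 40
    base = np.repeat(np.array([0, 1, 2], dtype=np.int8), (14, 28, 14))
    codes = np.column_stack([rng.permutation(base) for _ in range(m)])
    return cm.GenotypeMatrix(clone_id=[f"c{i}" for i in range(n)],
                             marker_id=np.array([f"m{j}" for j in range(m)]),
                             codes=codes)
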