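"""Shared fixtures: a simulated phage population and its pham assignment.

The scenario population (two clusters plus a focal phage plus HGT
satellites) is expensive enough that it is built once per session and
shared by the clustering, HGT, phylogeny and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from phamflock import assign_phams, bluefeather_preset, membership_profile, simulate_population
from phamflock.synthetic_data import SimulationParams

SESSION_SEED = 11


@pytest.fixture(scope="session")
def bf_population():
    """Default-scenario population: (genomes, metadata, truth)."""
    return simulate_population(bluefeather_preset(seed=SESSION_SEED))


@pytest.fixture(scope="session")
def bf_assignment(bf_population):
    genomes, _, _ = bf_population
    proteins = {
        (g.name, gene.gene_number): gene.protein_seq for g in genomes for gene in g.genes
    }
    return assign_phams(proteins)


@pytest.fixture(scope="session")
def bf_profiles(bf_population, bf_assignment):
    genomes, _, _ = bf_population
    return {g.name: membership_profile(bf_assignment, g.name) for g in genomes}


def tiny_params(seed: int = 3, **overrides) -> SimulationParams:
    """A small, fast population: two 2-phage clusters, 8 genes each."""
    defaults = dict(
        seed=seed,
        n_clusters=2,
        phages_per_cluster=(2, 2),
        genes_per_genome=(8, 8),
        pham_universe_size=120,
        core_fraction=0.4,
        cross_cluster_share=0.3,
        cross_cluster_extra={},
        orphams_per_genome=1,
        within_pham_aa_divergence=0.01,
        synonymous_scramble_rate=1.0,
        hgt_implants=[],
        protein_length_range=(80, 140),
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


def random_protein(rng: np.random.Generator, length: int) -> str:
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[int(i)] for i in rng.integers(len(aa), size=length))
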