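"""The population generator: determinism, codon scrambling, ground truth."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phamflock.io_formats import read_annotated_genome, read_genome_fasta, read_metadata_table
from phamflock.pham_assignment import pairwise_protein_identity
from phamflock.synthetic_data import (
    SimulationParams,
    codon_scramble,
    read_truth,
    simulate_population,
    translate_cds,
    write_population,
    write_truth,
)

from .conftest import random_protein, tiny_params

proteins = st.integers(0, 2**31 - 1).map(
    lambda s: random_protein(np.random.default_rng(s), 30 + s % 100)
)


class TestCodonScramble:
    @given(proteins, st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_translation_inverts_scramble(self, protein, seed):
        cds = codon_scramble(protein, 55.0, seed)
        assert translate_cds(cds) == protein
        assert len(cds) == 3 * (len(protein) + 1)  # stop codon appended

    def test_different_seeds_different_nucleotides_same_protein(self):
        protein = random_protein(np.random.default_rng(0), 200)
        a = codon_scramble(protein, 55.0, 1)
        b = codon_scramble(protein, 55.0, 2)
        assert a != b
        assert translate_cds(a) == translate_cds(b) == protein
        # nucleotide identity drops toward the synonymous baseline while
        # protein identity stays exact
        same = sum(1 for x, y in zip(a, b) if x == y) / len(a)
        assert same < 0.95
        assert pairwise_protein_identity(translate_cds(a), translate_cds(b))[0] == 100.0

    def test_gc_target_shifts_realized_gc(self):
        protein = random_protein(np.random.default_rng(3), 300)
        with pytest.warns(UserWarning, match="unreachable"):
            high = codon_scramble(protein, 70.0, 5)
        low = codon_scramble(protein, 55.0, 5)
        gc = lambda s: 100 * sum(c in "GC" for c in s) / len(s)
        assert gc(high) - gc(low) > 5.0

    @pytest.mark.parametrize("target", [45.0, 52.0, 58.0])
    def test_realized_gc_within_two_points_of_target(self, target):
        rng = np.random.default_rng(7)
        gc = lambda s: 100 * sum(c in "GC" for c in s) / len(s)
        for seed in range(20):
            protein = random_protein(rng, 220)
            realized = gc(codon_scramble(protein, target, seed))
            assert abs(realized - target) <= 2.0

    def test_unreachable_target_warns_and_clamps(self):
        with pytest.warns(UserWarning, match="achievable range"):
            cds = codon_scramble("MKKKKKKKKK", 95.0, 0)
        assert translate_cds(cds) == "MKKKKKKKKK"

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            codon_scramble("", 50.0, 0)


class TestSimulatePopulation:
    def test_fixed_seed_byte_identical(self):
        a_genomes, a_meta, a_truth = simulate_population(tiny_params(seed=41))
        b_genomes, b_meta, b_truth = simulate_population(tiny_params(seed=41))
        assert [(g.name, g.sequence) for g in a_genomes] == [
            (g.name, g.sequence) for g in b_genomes
        ]
        assert [g.genes for g in a_genomes] == [g.genes for g in b_genomes]
        assert a_meta.rows == b_meta.rows
        assert a_truth.pham_of == b_truth.pham_of

    def test_different_seeds_differ(self):
        a, _, _ = simulate_population(tiny_params(seed=41))
        b, _, _ = simulate_population(tiny_params(seed=42))
        assert a[0].sequence != b[0].sequence

    def test_every_gene_translates_to_its_protein(self):
        genomes, _, _ = simulate_population(tiny_params(seed=43))
        for genome in genomes:
            for gene in genome.genes:
                assert translate_cds(gene.nucleotide_seq) == gene.protein_seq

    def test_orpham_count_matches_parameters(self):
        params = tiny_params(seed=45)
        genomes, _, truth = simulate_population(params)
        orphams = truth.orpham_phams()
        for genome in genomes:
            own = {
                truth.pham_of[(genome.name, g.gene_number)] for g in genome.genes
            } & orphams
            assert len(own) >= params.orphams_per_genome

    def test_zero_divergence_zero_scramble_shares_nucleotides_within_cluster(self):
        params = tiny_params(
            seed=47, within_pham_aa_divergence=0.0, synonymous_scramble_rate=0.0
        )
        genomes, _, truth = simulate_population(params)
        by_cluster: dict[str, list] = {}
        for g in genomes:
            by_cluster.setdefault(truth.cluster_of[g.name], []).append(g)
        for members in by_cluster.values():
            if len(members) < 2:
                continue
            a, b = members[0], members[1]
            shared = truth.profile_of(a.name) & truth.profile_of(b.name)
            nt_a = {
                truth.pham_of[(a.name, g.gene_number)]: g.nucleotide_seq
                for g in a.genes
            }
            nt_b = {
                truth.pham_of[(b.name, g.gene_number)]: g.nucleotide_seq
                for g in b.genes
            }
            for pham in shared:
                assert nt_a[pham] == nt_b[pham]

    def test_scramble_rate_one_erases_cross_cluster_nucleotide_identity(self):
        params = tiny_params(seed=49, within_pham_aa_divergence=0.0)
        genomes, _, truth = simulate_population(params)
        clusters = sorted({truth.cluster_of[g.name] for g in genomes})
        a = next(g for g in genomes if truth.cluster_of[g.name] == clusters[0])
        b = next(g for g in genomes if truth.cluster_of[g.name] == clusters[1])
        shared = truth.profile_of(a.name) & truth.profile_of(b.name)
        assert shared  # construction sanity
        nt_a = {truth.pham_of[(a.name, g.gene_number)]: g.nucleotide_seq for g in a.genes}
        aa_a = {truth.pham_of[(a.name, g.gene_number)]: g.protein_seq for g in a.genes}
        nt_b = {truth.pham_of[(b.name, g.gene_number)]: g.nucleotide_seq for g in b.genes}
        aa_b = {truth.pham_of[(b.name, g.gene_number)]: g.protein_seq for g in b.genes}
        for pham in shared:
            assert aa_a[pham] == aa_b[pham]  # protein conserved exactly
            same = sum(x == y for x, y in zip(nt_a[pham], nt_b[pham])) / len(nt_a[pham])
            assert same < 0.9  # nucleotide realization re-drawn

    def test_genome_lengths_in_realistic_range(self, bf_population):
        genomes, _, truth = bf_population
        for g in genomes:
            if truth.cluster_of[g.name].startswith("T"):
                assert 12_000 <= len(g.sequence) <= 25_000

    def test_infeasible_sharing_rejected(self):
        with pytest.raises(ValueError, match="sharing structure needs"):
            simulate_population(
                tiny_params(seed=51, core_fraction=0.9, cross_cluster_share=0.9)
            )

    def test_exhausted_universe_rejected(self):
        with pytest.raises(ValueError, match="universe exhausted"):
            simulate_population(tiny_params(seed=53, pham_universe_size=5))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            simulate_population(tiny_params(seed=55, core_fraction=1.5))


class TestTruthSerialization:
    def test_truth_round_trip(self, tmp_path):
        _, _, truth = simulate_population(tiny_params(seed=57))
        write_truth(truth, tmp_path)
        back = read_truth(tmp_path, focal_phage=truth.focal_phage)
        assert back.pham_of == truth.pham_of
        assert back.cluster_of == truth.cluster_of
        assert back.hgt_genes == truth.hgt_genes
        assert back.gene_gc_target == truth.gene_gc_target

    def test_population_files_loadable_by_io_formats(self, tmp_path):
        genomes, metadata, truth = simulate_population(tiny_params(seed=59))
        paths = write_population(genomes, metadata, truth, tmp_path)
        sequences = dict(read_genome_fasta(paths["genomes"]))
        assert sequences == {g.name: g.sequence for g in genomes}
        table = read_metadata_table(paths["metadata"])
        assert table.rows == metadata.rows
        for genome in genomes:
            back = read_annotated_genome(
                paths["genes"], paths["genomes"], name=genome.name
            )
            assert back.genes == genome.genes
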