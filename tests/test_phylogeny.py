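"""Neighbor joining on GCD distances and NEXUS distance export."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from phamflock.gene_content_stats import gcs
from phamflock.phylogeny import (
    DistanceMatrix,
    export_nexus_distances,
    gcd_distance_matrix,
    neighbor_joining,
    parse_nexus_distances,
    sanitize_label,
    subsample_representatives,
)


def random_additive_matrix(rng: np.random.Generator, n: int):
    """Distances induced by a random binary tree with positive branches.

    Built by successively attaching leaves to random edges, tracking the
    full path-length matrix directly, so the oracle is independent of any
    tree data structure.
    """
    names = [f"t{i}" for i in range(n)]
    D = np.zeros((n, n))
    D[0, 1] = D[1, 0] = rng.uniform(0.2, 1.0)
    for k in range(2, n):
        # attach leaf k by a stem of its own to a point on the path
        # between two existing leaves i and j, at distance `along` from i
        i, j = rng.choice(k, size=2, replace=False)
        along = rng.uniform(0.25, 0.75) * D[i, j]
        stem = rng.uniform(0.1, 0.8)
        for m in range(k):
            # distance from i to where the path to m leaves path(i, j)
            join = 0.5 * (D[i, m] - D[j, m] + D[i, j])
            D[k, m] = D[m, k] = stem + abs(along - join) + (D[i, m] - join)
    return DistanceMatrix(names, D)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # hand-built additive matrix from tree ((A:1,B:2):3,(C:4,D:5))
        D = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
        )
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], D))
        parsed = dendropy.Tree.get(data=tree.newick, schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {leaf.taxon.label: leaf.taxon for leaf in parsed.leaf_node_iter()}
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        D[i, j], abs=1e-9
                    )

    @pytest.mark.parametrize("seed,n", [(0, 5), (1, 6), (2, 8)])
    def test_random_additive_matrices_recovered(self, seed, n):
        matrix = random_additive_matrix(np.random.default_rng(seed), n)
        tree = neighbor_joining(matrix)
        parsed = dendropy.Tree.get(data=tree.newick, schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {leaf.taxon.label: leaf.taxon for leaf in parsed.leaf_node_iter()}
        for i, a in enumerate(matrix.taxa):
            for j, b in enumerate(matrix.taxa):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        matrix.values[i, j], abs=1e-9
                    )

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], D))
        # a = (ab+ac-bc)/2 = 0.1, b = 0.3, c = 0.5
        assert tree.newick == "(A:0.1,B:0.3,C:0.5);"

    def test_equal_distances_deterministic(self):
        D = np.full((4, 4), 0.5)
        np.fill_diagonal(D, 0.0)
        m = DistanceMatrix(["A", "B", "C", "D"], D)
        assert neighbor_joining(m).newick == neighbor_joining(m).newick
        # smallest-name pair joined first
        assert neighbor_joining(m).newick.startswith("((A")

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))

    def test_leaf_set_and_total_length(self):
        D = np.array([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C", "D"], D))
        parsed = dendropy.Tree.get(data=tree.newick, schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == {"A", "B", "C", "D"}
        assert tree.total_length() == pytest.approx(parsed.length(), abs=1e-9)


class TestGcdDistanceMatrix:
    def test_identical_phages_at_distance_zero(self):
        m = gcd_distance_matrix({"A": {"P1"}, "B": {"P1"}, "C": {"P1"}})
        assert np.allclose(m.values[np.triu_indices(3, 1)], 0.0)

    def test_disjoint_phages_at_distance_one(self):
        m = gcd_distance_matrix({"A": {"P1"}, "B": {"P2"}, "C": {"P3"}})
        assert np.allclose(m.values[np.triu_indices(3, 1)], 1.0)

    def test_matches_gcs_complement(self, bf_profiles):
        m = gcd_distance_matrix(bf_profiles)
        for i, a in enumerate(m.taxa):
            for j, b in enumerate(m.taxa):
                if i < j:
                    expected = 1 - gcs(bf_profiles[a], bf_profiles[b]) / 100
                    assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_community_closer_than_outgroups(self, bf_population, bf_profiles):
        # the six community phages are mutually closer than any of them is
        # to a satellite outgroup
        _, _, truth = bf_population
        m = gcd_distance_matrix(bf_profiles)
        main = sorted(p for p, c in truth.cluster_of.items() if c.startswith("T"))
        outgroup = sorted(p for p, c in truth.cluster_of.items() if c.startswith("SAT"))
        intra = max(m.value(a, b) for a in main for b in main if a != b)
        cross = min(m.value(a, s) for a in main for s in outgroup)
        assert intra < cross


class TestNexusExport:
    def _matrix(self):
        D = np.array([[0, 0.2, 0.5], [0.2, 0, 0.6], [0.5, 0.6, 0]])
        return DistanceMatrix(["A", "B", "C"], D)

    def test_structure(self):
        text = export_nexus_distances(self._matrix())
        assert text.startswith("#NEXUS")
        assert "NTAX=3" in text
        matrix_lines = [
            l for l in text.splitlines() if l.strip().startswith(("A ", "B ", "C "))
        ]
        assert len(matrix_lines) == 3
        assert len(matrix_lines[0].split()) == 2  # label + diagonal
        assert len(matrix_lines[2].split()) == 4  # full lower row

    def test_round_trip(self):
        matrix = self._matrix()
        back = parse_nexus_distances(export_nexus_distances(matrix))
        assert back.taxa == matrix.taxa
        assert np.allclose(back.values, matrix.values, atol=1e-12)

    def test_labels_sanitized_deterministically(self):
        assert sanitize_label("Blue Feather-1") == "Blue_Feather_1"
        D = np.array([[0, 0.1], [0.1, 0]])
        with pytest.raises(ValueError, match="collide"):
            export_nexus_distances(DistanceMatrix(["a b", "a-b"], D))

    def test_loadable_by_dendropy(self):
        text = export_nexus_distances(self._matrix())
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_as_csv(self._matrix()), delimiter=","
        )
        # independent readback of the same values through a second format
        assert pdm.distance(*_taxa(pdm, "A", "B")) == pytest.approx(0.2)
        assert "TRIANGLE=LOWER" in text


def _as_csv(matrix):
    import io

    rows = [","] + []
    header = "," + ",".join(matrix.taxa)
    lines = [header]
    for i, t in enumerate(matrix.taxa):
        lines.append(t + "," + ",".join(str(v) for v in matrix.values[i]))
    return io.StringIO("\n".join(lines))


def _taxa(pdm, a, b):
    taxa = {t.label: t for t in pdm.taxon_namespace}
    return taxa[a], taxa[b]


class TestSubsampling:
    def test_lexicographic_representatives(self):
        members = {"C1": ["z", "a", "m", "b"], "C2": ["q"]}
        assert subsample_representatives(members, max_per_cluster=2) == ["a", "b", "q"]

    def test_invalid_cap_rejected(self):
        with pytest.raises(ValueError):
            subsample_representatives({"C1": ["a"]}, max_per_cluster=0)
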