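"""Pham assignment: grouping phage proteins into amino-acid-similarity families.

A *pham* is a family of phage genes related at the amino-acid level; it is
the unit on which all gene-content statistics downstream are computed.
Assignment is single linkage: every pair of proteins whose global alignment
meets both an identity and a coverage threshold contributes an edge, and
phams are the connected components of that similarity graph.  A pham whose
members all come from one phage is an *orpham*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
from Bio import Align
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "AlignmentScoring",
    "SimilarityEdge",
    "PhamAssignment",
    "PhamClusterer",
    "pairwise_protein_identity",
    "assign_phams",
    "membership_profile",
]

GeneId = tuple[str, int]  # (phage_name, gene_number)


@dataclass(frozen=True)
class AlignmentScoring:
    """Global-alignment parameters with free terminal gaps.

    Defaults favour contiguous alignment of homologous proteins while
    letting unrelated termini hang off for free; identity is computed over
    the columns between the first and last position at which both
    sequences are present (terminal-gap columns excluded).
    """

    match: float = 1.0
    mismatch: float = 0.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


@dataclass(frozen=True)
class SimilarityEdge:
    """An undirected similarity edge between two genes (stored once)."""

    gene_a: GeneId
    gene_b: GeneId
    identity: float
    coverage: float


@dataclass
class PhamAssignment:
    """A partition of genes into phams, plus the graph it came from.

    Pham identifiers are canonical: components are sorted by their
    lexicographically smallest member and numbered PH0001, PH0002, ... so
    the labelling is invariant under permutation of the input genes.
    """

    pham_of: dict[GeneId, str]
    phams: dict[str, set[GeneId]]
    edges: list[SimilarityEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        covered = set()
        for pham_id, members in self.phams.items():
            for g in members:
                if g in covered:
                    raise ValueError(f"gene {g} appears in more than one pham")
                covered.add(g)
                if self.pham_of.get(g) != pham_id:
                    raise ValueError(f"gene {g} map/pham inconsistency")
        if covered != set(self.pham_of):
            raise ValueError("pham_of and phams cover different gene sets")

    def is_orpham(self, pham_id: str) -> bool:
        phages = {phage for phage, _ in self.phams[pham_id]}
        return len(phages) == 1

    @property
    def orphams(self) -> set[str]:
        return {p for p in self.phams if self.is_orpham(p)}

    @property
    def phage_names(self) -> list[str]:
        return sorted({phage for phage, _ in self.pham_of})

    def to_table_rows(self) -> list[tuple[str, str, int, int]]:
        """Rows (pham_id, phage_name, gene_number, orpham 0/1) for TSV export."""
        rows = []
        for pham_id in sorted(self.phams):
            flag = int(self.is_orpham(pham_id))
            for phage, num in sorted(self.phams[pham_id]):
                rows.append((pham_id, phage, num, flag))
        return rows


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=scoring.match,
        mismatch_score=scoring.mismatch,
        open_gap_score=scoring.gap_open,
        extend_gap_score=scoring.gap_extend,
    )
    # terminal gaps are free; attribute name changed across Biopython releases
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            aligner.end_gap_score = 0.0
        except AttributeError:
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def pairwise_protein_identity(
    protein_a: str,
    protein_b: str,
    scoring: AlignmentScoring | None = None,
    _aligner: Align.PairwiseAligner | None = None,
) -> tuple[float, float]:
    """Percent identity and coverage of the best global alignment.

    identity  = identical columns / alignment columns, terminal-gap columns
                excluded, x100
    coverage  = residues of the shorter sequence inside that window /
                length of the shorter sequence, x100

    Both are symmetric in argument order.
    """
    if not protein_a or not protein_b:
        raise ValueError("protein sequences must be nonempty")
    if protein_a == protein_b:
        return 100.0, 100.0
    # canonical argument order so co-optimal alignment choice is symmetric
    if protein_b < protein_a:
        protein_a, protein_b = protein_b, protein_a
    aligner = _aligner if _aligner is not None else _make_aligner(scoring or AlignmentScoring())
    aln = aligner.align(protein_a, protein_b)[0]
    s_a, s_b = str(aln[0]), str(aln[1])
    start = max(len(s_a) - len(s_a.lstrip("-")), len(s_b) - len(s_b.lstrip("-")))
    end = min(len(s_a.rstrip("-")), len(s_b.rstrip("-")))
    cols = end - start
    if cols <= 0:
        return 0.0, 0.0
    matches = sum(1 for k in range(start, end) if s_a[k] == s_b[k] and s_a[k] != "-")
    shorter, gapped = (protein_a, s_a) if len(protein_a) <= len(protein_b) else (protein_b, s_b)
    span = sum(1 for k in range(start, end) if gapped[k] != "-")
    return 100.0 * matches / cols, 100.0 * span / len(shorter)


class PhamClusterer(BaseEstimator, ClusterMixin):
    """Single-linkage clustering of protein sequences into phams.

    scikit-learn-style estimator: ``fit`` takes a sequence of protein
    strings (optionally with gene identifiers) and exposes integer
    ``labels_`` plus the richer ``assignment_`` with canonical pham ids.

    Parameters
    ----------
    identity_threshold : percent amino-acid identity required for an edge.
    coverage_threshold : percent of the shorter protein that must lie in
        the aligned window.
    scoring : global-alignment parameters (see :class:`AlignmentScoring`).
    """

    def __init__(
        self,
        identity_threshold: float = 35.0,
        coverage_threshold: float = 75.0,
        scoring: AlignmentScoring | None = None,
    ):
        self.identity_threshold = identity_threshold
        self.coverage_threshold = coverage_threshold
        self.scoring = scoring

    def fit(self, X: Sequence[str] | Mapping[GeneId, str], y=None):
        """Cluster proteins; X is a list of sequences or a gene-id -> protein map."""
        if not (0 < self.identity_threshold <= 100) or not (0 < self.coverage_threshold <= 100):
            raise ValueError("thresholds must be in (0, 100]")
        if isinstance(X, Mapping):
            ids = list(X)
            proteins = [X[g] for g in ids]
        else:
            proteins = list(X)
            ids = [("seq", i + 1) for i in range(len(proteins))]
        if not proteins:
            raise ValueError("at least one protein is required")
        for g, p in zip(ids, proteins):
            if not p:
                raise ValueError(f"gene {g}: empty protein sequence")

        graph = nx.Graph()
        graph.add_nodes_from(ids)
        edges: list[SimilarityEdge] = []
        aligner = _make_aligner(self.scoring or AlignmentScoring())

        # identical sequences collapse to one representative; alignment work
        # is done once per unique pair and broadcast back
        unique: dict[str, list[GeneId]] = {}
        for g, p in zip(ids, proteins):
            unique.setdefault(p, []).append(g)
        for members in unique.values():
            anchor = members[0]
            for other in members[1:]:
                graph.add_edge(anchor, other)
                edges.append(SimilarityEdge(anchor, other, 100.0, 100.0))
        reps = sorted(unique)
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                ident, cov = pairwise_protein_identity(reps[i], reps[j], _aligner=aligner)
                if ident >= self.identity_threshold and cov >= self.coverage_threshold:
                    a, b = unique[reps[i]][0], unique[reps[j]][0]
                    graph.add_edge(a, b)
                    edges.append(SimilarityEdge(a, b, ident, cov))

        components = sorted(nx.connected_components(graph), key=lambda c: min(c))
        pham_of: dict[GeneId, str] = {}
        phams: dict[str, set[GeneId]] = {}
        for k, comp in enumerate(components, start=1):
            pham_id = f"PH{k:04d}"
            phams[pham_id] = set(comp)
            for g in comp:
                pham_of[g] = pham_id
        self.assignment_ = PhamAssignment(pham_of=pham_of, phams=phams, edges=edges)
        self.labels_ = [int(pham_of[g][2:]) - 1 for g in ids]
        self.gene_ids_ = ids
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_


def assign_phams(
    proteins: Mapping[GeneId, str],
    identity_threshold: float = 35.0,
    coverage_threshold: float = 75.0,
    scoring: AlignmentScoring | None = None,
) -> PhamAssignment:
    """Assign every gene in a population to a pham (see :class:`PhamClusterer`)."""
    clusterer = PhamClusterer(identity_threshold, coverage_threshold, scoring)
    return clusterer.fit(proteins).assignment_


def membership_profile(assignment: PhamAssignment, phage: str) -> set[str]:
    """The set of distinct phams with at least one member gene in ``phage``."""
    profile = {pham for (p, _), pham in assignment.pham_of.items() if p == phage}
    if not profile:
        raise KeyError(f"phage {phage!r} has no genes in this assignment")
    return profile
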