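"""Cluster assignment from pairwise similarity.

Two parameters are implemented: the gene-content rule (35% shared gene
content with at least one phage in a cluster — clusters are the connected
components of the GCS >= threshold graph) and a conservative screen for the
legacy nucleotide rule (50% nucleotide identity over 50% span), approximated
as exact-word span coverage.  The word screen deliberately under-reports
similarity: genomes that fail it may still be related at the amino-acid
level, which is exactly the situation the gene-content rule exists for.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from sklearn.base import BaseEstimator, ClusterMixin

from .gene_content_stats import GcsMatrix
from .io_formats import PhageMetadataTable

__all__ = [
    "ClusterPartition",
    "GeneContentClusterer",
    "cluster_by_gcs",
    "nucleotide_span_coverage",
    "cluster_report",
]


@dataclass
class ClusterPartition:
    """Cluster label per phage; labels C1, C2, ... by descending size then
    lexicographically smallest member.  A singleton is a size-1 component."""

    label_of: dict[str, str]

    @property
    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for phage, label in self.label_of.items():
            out.setdefault(label, []).append(phage)
        return {k: sorted(v) for k, v in out.items()}

    def is_singleton(self, phage: str) -> bool:
        label = self.label_of[phage]
        return sum(1 for v in self.label_of.values() if v == label) == 1

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phage_name": list(self.label_of),
                "cluster": [self.label_of[p] for p in self.label_of],
                "singleton": [int(self.is_singleton(p)) for p in self.label_of],
            }
        ).sort_values(["cluster", "phage_name"], ignore_index=True)


class GeneContentClusterer(BaseEstimator, ClusterMixin):
    """Threshold clustering on a precomputed GCS matrix.

    scikit-learn-style estimator: ``fit`` takes a :class:`GcsMatrix` (or a
    plain symmetric percent matrix with ``names``) and exposes ``labels_``
    (integers aligned with the matrix order) and ``partition_``.
    """

    def __init__(self, gcs_threshold: float = 35.0):
        self.gcs_threshold = gcs_threshold

    def fit(self, X: GcsMatrix, y=None):
        if not isinstance(X, GcsMatrix):
            raise TypeError("X must be a GcsMatrix")
        graph = nx.Graph()
        graph.add_nodes_from(X.names)
        n = len(X.names)
        for i in range(n):
            for j in range(i + 1, n):
                if X.values[i, j] >= self.gcs_threshold:
                    graph.add_edge(X.names[i], X.names[j])
        components = sorted(
            nx.connected_components(graph), key=lambda c: (-len(c), min(c))
        )
        label_of: dict[str, str] = {}
        for k, comp in enumerate(components, start=1):
            for phage in comp:
                label_of[phage] = f"C{k}"
        self.partition_ = ClusterPartition(label_of=label_of)
        self.labels_ = [int(label_of[name][1:]) - 1 for name in X.names]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_


def cluster_by_gcs(matrix: GcsMatrix, threshold: float = 35.0) -> ClusterPartition:
    """Connected components of the GCS >= threshold graph."""
    return GeneContentClusterer(gcs_threshold=threshold).fit(matrix).partition_


def nucleotide_span_coverage(genome_a: str, genome_b: str, word: int = 15) -> float:
    """Percent of ``genome_a`` positions covered by an exact word match to
    ``genome_b`` (either strand).

    Conservative screen for the legacy nucleotide clustering rule: a pair
    of genomes with high alignment identity has high coverage, but high
    coverage is not claimed to imply any particular alignment identity.
    Asymmetric in its arguments by design (coverage *of* genome_a).
    """
    if len(genome_a) < word or len(genome_b) < word:
        raise ValueError(f"sequences must be at least word size ({word}) long")
    words_b: set[str] = set()
    for i in range(len(genome_b) - word + 1):
        words_b.add(genome_b[i : i + word])
    rc = str(Seq(genome_b).reverse_complement())
    for i in range(len(rc) - word + 1):
        words_b.add(rc[i : i + word])
    covered = np.zeros(len(genome_a), dtype=bool)
    for i in range(len(genome_a) - word + 1):
        if genome_a[i : i + word] in words_b:
            covered[i : i + word] = True
    return 100.0 * float(covered.mean())


def cluster_report(
    partition: ClusterPartition, metadata: PhageMetadataTable
) -> pd.DataFrame:
    """Per-phage comparison of original vs new cluster labels.

    Each new component inherits an original cluster name by plurality vote
    of its members' original labels ("singleton"/"unassigned" members do
    not vote; ties go to the lexicographically smallest label).  A phage is
    flagged ``changed`` when its original label differs from the inherited
    label of its new component; a phage that was and remains alone is
    unchanged.
    """
    phages = sorted(partition.label_of)
    missing = [p for p in phages if p not in metadata.phage_names]
    if missing:
        raise KeyError(f"phages missing from metadata: {missing}")

    inherited: dict[str, str | None] = {}
    for label, members in partition.clusters.items():
        votes: dict[str, int] = {}
        for p in members:
            orig = metadata.cluster_of(p)
            if orig not in ("singleton", "unassigned"):
                votes[orig] = votes.get(orig, 0) + 1
        if votes:
            best = max(votes.values())
            inherited[label] = min(l for l, v in votes.items() if v == best)
        else:
            inherited[label] = None

    rows = []
    for p in phages:
        orig = metadata.cluster_of(p)
        new_label = partition.label_of[p]
        inh = inherited[new_label]
        if inh is None:
            # no member carried a proper label: a lone phage that stays
            # alone is unchanged, anything grouped is new co-membership
            changed = not (
                partition.is_singleton(p) and orig in ("singleton", "unassigned")
            )
        else:
            changed = orig != inh
        rows.append(
            {
                "phage_name": p,
                "host": metadata.host_of(p),
                "original_cluster": orig,
                "new_cluster": new_label,
                "inherited_label": inh if inh is not None else new_label,
                "singleton": int(partition.is_singleton(p)),
                "changed": int(changed),
            }
        )
    return pd.DataFrame(rows)
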