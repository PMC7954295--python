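"""Gene-content phylogeny: GCD distance matrices, neighbor joining, and
NEXUS distance export for split-network tools.

The distance between two phages is their Gene Content Dissimilarity
(GCD = 1 - GCS/100), so the tree groups phages by pham similarity.  An
unrooted neighbor-joining tree is produced internally for inspection; the
NEXUS distance block can be loaded into external split-network software to
draw a network phylogeny from the same matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .gene_content_stats import gcs

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "gcd_distance_matrix",
    "neighbor_joining",
    "export_nexus_distances",
    "parse_nexus_distances",
    "subsample_representatives",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} taxa")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < -1e-12:
            raise ValueError("distances must be nonnegative")
        self.values = v

    def value(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


@dataclass
class PhyloTree:
    """An unrooted tree as a newick string plus its leaf set."""

    newick: str
    taxa: list[str]

    def total_length(self) -> float:
        return sum(float(x) for x in re.findall(r":([0-9.eE+-]+)", self.newick))


def gcd_distance_matrix(profiles: Mapping[str, set[str]]) -> DistanceMatrix:
    """GCD distances between all pairs of pham profiles."""
    taxa = list(profiles)
    if len(taxa) < 3:
        raise ValueError("need at least 3 phages for a distance matrix")
    n = len(taxa)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - gcs(profiles[taxa[i]], profiles[taxa[j]]) / 100.0
            values[i, j] = values[j, i] = d
    return DistanceMatrix(taxa=taxa, values=values)


class _Node:
    __slots__ = ("name", "children", "min_taxon")

    def __init__(self, name: str | None, children=None, min_taxon: str = ""):
        self.name = name
        self.children = children or []  # list of (child, branch length)
        self.min_taxon = min_taxon or (name or "")

    def newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaks.

    When several pairs minimise the Q criterion, the pair whose sorted
    (lexicographically smallest member) taxon names are smallest is joined.
    Negative branch-length estimates are clamped to zero.
    """
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = matrix.values.copy()
    nodes = [_Node(t) for t in matrix.taxa]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D[i, j] - sums[i] - sums[j]
                key = tuple(sorted((nodes[i].min_taxon, nodes[j].min_taxon)))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        bl_i = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (m - 2))
        bl_j = D[i, j] - bl_i
        bl_i, bl_j = max(bl_i, 0.0), max(bl_j, 0.0)
        new = _Node(None, [(nodes[i], bl_i), (nodes[j], bl_j)],
                    min_taxon=min(nodes[i].min_taxon, nodes[j].min_taxon))
        # distances from the new node to every remaining taxon
        k_new = len(nodes)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[k_new, k] = D[k, k_new] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [k_new]

    i, j, k = active
    # closed-form star resolution for the final three nodes
    bl_i = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    bl_j = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    bl_k = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    children = sorted(
        [(nodes[i], max(bl_i, 0.0)), (nodes[j], max(bl_j, 0.0)), (nodes[k], max(bl_k, 0.0))],
        key=lambda t: t[0].min_taxon,
    )
    root = _Node(None, children)
    newick = root.newick() + ";"
    return PhyloTree(newick=newick, taxa=sorted(matrix.taxa))


def sanitize_label(label: str) -> str:
    """Restrict a taxon label to alphanumerics and underscores."""
    out = re.sub(r"[^0-9A-Za-z_]", "_", label)
    return out or "_"


def export_nexus_distances(matrix: DistanceMatrix) -> str:
    """NEXUS text with TAXA and lower-triangular DISTANCES blocks.

    Labels are sanitized to alphanumerics+underscore; a collision after
    sanitization is an error (the mapping would be ambiguous).
    """
    labels = [sanitize_label(t) for t in matrix.taxa]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"sanitized labels collide: {dupes}")
    n = len(labels)
    lines = [
        "#NEXUS",
        "",
        "BEGIN TAXA;",
        f"    DIMENSIONS NTAX={n};",
        "    TAXLABELS " + " ".join(labels) + ";",
        "END;",
        "",
        "BEGIN DISTANCES;",
        f"    DIMENSIONS NTAX={n};",
        "    FORMAT TRIANGLE=LOWER DIAGONAL LABELS=LEFT;",
        "    MATRIX",
    ]
    for i in range(n):
        row = " ".join(f"{matrix.values[i, j]:.6f}" for j in range(i + 1))
        lines.append(f"        {labels[i]} {row}")
    lines += ["    ;", "END;", ""]
    return "\n".join(lines)


def parse_nexus_distances(text: str) -> DistanceMatrix:
    """Parse the DISTANCES block written by :func:`export_nexus_distances`."""
    in_matrix = False
    taxa: list[str] = []
    rows: list[list[float]] = []
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.upper() == "MATRIX":
            in_matrix = True
            continue
        if in_matrix:
            if stripped == ";":
                break
            parts = stripped.split()
            taxa.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if not taxa:
        raise ValueError("no MATRIX block found")
    n = len(taxa)
    values = np.zeros((n, n))
    for i, row in enumerate(rows):
        if len(row) != i + 1:
            raise ValueError(f"row {taxa[i]} has {len(row)} entries, expected {i + 1}")
        for j, v in enumerate(row):
            values[i, j] = values[j, i] = v
    return DistanceMatrix(taxa=taxa, values=values)


def subsample_representatives(
    cluster_members: Mapping[str, list[str]], max_per_cluster: int = 10
) -> list[str]:
    """Up to ``max_per_cluster`` representatives per cluster, chosen by
    lexicographic name for determinism."""
    if max_per_cluster < 1:
        raise ValueError("max_per_cluster must be >= 1")
    chosen: list[str] = []
    for label in sorted(cluster_members):
        chosen.extend(sorted(cluster_members[label])[:max_per_cluster])
    return chosen
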