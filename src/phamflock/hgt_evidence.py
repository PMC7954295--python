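"""Per-gene horizontal-gene-transfer evidence.

Two signals are tabulated for every gene of a focal genome: how far its GC
content deviates from the genome mean (an atypical composition suggests a
foreign origin), and how many distinct isolation hosts are represented
among the phages carrying its pham (a family spanning phages of unrelated
hosts suggests cross-host exchange).  Neither signal is conclusive alone,
so the full ranked table is always reported; the boolean flag applies a
configurable OR rule over the two thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io_formats import AnnotatedGenome, PhageMetadataTable
from .pham_assignment import PhamAssignment

__all__ = [
    "HgtEvidenceRow",
    "gc_content",
    "pham_host_diversity",
    "hgt_evidence_table",
    "evidence_dataframe",
]


def gc_content(seq: str) -> float:
    """Percent G+C of a nucleotide sequence, ignoring N bases.

    Strand-independent: a sequence and its reverse complement give the
    same value (G+C is preserved under complementation).
    """
    counts = {b: 0 for b in "ACGT"}
    for ch in seq.upper():
        if ch in counts:
            counts[ch] += 1
        elif ch != "N":
            raise ValueError(f"illegal nucleotide {ch!r}")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence is empty or all-N")
    return 100.0 * (counts["G"] + counts["C"]) / total


@dataclass(frozen=True)
class HgtEvidenceRow:
    gene_number: int
    gene_gc: float
    genome_gc: float
    gc_deviation: float  # gene - genome mean, percentage points
    pham: str
    unique_host_count: int
    hosts: tuple[str, ...]
    flagged: bool
    rank: int


def pham_host_diversity(
    pham: str, assignment: PhamAssignment, metadata: PhageMetadataTable
) -> tuple[int, set[str]]:
    """Distinct isolation hosts among the phages carrying ``pham``.

    Host strings are compared exactly at the granularity the metadata
    provides (no taxonomy normalization); the focal phage's own host
    counts, so an orpham always yields 1.
    """
    if pham not in assignment.phams:
        raise KeyError(f"unknown pham {pham!r}")
    hosts = set()
    for phage, _num in assignment.phams[pham]:
        hosts.add(metadata.host_of(phage))  # raises KeyError if missing
    return len(hosts), hosts


def hgt_evidence_table(
    genome: AnnotatedGenome,
    assignment: PhamAssignment,
    metadata: PhageMetadataTable,
    gc_delta: float = 5.0,
    host_min: int = 3,
) -> list[HgtEvidenceRow]:
    """Ranked per-gene HGT evidence for one genome.

    A gene is flagged iff its GC deviation is at least ``gc_delta``
    percentage points above the genome mean OR its pham spans at least
    ``host_min`` distinct isolation hosts.  Rows are ranked by (host count
    desc, GC deviation desc); the table always contains every gene so a
    different cut can be applied downstream.
    """
    if not genome.genes:
        raise ValueError(f"genome {genome.name} has no annotated genes")
    genome_gc = gc_content(genome.sequence)
    entries = []
    for gene in genome.genes:
        gid = (genome.name, gene.gene_number)
        if gid not in assignment.pham_of:
            raise KeyError(f"gene {gid} has no pham assignment")
        pham = assignment.pham_of[gid]
        count, hosts = pham_host_diversity(pham, assignment, metadata)
        gene_gc = gc_content(gene.nucleotide_seq)
        deviation = gene_gc - genome_gc
        flagged = (deviation >= gc_delta) or (count >= host_min)
        entries.append((gene.gene_number, gene_gc, deviation, pham, count, hosts, flagged))

    order = sorted(entries, key=lambda e: (-e[4], -e[2], e[0]))
    rank_of = {e[0]: r + 1 for r, e in enumerate(order)}
    return [
        HgtEvidenceRow(
            gene_number=num,
            gene_gc=gc,
            genome_gc=genome_gc,
            gc_deviation=dev,
            pham=pham,
            unique_host_count=count,
            hosts=tuple(sorted(hosts)),
            flagged=flagged,
            rank=rank_of[num],
        )
        for num, gc, dev, pham, count, hosts, flagged in entries
    ]


def evidence_dataframe(rows: Sequence[HgtEvidenceRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene_number for r in rows],
            "gc": [round(r.gene_gc, 2) for r in rows],
            "deviation": [round(r.gc_deviation, 2) for r in rows],
            "pham": [r.pham for r in rows],
            "host_count": [r.unique_host_count for r in rows],
            "flagged": [int(r.flagged) for r in rows],
            "rank": [r.rank for r in rows],
        }
    )
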