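"""Readers and writers for the file formats the pipeline touches.

Genomes travel as plain nucleotide FASTA; gene annotations come either from
GenBank flat files (CDS features with ``translation`` qualifiers) or from a
simple tab-separated gene table accompanied by the genome FASTA.  All
coordinates in files are 1-based inclusive, following GenBank convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneRecord",
    "AnnotatedGenome",
    "PhageMetadataTable",
    "FormatError",
    "read_genome_fasta",
    "write_genome_fasta",
    "read_annotated_genome",
    "read_gene_table",
    "write_gene_table",
    "read_metadata_table",
    "write_metadata_table",
]

NUCLEOTIDES = set("ACGTN")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

GENE_TABLE_COLUMNS = [
    "phage_name",
    "gene_number",
    "start",
    "end",
    "strand",
    "function",
    "translation",
]

METADATA_COLUMNS = ["phage_name", "host", "original_cluster"]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GeneRecord:
    """A single annotated protein-coding gene.

    ``start``/``end`` are 1-based inclusive genome coordinates; for a
    reverse-strand gene ``nucleotide_seq`` is the reverse complement of the
    genome slice, i.e. the coding-strand sequence.
    """

    gene_number: int
    start: int
    end: int
    strand: str  # "+" or "-"
    nucleotide_seq: str
    protein_seq: str
    function_label: str = "unknown"

    def __post_init__(self) -> None:
        if self.gene_number < 1:
            raise ValueError(f"gene_number must be positive, got {self.gene_number}")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_number}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_number}: strand must be '+' or '-'")
        if len(self.nucleotide_seq) != self.end - self.start + 1:
            raise ValueError(
                f"gene {self.gene_number}: sequence length {len(self.nucleotide_seq)} "
                f"does not match span {self.end - self.start + 1}"
            )
        if not self.protein_seq:
            raise ValueError(f"gene {self.gene_number}: empty protein sequence")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    """A phage genome with its ordered gene records and metadata."""

    name: str
    sequence: str
    genes: list[GeneRecord] = field(default_factory=list)
    host: str = ""
    original_cluster: str = "unassigned"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.name}: empty sequence")
        seen = set()
        for g in self.genes:
            if g.gene_number in seen:
                raise ValueError(f"genome {self.name}: duplicate gene number {g.gene_number}")
            seen.add(g.gene_number)
            if g.start < 1 or g.end > len(self.sequence):
                raise ValueError(
                    f"genome {self.name}: gene {g.gene_number} coordinates "
                    f"[{g.start},{g.end}] exceed sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def gene_slice(self, gene: GeneRecord) -> str:
        """Coding-strand sequence recovered from the genome itself."""
        raw = self.sequence[gene.start - 1 : gene.end]
        return _revcomp(raw) if gene.strand == "-" else raw

    @property
    def proteome(self) -> dict[int, str]:
        return {g.gene_number: g.protein_seq for g in self.genes}


@dataclass
class PhageMetadataTable:
    """Phage name, isolation host, and original cluster label per phage."""

    rows: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("metadata table is empty")
        names = [r[0] for r in self.rows]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate phage names in metadata: {dupes}")
        for name, host, _cluster in self.rows:
            if not host:
                raise ValueError(f"phage {name}: empty host")

    def host_of(self, phage: str) -> str:
        for name, host, _ in self.rows:
            if name == phage:
                return host
        raise KeyError(f"phage {phage!r} not in metadata")

    def cluster_of(self, phage: str) -> str:
        for name, _, cluster in self.rows:
            if name == phage:
                return cluster
        raise KeyError(f"phage {phage!r} not in metadata")

    @property
    def phage_names(self) -> list[str]:
        return [r[0] for r in self.rows]


# ---------------------------------------------------------------------------
# FASTA


def read_genome_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-record nucleotide FASTA into (name, sequence) pairs.

    Sequences are uppercased; characters outside {A,C,G,T,N} are rejected
    with the record name and offset of the first offending character.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record name {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in NUCLEOTIDES:
                raise FormatError(
                    f"{path}: record {rec.id!r} has illegal character {ch!r} at offset {i}"
                )
        out.append((rec.id, seq))
    return out


def write_genome_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GenBank / gene table


def read_annotated_genome(
    path: str | Path,
    fasta_fallback: str | Path | None = None,
    *,
    name: str | None = None,
    host: str = "",
    original_cluster: str = "unassigned",
) -> AnnotatedGenome:
    """Read one annotated genome from a GenBank flat file or a gene TSV.

    GenBank: every CDS feature with a ``translation`` qualifier becomes a
    :class:`GeneRecord`; strand comes from the feature location and
    reverse-strand genes are reverse complemented into coding orientation.
    Gene numbers are assigned by ascending start coordinate.

    TSV: the gene-table dialect (see :data:`GENE_TABLE_COLUMNS`) plus a
    genome FASTA passed as ``fasta_fallback``.
    """
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        if fasta_fallback is None:
            raise FormatError(f"{path}: gene TSV requires a genome FASTA (fasta_fallback)")
        return _read_tsv_genome(path, Path(fasta_fallback), name=name, host=host, original_cluster=original_cluster)
    return _read_genbank_genome(path, name=name, host=host, original_cluster=original_cluster)


def _read_genbank_genome(
    path: Path, *, name: str | None, host: str, original_cluster: str
) -> AnnotatedGenome:
    record = SeqIO.read(str(path), "genbank")
    sequence = str(record.seq).upper()
    cds = []
    for feat in record.features:
        if feat.type != "CDS":
            continue
        if "translation" not in feat.qualifiers:
            raise FormatError(
                f"{path}: CDS at {feat.location} lacks a translation qualifier"
            )
        start = int(feat.location.start) + 1  # to 1-based inclusive
        end = int(feat.location.end)
        if end > len(sequence):
            raise FormatError(f"{path}: CDS end {end} exceeds sequence length {len(sequence)}")
        strand = "-" if feat.location.strand == -1 else "+"
        nt = sequence[start - 1 : end]
        if strand == "-":
            nt = _revcomp(nt)
        protein = feat.qualifiers["translation"][0]
        function = feat.qualifiers.get("product", ["unknown"])[0] or "unknown"
        cds.append((start, end, strand, nt, protein, function))
    cds.sort(key=lambda t: (t[0], t[1]))
    genes = [
        GeneRecord(
            gene_number=i + 1,
            start=start,
            end=end,
            strand=strand,
            nucleotide_seq=nt,
            protein_seq=protein,
            function_label=function,
        )
        for i, (start, end, strand, nt, protein, function) in enumerate(cds)
    ]
    return AnnotatedGenome(
        name=name or record.id,
        sequence=sequence,
        genes=genes,
        host=host,
        original_cluster=original_cluster,
    )


def _read_tsv_genome(
    path: Path, fasta_path: Path, *, name: str | None, host: str, original_cluster: str
) -> AnnotatedGenome:
    fasta_entries = dict(read_genome_fasta(fasta_path))
    rows = _read_tsv_rows(path, GENE_TABLE_COLUMNS)
    phage_names = {r["phage_name"] for r in rows}
    if name is not None:
        rows = [r for r in rows if r["phage_name"] == name]
        if not rows:
            raise FormatError(f"{path}: no genes for phage {name!r}")
    elif len(phage_names) != 1:
        raise FormatError(
            f"{path}: gene table covers {sorted(phage_names)}; pass `name` to select one"
        )
    phage = rows[0]["phage_name"]
    if phage not in fasta_entries:
        raise FormatError(f"{fasta_path}: no sequence for phage {phage!r}")
    sequence = fasta_entries[phage]
    genes = []
    for r in sorted(rows, key=lambda r: int(r["start"])):
        start, end = int(r["start"]), int(r["end"])
        strand = r["strand"]
        if strand not in ("+", "-"):
            raise FormatError(f"{path}: bad strand {strand!r} for gene {r['gene_number']}")
        if end > len(sequence):
            raise FormatError(f"{path}: gene {r['gene_number']} end {end} exceeds genome length")
        nt = sequence[start - 1 : end]
        if strand == "-":
            nt = _revcomp(nt)
        genes.append(
            GeneRecord(
                gene_number=int(r["gene_number"]),
                start=start,
                end=end,
                strand=strand,
                nucleotide_seq=nt,
                protein_seq=r["translation"],
                function_label=r["function"] or "unknown",
            )
        )
    return AnnotatedGenome(
        name=phage, sequence=sequence, genes=genes, host=host, original_cluster=original_cluster
    )


def write_gene_table(genomes: Sequence[AnnotatedGenome], path: str | Path) -> None:
    """Write the gene-table TSV dialect for one or more genomes."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(GENE_TABLE_COLUMNS)
        for genome in genomes:
            for g in genome.genes:
                w.writerow(
                    [genome.name, g.gene_number, g.start, g.end, g.strand, g.function_label, g.protein_seq]
                )


def read_gene_table(path: str | Path) -> dict[str, list[dict]]:
    """Read a (possibly multi-phage) gene table into rows grouped by phage."""
    rows = _read_tsv_rows(Path(path), GENE_TABLE_COLUMNS)
    grouped: dict[str, list[dict]] = {}
    for r in rows:
        grouped.setdefault(r["phage_name"], []).append(r)
    return grouped


# ---------------------------------------------------------------------------
# Metadata


def read_metadata_table(path: str | Path) -> PhageMetadataTable:
    """Read the phage metadata TSV (phage_name, host, original_cluster)."""
    rows = _read_tsv_rows(Path(path), METADATA_COLUMNS)
    table_rows = []
    for r in rows:
        cluster = r["original_cluster"].strip() or "unassigned"
        table_rows.append((r["phage_name"], r["host"], cluster))
    return PhageMetadataTable(rows=table_rows)


def write_metadata_table(table: PhageMetadataTable, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(METADATA_COLUMNS)
        for row in table.rows:
            w.writerow(row)


def _read_tsv_rows(path: Path, required_columns: list[str]) -> list[dict]:
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        missing = [c for c in required_columns if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        rows = list(reader)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return rows
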