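"""Synthetic phage populations with known ground truth.

The generator emulates the statistical structure the gene-content analysis
assumes: a community of small phage genomes whose genes are drawn from a
pham universe with cluster-structured sharing (within-cluster core phams,
community-wide shared phams, extra sharing between designated cluster
pairs), per-genome orphams, implanted HGT genes (atypical GC and/or phams
spanning phages of multiple isolation hosts), and nucleotide sequences
produced by synonymous codon assignment so that protein identity can be
held at 100% while nucleotide identity between clusters is erased.

The default parameters describe the scenario this package was built
around: two small clusters plus one focal singleton-by-nucleotide phage
whose gene content ties all three together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io_formats import (
    AnnotatedGenome,
    GeneRecord,
    PhageMetadataTable,
    write_gene_table,
    write_genome_fasta,
    write_metadata_table,
)

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "simulate_population",
    "codon_scramble",
    "translate_cds",
    "write_truth",
    "read_truth",
    "write_population",
    "bluefeather_preset",
]

GeneId = tuple[str, int]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

COMMUNITY_HOST = "Arthrobacter globiformis B-2979"
SATELLITE_HOSTS = [
    "Gordonia malaquae BEN700",
    "Mycobacterium smegmatis mc2 155",
    "Microbacterium foliorum NRRL B-24224",
    "Gordonia rubripertincta NRRL B-16540",
    "Arthrobacter sp. ATCC 21022",
]

# standard bacterial/phage genetic code (table 11)
_TABLE = CodonTable.unambiguous_dna_by_id[11]
CODONS_OF: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    CODONS_OF.setdefault(aa, []).append(codon)
STOP_CODONS = sorted(_TABLE.stop_codons)


def _gc_count(codon: str) -> int:
    return sum(1 for b in codon if b in "GC")


def _min_max_codons(options: Sequence[str]) -> tuple[list[str], list[str], int, int]:
    lo = min(_gc_count(c) for c in options)
    hi = max(_gc_count(c) for c in options)
    return (
        [c for c in options if _gc_count(c) == lo],
        [c for c in options if _gc_count(c) == hi],
        lo,
        hi,
    )


@dataclass
class SimulationParams:
    """Knobs of the population generator; defaults define the focal
    singleton-joins-two-clusters scenario.

    ``cross_cluster_share`` is the fraction of a genome's non-orpham gene
    budget drawn from a pool shared by *all* clusters;
    ``cross_cluster_extra`` adds pair-specific shared pools on top.
    ``hgt_implants`` entries are (gene slot in the focal genome, GC offset
    in percentage points, number of extra isolation hosts); extra hosts
    are realised as small satellite genomes, each with a unique host,
    carrying the implanted pham.
    """

    seed: int = 17
    n_clusters: int = 3
    phages_per_cluster: tuple[int, ...] = (3, 2, 1)
    genes_per_genome: tuple[int, int] = (24, 26)
    pham_universe_size: int = 400
    core_fraction: float = 0.30
    cross_cluster_share: float = 0.45
    cross_cluster_extra: dict[tuple[int, int], float] = field(
        default_factory=lambda: {(1, 2): 0.22}
    )
    orphams_per_genome: int = 2
    within_pham_aa_divergence: float = 0.01
    synonymous_scramble_rate: float = 1.0
    gc_target: float = 52.0
    hgt_implants: list[tuple[int, float, int]] = field(
        default_factory=lambda: [(15, 6.0, 0), (24, 6.0, 0), (2, 0.0, 2), (19, 0.0, 2)]
    )
    protein_length_range: tuple[int, int] = (140, 260)
    spacer_length_range: tuple[int, int] = (10, 50)
    satellite_genes: int = 9
    community_host: str = COMMUNITY_HOST

    def validate(self) -> None:
        if self.n_clusters < 1 or len(self.phages_per_cluster) != self.n_clusters:
            raise ValueError("phages_per_cluster must list one size per cluster")
        lo, hi = self.genes_per_genome
        if lo > hi or lo < 1:
            raise ValueError("invalid genes_per_genome range")
        for p in (
            self.core_fraction,
            self.cross_cluster_share,
            self.within_pham_aa_divergence,
            self.synonymous_scramble_rate,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability parameter {p} out of [0,1]")
        if lo < self.orphams_per_genome + 1:
            raise ValueError("genes_per_genome must exceed orphams_per_genome")
        for (i, j), extra in self.cross_cluster_extra.items():
            if not (0 <= i < self.n_clusters and 0 <= j < self.n_clusters and i != j):
                raise ValueError(f"bad cluster pair {(i, j)}")
            if not (0.0 <= extra <= 1.0):
                raise ValueError(f"cross_cluster_extra {extra} out of [0,1]")
        for slot, _offset, n_extra in self.hgt_implants:
            if not (1 <= slot <= lo):
                raise ValueError(f"implant slot {slot} outside every genome (min {lo} genes)")
            if n_extra < 0 or n_extra > len(SATELLITE_HOSTS):
                raise ValueError(f"unsupported number of extra hosts: {n_extra}")

    def budget_min(self) -> int:
        return self.genes_per_genome[0] - self.orphams_per_genome


def bluefeather_preset(seed: int = 17) -> SimulationParams:
    """The default scenario: a 3-phage cluster, a 2-phage cluster, and a
    focal phage, all sharing gene content above the clustering threshold
    while nucleotide identity between clusters is synonymously erased."""
    return SimulationParams(seed=seed)


@dataclass
class SyntheticTruth:
    """Generator ground truth for recovery tests."""

    pham_of: dict[GeneId, str]
    cluster_of: dict[str, str]
    hgt_genes: list[tuple[str, int, float, int]]  # (phage, gene, gc_offset, n_extra_hosts)
    gene_gc_target: dict[GeneId, float]
    focal_phage: str

    def profile_of(self, phage: str) -> set[str]:
        return {pham for (p, _), pham in self.pham_of.items() if p == phage}

    def orpham_phams(self) -> set[str]:
        phages_of: dict[str, set[str]] = {}
        for (phage, _), pham in self.pham_of.items():
            phages_of.setdefault(pham, set()).add(phage)
        return {pham for pham, phages in phages_of.items() if len(phages) == 1}


# ---------------------------------------------------------------------------
# codon machinery


def translate_cds(nucleotide_seq: str) -> str:
    """Translate a CDS with the standard bacterial code, dropping the
    terminal stop if present."""
    protein = str(Seq(nucleotide_seq).translate(table=11))
    return protein[:-1] if protein.endswith("*") else protein


def codon_scramble(
    protein: str,
    gc_target: float = 60.0,
    scramble_seed: int | Sequence[int] = 0,
    *,
    include_stop: bool = True,
    warn: bool = True,
) -> str:
    """Back-translate a protein with synonymous codons biased toward a GC
    target.

    At each position either a minimum-GC or a maximum-GC synonymous codon
    is chosen; the running GC total is steered toward the target, so the
    realised GC of the output tracks the (achievable) target to within a
    few bases regardless of length.  Different seeds shuffle which
    positions take which codon and which codon is drawn from GC ties, so
    repeated calls give distinct nucleotide sequences encoding exactly the
    same protein.  An unreachable target (the achievable range depends on
    amino-acid composition) triggers a warning and the nearest achievable
    value is used.
    """
    if not protein:
        raise ValueError("protein must be nonempty")
    rng = np.random.default_rng(scramble_seed)
    slots: list[tuple[list[str], list[str], int, int]] = []
    for aa in protein:
        if aa not in CODONS_OF:
            raise ValueError(f"unknown amino acid {aa!r}")
        slots.append(_min_max_codons(CODONS_OF[aa]))
    if include_stop:
        slots.append(_min_max_codons(STOP_CODONS))

    n = len(slots)
    lo_total = sum(s[2] for s in slots)
    hi_total = sum(s[3] for s in slots)
    target_bases = gc_target / 100.0 * 3 * n
    if target_bases < lo_total or target_bases > hi_total:
        if warn:
            lo_pct, hi_pct = 100 * lo_total / (3 * n), 100 * hi_total / (3 * n)
            warnings.warn(
                f"gc_target {gc_target:.2f}% unreachable for this protein; "
                f"achievable range is [{lo_pct:.2f}%, {hi_pct:.2f}%]",
                stacklevel=2,
            )
        target_bases = min(max(target_bases, lo_total), hi_total)
    lam = 0.5 if hi_total == lo_total else (target_bases - lo_total) / (hi_total - lo_total)

    order = rng.permutation(n)
    choose_hi = np.zeros(n, dtype=bool)
    err = 0.0  # cumulative (actual - expected) GC bases
    for idx in order:
        lo_set, hi_set, lo, hi = slots[idx]
        expected = lo + lam * (hi - lo)
        # pick the option that keeps the running total closest to expectation
        if abs(err + hi - expected) < abs(err + lo - expected):
            choose_hi[idx] = True
            err += hi - expected
        else:
            err += lo - expected
    out = []
    for idx in range(n):
        lo_set, hi_set, _, _ = slots[idx]
        options = hi_set if choose_hi[idx] else lo_set
        out.append(options[int(rng.integers(len(options)))])
    return "".join(out)


def _mutate_protein(protein: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence <= 0:
        return protein
    chars = list(protein)
    hits = np.nonzero(rng.random(len(chars)) < divergence)[0]
    for i in hits:
        alternatives = AA_ALPHABET.replace(chars[i], "")
        chars[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def _random_spacer(length: int, gc_target: float, rng: np.random.Generator) -> str:
    t = gc_target / 100.0
    bases = []
    for _ in range(length):
        if rng.random() < t:
            bases.append("G" if rng.random() < 0.5 else "C")
        else:
            bases.append("A" if rng.random() < 0.5 else "T")
    return "".join(bases)


# ---------------------------------------------------------------------------
# population assembly


class _PhamUniverse:
    """Allocates pham identifiers and reference proteins on demand."""

    def __init__(self, params: SimulationParams):
        self.params = params
        self.rng = np.random.default_rng([params.seed, 1])
        self.reference: dict[str, str] = {}

    def new_pham(self) -> str:
        k = len(self.reference) + 1
        if k > self.params.pham_universe_size:
            raise ValueError(
                "pham universe exhausted: the requested sharing structure needs "
                f"more than pham_universe_size={self.params.pham_universe_size} phams"
            )
        pham = f"TP{k:04d}"
        lo, hi = self.params.protein_length_range
        length = int(self.rng.integers(lo, hi + 1))
        body = "".join(
            AA_ALPHABET[int(x)] for x in self.rng.integers(len(AA_ALPHABET), size=length - 1)
        )
        self.reference[pham] = "M" + body
        return pham

    def new_phams(self, count: int) -> list[str]:
        return [self.new_pham() for _ in range(count)]


def _cluster_codon_realization(
    pham: str,
    pham_index: int,
    cluster_index: int,
    reference: str,
    params: SimulationParams,
    cache: dict[tuple[str, int], list[str]],
) -> list[str]:
    """Per-(pham, cluster) codon realization of the reference protein.

    Cluster 0 carries the base realization; other clusters re-draw each
    codon position with probability ``synonymous_scramble_rate``, so at
    rate 1 the realizations are independent (nucleotide identity between
    clusters collapses to the synonymous baseline) while at rate 0 all
    clusters share one nucleotide sequence.
    """
    key = (pham, cluster_index)
    if key in cache:
        return cache[key]
    base_key = (pham, 0)
    if base_key not in cache:
        cds = codon_scramble(
            reference, params.gc_target, [params.seed, 2, pham_index], warn=False
        )
        cache[base_key] = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    codons = list(cache[base_key])
    if cluster_index != 0 and params.synonymous_scramble_rate > 0:
        alt = codon_scramble(
            reference, params.gc_target, [params.seed, 3, pham_index, cluster_index],
            warn=False,
        )
        alt_codons = [alt[i : i + 3] for i in range(0, len(alt), 3)]
        rng = np.random.default_rng([params.seed, 4, pham_index, cluster_index])
        redraw = rng.random(len(codons)) < params.synonymous_scramble_rate
        codons = [a if r else b for a, b, r in zip(alt_codons, codons, redraw)]
    cache[key] = codons
    return codons


def _gene_nucleotide(
    protein: str,
    pham: str,
    pham_index: int,
    cluster_index: int,
    reference: str,
    gc_target: float,
    params: SimulationParams,
    cache: dict[tuple[str, int], list[str]],
    rng: np.random.Generator,
) -> str:
    if abs(gc_target - params.gc_target) > 1e-9:
        # implanted-GC genes get an independent realization at their own target
        return codon_scramble(protein, gc_target, rng.integers(2**31), warn=False)
    codons = list(
        _cluster_codon_realization(pham, pham_index, cluster_index, reference, params, cache)
    )
    # patch codons where this member's protein diverged from the reference
    for i, (aa_ref, aa_mem) in enumerate(zip(reference, protein)):
        if aa_ref != aa_mem:
            codons[i] = codon_scramble(
                aa_mem, params.gc_target, rng.integers(2**31),
                include_stop=False, warn=False,
            )
    return "".join(codons)


def simulate_population(
    params: SimulationParams | None = None,
) -> tuple[list[AnnotatedGenome], PhageMetadataTable, SyntheticTruth]:
    """Generate a phage population, its metadata table, and ground truth.

    Deterministic for a fixed seed: every phage derives its own RNG stream
    from (seed, phage index), the pham universe and per-pham codon
    realizations from their own streams, so adding phages does not perturb
    existing genomes.
    """
    params = params or SimulationParams()
    params.validate()

    universe = _PhamUniverse(params)
    budget_min = params.budget_min()
    k_all = round(params.cross_cluster_share * budget_min)
    k_core = round(params.core_fraction * budget_min)
    k_extra = {
        tuple(sorted(pair)): round(x * budget_min)
        for pair, x in params.cross_cluster_extra.items()
    }

    # feasibility per cluster
    for c in range(params.n_clusters):
        need = k_all + k_core + sum(
            k for pair, k in k_extra.items() if c in pair
        ) + params.orphams_per_genome
        if need > params.genes_per_genome[0]:
            raise ValueError(
                f"cluster {c}: sharing structure needs {need} genes but the "
                f"smallest genome has {params.genes_per_genome[0]}"
            )

    shared_all = universe.new_phams(k_all)
    pair_pools = {pair: universe.new_phams(k) for pair, k in sorted(k_extra.items())}
    core_pools = [universe.new_phams(k_core) for _ in range(params.n_clusters)]
    accessory_size = max(4, params.genes_per_genome[1] - budget_min + 4)
    accessory_pools = [universe.new_phams(accessory_size) for _ in range(params.n_clusters)]

    # satellites realise the "extra hosts" of HGT implants
    n_satellites = max((n for _, _, n in params.hgt_implants), default=0)
    implant_phams: dict[int, str] = {}  # slot -> dedicated pham (host implants only)
    for slot, _offset, n_extra in params.hgt_implants:
        if n_extra > 0:
            implant_phams[slot] = universe.new_pham()

    codon_cache: dict[tuple[str, int], list[str]] = {}

    genomes: list[AnnotatedGenome] = []
    meta_rows: list[tuple[str, str, str]] = []
    truth_pham: dict[GeneId, str] = {}
    truth_cluster: dict[str, str] = {}
    truth_gc: dict[GeneId, float] = {}
    hgt_genes: list[tuple[str, int, float, int]] = []
    focal_phage = ""

    global_index = 0
    for c, size in enumerate(params.phages_per_cluster):
        is_last_cluster = c == params.n_clusters - 1
        original_label = "singleton" if size == 1 else f"OC{c + 1}"
        for m in range(size):
            name = f"Phage{c + 1}_{m + 1}"
            rng = np.random.default_rng([params.seed, 100 + global_index])
            global_index += 1
            n_genes = int(rng.integers(params.genes_per_genome[0], params.genes_per_genome[1] + 1))

            phams: list[str] = list(shared_all)
            for pair, pool in pair_pools.items():
                if c in pair:
                    phams.extend(pool)
            phams.extend(core_pools[c])
            n_accessory = n_genes - params.orphams_per_genome - len(phams)
            if n_accessory > 0:
                pick = rng.choice(len(accessory_pools[c]), size=n_accessory, replace=False)
                phams.extend(accessory_pools[c][i] for i in sorted(pick))
            phams.extend(universe.new_phams(params.orphams_per_genome))
            order = rng.permutation(len(phams))
            phams = [phams[i] for i in order]

            is_focal = is_last_cluster and m == 0
            gc_targets = [params.gc_target] * len(phams)
            if is_focal:
                focal_phage = name
                shared_set = set(shared_all) | {p for pool in pair_pools.values() for p in pool}
                for slot, offset, n_extra in params.hgt_implants:
                    pos = slot - 1
                    if n_extra > 0:
                        if phams[pos] in shared_set:
                            # keep the shared pham: move it to a private slot
                            implant_slots = {sl for sl, _, _ in params.hgt_implants}
                            swap = next(
                                i for i, p in enumerate(phams)
                                if p not in shared_set and i + 1 not in implant_slots
                            )
                            phams[pos], phams[swap] = phams[swap], phams[pos]
                        phams[pos] = implant_phams[slot]
                    gc_targets[pos] = params.gc_target + offset
                    hgt_genes.append((name, slot, offset, n_extra))

            genomes.append(
                _assemble_genome(
                    name, c, phams, gc_targets, universe,
                    codon_cache, params, rng, host=params.community_host,
                    original_cluster=original_label,
                )
            )
            meta_rows.append((name, params.community_host, original_label))
            truth_cluster[name] = f"T{c + 1}"
            for g, (pham, gct) in enumerate(zip(phams, gc_targets), start=1):
                truth_pham[(name, g)] = pham
                truth_gc[(name, g)] = gct

    for sat in range(n_satellites):
        name = f"Satellite{sat + 1}"
        rng = np.random.default_rng([params.seed, 100 + global_index])
        global_index += 1
        carried = [
            implant_phams[slot]
            for slot, _offset, n_extra in params.hgt_implants
            if n_extra > sat and n_extra > 0
        ]
        phams = carried + universe.new_phams(params.satellite_genes - len(carried))
        order = rng.permutation(len(phams))
        phams = [phams[i] for i in order]
        host = SATELLITE_HOSTS[sat]
        genomes.append(
            _assemble_genome(
                name, params.n_clusters + sat, phams, [params.gc_target] * len(phams),
                universe, codon_cache, params, rng, host=host,
                original_cluster="singleton",
            )
        )
        meta_rows.append((name, host, "singleton"))
        truth_cluster[name] = f"SAT{sat + 1}"
        for g, pham in enumerate(phams, start=1):
            truth_pham[(name, g)] = pham
            truth_gc[(name, g)] = params.gc_target

    metadata = PhageMetadataTable(rows=meta_rows)
    truth = SyntheticTruth(
        pham_of=truth_pham,
        cluster_of=truth_cluster,
        hgt_genes=hgt_genes,
        gene_gc_target=truth_gc,
        focal_phage=focal_phage,
    )
    return genomes, metadata, truth


def _assemble_genome(
    name: str,
    cluster_index: int,
    phams: Sequence[str],
    gc_targets: Sequence[float],
    universe: _PhamUniverse,
    codon_cache: dict,
    params: SimulationParams,
    rng: np.random.Generator,
    *,
    host: str,
    original_cluster: str,
) -> AnnotatedGenome:
    lo, hi = params.spacer_length_range
    reverse_slot = int(rng.integers(len(phams)))  # one reverse-strand gene per genome
    parts: list[str] = []
    genes: list[GeneRecord] = []
    pos = 0
    for g, (pham, gct) in enumerate(zip(phams, gc_targets)):
        spacer = _random_spacer(int(rng.integers(lo, hi + 1)), params.gc_target, rng)
        parts.append(spacer)
        pos += len(spacer)
        reference = universe.reference[pham]
        protein = _mutate_protein(reference, params.within_pham_aa_divergence, rng)
        nt = _gene_nucleotide(
            protein, pham, int(pham[2:]) - 1, cluster_index, reference, gct,
            params, codon_cache, rng,
        )
        strand = "-" if g == reverse_slot else "+"
        genomic = str(Seq(nt).reverse_complement()) if strand == "-" else nt
        parts.append(genomic)
        genes.append(
            GeneRecord(
                gene_number=g + 1,
                start=pos + 1,
                end=pos + len(nt),
                strand=strand,
                nucleotide_seq=nt,
                protein_seq=protein,
                function_label="hypothetical protein",
            )
        )
        pos += len(nt)
    parts.append(_random_spacer(int(rng.integers(lo, hi + 1)), params.gc_target, rng))
    return AnnotatedGenome(
        name=name,
        sequence="".join(parts),
        genes=genes,
        host=host,
        original_cluster=original_cluster,
    )


# ---------------------------------------------------------------------------
# truth and population serialization


def write_truth(truth: SyntheticTruth, directory: str | Path) -> dict[str, Path]:
    """Write ground-truth TSVs (pham table, cluster labels, HGT implants,
    per-gene GC targets) into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    orphams = truth.orpham_phams()
    path = directory / "truth_phams.tsv"
    with path.open("w") as fh:
        fh.write("pham_id\tphage_name\tgene_number\torpham\n")
        for (phage, num), pham in sorted(truth.pham_of.items(), key=lambda kv: (kv[1], kv[0])):
            fh.write(f"{pham}\t{phage}\t{num}\t{int(pham in orphams)}\n")
    paths["phams"] = path

    path = directory / "truth_clusters.tsv"
    with path.open("w") as fh:
        fh.write("phage_name\ttrue_cluster\n")
        for phage in sorted(truth.cluster_of):
            fh.write(f"{phage}\t{truth.cluster_of[phage]}\n")
    paths["clusters"] = path

    path = directory / "truth_hgt.tsv"
    with path.open("w") as fh:
        fh.write("phage_name\tgene_number\tgc_offset\tn_extra_hosts\n")
        for phage, num, offset, n_extra in truth.hgt_genes:
            fh.write(f"{phage}\t{num}\t{offset}\t{n_extra}\n")
    paths["hgt"] = path

    path = directory / "truth_gc.tsv"
    with path.open("w") as fh:
        fh.write("phage_name\tgene_number\tgc_target\n")
        for (phage, num), gct in sorted(truth.gene_gc_target.items()):
            fh.write(f"{phage}\t{num}\t{gct}\n")
    paths["gc"] = path
    return paths


def read_truth(directory: str | Path, focal_phage: str = "") -> SyntheticTruth:
    """Load ground-truth TSVs written by :func:`write_truth`."""
    directory = Path(directory)
    pham_of: dict[GeneId, str] = {}
    with (directory / "truth_phams.tsv").open() as fh:
        next(fh)
        for line in fh:
            pham, phage, num, _orpham = line.rstrip("\n").split("\t")
            pham_of[(phage, int(num))] = pham
    cluster_of: dict[str, str] = {}
    with (directory / "truth_clusters.tsv").open() as fh:
        next(fh)
        for line in fh:
            phage, cluster = line.rstrip("\n").split("\t")
            cluster_of[phage] = cluster
    hgt: list[tuple[str, int, float, int]] = []
    with (directory / "truth_hgt.tsv").open() as fh:
        next(fh)
        for line in fh:
            phage, num, offset, n_extra = line.rstrip("\n").split("\t")
            hgt.append((phage, int(num), float(offset), int(n_extra)))
    gc: dict[GeneId, float] = {}
    with (directory / "truth_gc.tsv").open() as fh:
        next(fh)
        for line in fh:
            phage, num, gct = line.rstrip("\n").split("\t")
            gc[(phage, int(num))] = float(gct)
    return SyntheticTruth(
        pham_of=pham_of,
        cluster_of=cluster_of,
        hgt_genes=hgt,
        gene_gc_target=gc,
        focal_phage=focal_phage,
    )


def write_population(
    genomes: Sequence[AnnotatedGenome],
    metadata: PhageMetadataTable,
    truth: SyntheticTruth | None,
    directory: str | Path,
) -> dict[str, Path]:
    """Write a simulated population as FASTA + gene TSV + metadata TSV
    (the io_formats dialects), plus truth TSVs when provided."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["genomes"] = directory / "genomes.fasta"
    write_genome_fasta([(g.name, g.sequence) for g in genomes], paths["genomes"])
    paths["genes"] = directory / "genes.tsv"
    write_gene_table(genomes, paths["genes"])
    paths["metadata"] = directory / "metadata.tsv"
    write_metadata_table(metadata, paths["metadata"])
    if truth is not None:
        paths.update(write_truth(truth, directory))
    return paths
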