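"""End-to-end orchestration: phams -> GCS/GCD -> clustering -> tree/NEXUS
-> dot plots -> HGT report, from a single flat configuration.

Every stage writes its outputs under the configured output directory and
records its status in a machine-readable run manifest (inputs hashed,
package version, parameters, per-stage status).  A re-run with unchanged
inputs and configuration produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path

from . import __version__
from .clustering import cluster_by_gcs, cluster_report
from .dotplot import concatenated_dotplot
from .gene_content_stats import gcd_profile, gcs_matrix
from .hgt_evidence import evidence_dataframe, hgt_evidence_table
from .io_formats import (
    AnnotatedGenome,
    read_annotated_genome,
    read_gene_table,
    read_genome_fasta,
    read_metadata_table,
)
from .pham_assignment import assign_phams, membership_profile
from .phylogeny import export_nexus_distances, gcd_distance_matrix, neighbor_joining

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("phamflock")


@dataclass
class RunConfig:
    """Flat pipeline configuration; keys in a config file are dotted
    ``stage.parameter`` names (e.g. ``cluster.gcs_threshold = 35``)."""

    genomes_fasta: str = ""
    genes_tsv: str = ""
    metadata_tsv: str = ""
    output_dir: str = "phamflock_out"
    pham_identity_threshold: float = 35.0
    pham_coverage_threshold: float = 75.0
    gcs_threshold: float = 35.0
    nucleotide_word: int = 15
    protein_word: int = 5
    focal_phage: str = ""
    hgt_gc_delta: float = 5.0
    hgt_host_min: int = 3
    gap_from_zero: bool = True
    seed: int = 0

    _KEYMAP = {
        "io.genomes_fasta": "genomes_fasta",
        "io.genes_tsv": "genes_tsv",
        "io.metadata_tsv": "metadata_tsv",
        "io.output_dir": "output_dir",
        "pham.identity_threshold": "pham_identity_threshold",
        "pham.coverage_threshold": "pham_coverage_threshold",
        "cluster.gcs_threshold": "gcs_threshold",
        "dotplot.nucleotide_word": "nucleotide_word",
        "dotplot.protein_word": "protein_word",
        "stats.focal_phage": "focal_phage",
        "stats.gap_from_zero": "gap_from_zero",
        "hgt.gc_delta": "hgt_gc_delta",
        "hgt.host_min": "hgt_host_min",
        "run.seed": "seed",
    }

    def validate(self) -> None:
        for name in ("pham_identity_threshold", "pham_coverage_threshold", "gcs_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 100):
                raise ValueError(f"{name} must be in (0, 100], got {v}")
        if self.nucleotide_word < 1 or self.protein_word < 1:
            raise ValueError("word sizes must be >= 1")
        for name in ("genomes_fasta", "genes_tsv", "metadata_tsv"):
            path = getattr(self, name)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path!r} does not exist")


def load_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    """Read a flat ``key = value`` config file; ``overrides`` win."""
    config = RunConfig()
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in RunConfig._KEYMAP:
            raise ValueError(f"unknown config key: {key!r}")
        _set_typed(config, RunConfig._KEYMAP[key], value)
    for key, value in (overrides or {}).items():
        setattr(config, key, value)
    return config


def _set_typed(config: RunConfig, attr: str, raw: str) -> None:
    current = getattr(config, attr)
    if isinstance(current, bool):
        setattr(config, attr, raw.lower() in ("1", "true", "yes", "on"))
    elif isinstance(current, int):
        setattr(config, attr, int(raw))
    elif isinstance(current, float):
        setattr(config, attr, float(raw))
    else:
        setattr(config, attr, raw)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _load_genomes(config: RunConfig) -> list[AnnotatedGenome]:
    metadata = read_metadata_table(config.metadata_tsv)
    sequences = dict(read_genome_fasta(config.genomes_fasta))
    grouped = read_gene_table(config.genes_tsv)
    genomes = []
    for name in sequences:
        if name not in grouped:
            raise ValueError(f"genome {name!r} has no genes in {config.genes_tsv}")
        genome = read_annotated_genome(
            config.genes_tsv,
            config.genomes_fasta,
            name=name,
            host=metadata.host_of(name),
            original_cluster=metadata.cluster_of(name),
        )
        genomes.append(genome)
    return genomes


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in dependency order and return the manifest dict.

    A stage failure is recorded with its cause and downstream stages are
    skipped; the manifest is always written.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {k: v for k, v in asdict(config).items() if not k.startswith("_")},
        "stages": {},
    }
    failed = False

    def stage(name):
        # runs the stage body eagerly; the decorated name is bound to the
        # stage's return value (or None on failure/skip)
        def decorator(fn):
            nonlocal failed
            if failed:
                manifest["stages"][name] = {"status": "skipped"}
                return None
            try:
                logger.info("[%s] running", name)
                result = fn()
                manifest["stages"][name] = {"status": "ok"}
                return result
            except Exception as exc:  # noqa: BLE001 - recorded, not silenced
                logger.error("[%s] failed: %s", name, exc)
                manifest["stages"][name] = {"status": "failed", "cause": str(exc)}
                failed = True
                return None
        return decorator

    @stage("io")
    def _io():
        config.validate()
        manifest["inputs"] = {
            name: {"path": getattr(config, name), "sha256": _sha256(getattr(config, name))}
            for name in ("genomes_fasta", "genes_tsv", "metadata_tsv")
        }
        genomes = _load_genomes(config)
        metadata = read_metadata_table(config.metadata_tsv)
        manifest["n_phages"] = len(genomes)
        return genomes, metadata

    genomes, metadata = _io if _io is not None else (None, None)

    @stage("phams")
    def _phams():
        proteins = {
            (g.name, gene.gene_number): gene.protein_seq
            for g in genomes
            for gene in g.genes
        }
        assignment = assign_phams(
            proteins,
            identity_threshold=config.pham_identity_threshold,
            coverage_threshold=config.pham_coverage_threshold,
        )
        with (out / "phams.tsv").open("w") as fh:
            fh.write("pham_id\tphage_name\tgene_number\torpham\n")
            for pham_id, phage, num, orpham in assignment.to_table_rows():
                fh.write(f"{pham_id}\t{phage}\t{num}\t{orpham}\n")
        manifest["n_phams"] = len(assignment.phams)
        manifest["n_orphams"] = len(assignment.orphams)
        return assignment

    assignment = _phams

    @stage("gene_content")
    def _gene_content():
        profiles = {g.name: membership_profile(assignment, g.name) for g in genomes}
        matrix = gcs_matrix(profiles)
        matrix.to_csv(out / "gcs_matrix.csv")
        focal = config.focal_phage or sorted(profiles)[0]
        profile = gcd_profile(focal, profiles, gap_from_zero=config.gap_from_zero)
        profile.to_dataframe().round(6).to_csv(out / "gcd_profile.csv", index=False)
        manifest["focal_phage"] = focal
        manifest["max_gcd_gap"] = round(profile.max_gcd_gap, 2)
        manifest["gap_partner"] = profile.gap_partner
        return profiles, matrix

    profiles, matrix = _gene_content if _gene_content else (None, None)

    @stage("clustering")
    def _clustering():
        partition = cluster_by_gcs(matrix, threshold=config.gcs_threshold)
        partition.to_dataframe().to_csv(out / "clusters.tsv", sep="\t", index=False)
        report = cluster_report(partition, metadata)
        report.to_csv(out / "cluster_report.tsv", sep="\t", index=False)
        manifest["n_clusters"] = len(partition.clusters)
        manifest["cluster_sizes"] = sorted(
            (len(v) for v in partition.clusters.values()), reverse=True
        )
        manifest["n_changed"] = int(report["changed"].sum())
        return partition

    @stage("phylogeny")
    def _phylogeny():
        dm = gcd_distance_matrix(profiles)
        tree = neighbor_joining(dm)
        (out / "tree.nwk").write_text(tree.newick + "\n")
        (out / "distances.nex").write_text(export_nexus_distances(dm))

    @stage("dotplot")
    def _dotplot():
        ordered = sorted(genomes, key=lambda g: g.name)
        for level, word, tag in (
            ("genome", config.nucleotide_word, "nucleotide"),
            ("proteome", config.protein_word, "protein"),
        ):
            plot = concatenated_dotplot(ordered, level=level, word=word)
            plot.to_tsv(out / f"dotplot_{tag}.tsv")
            plot.boundaries_dataframe().to_csv(
                out / f"dotplot_{tag}_boundaries.tsv", sep="\t", index=False
            )

    @stage("hgt")
    def _hgt():
        focal = manifest.get("focal_phage") or sorted(g.name for g in genomes)[0]
        genome = next(g for g in genomes if g.name == focal)
        rows = hgt_evidence_table(
            genome,
            assignment,
            metadata,
            gc_delta=config.hgt_gc_delta,
            host_min=config.hgt_host_min,
        )
        evidence_dataframe(rows).to_csv(out / "hgt_evidence.tsv", sep="\t", index=False)
        manifest["n_hgt_flagged"] = sum(r.flagged for r in rows)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def configure_logging(verbosity: int = 0) -> None:
    level = logging.WARNING if verbosity < 0 else logging.INFO if verbosity == 0 else logging.DEBUG
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)
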