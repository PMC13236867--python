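"""Pipeline orchestration: stages, outputs and a reproducibility manifest.

Stages run in a fixed order (design -> [cluster] -> classify -> bgc ->
proximity -> annotate -> report); each enabled stage writes its table
into the output directory and registers itself in ``manifest.json``
together with the tool version, a configuration hash and input-file
checksums.  Re-running with identical inputs and configuration
reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .annotate import attach_annotations, prioritize, prioritized_rows
from .bgc import build_matrix, matrix_rows, species_long_rows, species_uniqueness, strain_concordance
from .classify import classification_rows, summarize, summary_rows
from .cluster import cluster_proteomes
from .design import read_design_file
from .io import (
    read_annotations,
    read_bgc_hits,
    read_gene_coordinates,
    read_orthogroups,
    read_protein_fasta,
    write_orthogroups_long,
    write_table,
)
from .proximity import chain_by_distance, proximity_rows, select_candidate_genes

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; hashed into the manifest."""

    design_path: str
    out_dir: str
    proteome_paths: dict[str, str] = field(default_factory=dict)  # strain -> FASTA
    gff_paths: dict[str, str] = field(default_factory=dict)       # strain -> GFF3
    orthogroups_path: str | None = None
    orthogroups_dialect: str = "long"
    bgc_path: str | None = None
    annotations_path: str | None = None
    min_score: float = 0.3
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    max_gap_bp: int = 5000
    keyword_sets: dict[str, list[str]] | None = None
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as e:
            raise ConfigError(str(e)) from None


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict

    @property
    def stages_run(self) -> list[str]:
        return [s["name"] for s in self.manifest["stages"] if s["status"] == "ok"]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages enabled by the supplied inputs.

    The cluster stage runs only when no external orthogroup table is
    given and proteomes are; BGC/proximity/annotate stages run when
    their inputs are present, and skipped stages are noted in the
    manifest.  Raises ConfigError for unusable configuration; stage
    errors propagate after being recorded in the manifest.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "twobytwo",
        "version": __version__,
        "config_hash": config.config_hash(),
        "inputs": {},
        "stages": [],
        "outputs": {},
    }

    def record_input(label: str, path: str | Path) -> None:
        manifest["inputs"][str(label)] = {"path": str(path), "sha256_16": _checksum(path)}

    def stage(name: str, status: str, **info) -> None:
        manifest["stages"].append({"name": name, "status": status, **info})

    def write_manifest() -> None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")

    try:
        # --- design -----------------------------------------------------
        record_input("design", config.design_path)
        design = read_design_file(config.design_path)
        stage("design", "ok", n_strains=len(design.strain_ids), n_species=len(design.species_ids))

        proteomes = None
        if config.proteome_paths:
            proteomes = {}
            for strain, path in sorted(config.proteome_paths.items()):
                record_input(f"proteome:{strain}", path)
                proteomes[strain] = {
                    r.protein_id: r.sequence for r in read_protein_fasta(path, strain)
                }

        # --- cluster (built-in, only without an external table) ---------
        if config.orthogroups_path:
            record_input("orthogroups", config.orthogroups_path)
            clusters, unassigned = read_orthogroups(
                config.orthogroups_path, config.orthogroups_dialect, design
            )
            stage("cluster", "skipped", reason="external orthogroup table supplied")
        elif proteomes:
            clusters, unassigned = cluster_proteomes(
                proteomes,
                min_score=config.min_score,
                matrix_name=config.matrix_name,
                gap_open=config.gap_open,
                gap_extend=config.gap_extend,
            )
            write_orthogroups_long(clusters, out / "orthogroups.tsv")
            manifest["outputs"]["orthogroups"] = "orthogroups.tsv"
            stage("cluster", "ok", n_clusters=len(clusters), n_singletons=len(unassigned))
        else:
            raise ConfigError("need either orthogroups_path or proteome_paths")

        # --- classify ---------------------------------------------------
        summary = summarize(clusters, unassigned, design, proteomes=proteomes)
        write_table(classification_rows(clusters, design), out / "classification.tsv",
                    columns=["cluster_id", "category", "subject", "size", "signature"])
        write_table(summary_rows(summary, design), out / "classification_summary.tsv",
                    columns=["scope", "entity", "metric", "count"])
        manifest["outputs"]["classification"] = "classification.tsv"
        manifest["outputs"]["classification_summary"] = "classification_summary.tsv"
        stage("classify", "ok", n_clusters=summary.n_clusters, core=summary.core_count)

        # --- bgc --------------------------------------------------------
        if config.bgc_path:
            record_input("bgc_hits", config.bgc_path)
            hits = read_bgc_hits(config.bgc_path, design)
            matrix = build_matrix(hits, design)
            write_table(matrix_rows(matrix), out / "bgc_matrix.tsv",
                        columns=["reference_id", *design.strain_ids, "species_count"])
            write_table(species_long_rows(matrix), out / "bgc_species.tsv",
                        columns=["reference_id", "species_id", "presence", "bin", "max_similarity"])
            uniq = species_uniqueness(matrix)
            conc_rows = []
            for sp in design.species_ids:
                shared, u1, u2, union = strain_concordance(matrix, sp)
                s1, s2 = design.strains_of(sp)
                conc_rows.append({"species_id": sp, "strain_1": s1, "strain_2": s2,
                                  "shared": shared, "unique_1": u1, "unique_2": u2,
                                  "union": union})
            write_table(conc_rows, out / "bgc_concordance.tsv",
                        columns=["species_id", "strain_1", "strain_2", "shared",
                                 "unique_1", "unique_2", "union"])
            write_table([uniq.as_row()], out / "bgc_uniqueness.tsv",
                        columns=["total_matched_references", "unique_to_single_species",
                                 "unique_pct"])
            manifest["outputs"]["bgc_matrix"] = "bgc_matrix.tsv"
            manifest["outputs"]["bgc_species"] = "bgc_species.tsv"
            manifest["outputs"]["bgc_concordance"] = "bgc_concordance.tsv"
            manifest["outputs"]["bgc_uniqueness"] = "bgc_uniqueness.tsv"
            stage("bgc", "ok", n_references=uniq.total_matched_references)
        else:
            stage("bgc", "skipped", reason="no BGC hit table supplied")

        # --- proximity --------------------------------------------------
        if config.gff_paths:
            all_chains = []
            skipped_total = 0
            for sp in design.species_ids:
                ref_strain = design.reference_strain(sp)
                gff = config.gff_paths.get(ref_strain)
                if gff is None:
                    continue
                record_input(f"gff:{ref_strain}", gff)
                coords = {c.gene_id: c for c in read_gene_coordinates(gff, ref_strain)}
                genes, skipped = select_candidate_genes(clusters, coords, design, sp)
                skipped_total += skipped
                all_chains.extend(chain_by_distance(genes, design, config.max_gap_bp))
            write_table(proximity_rows(all_chains), out / "proximity_clusters.tsv",
                        columns=["species_id", "strain_id", "contig", "span_start",
                                 "span_end", "n_genes", "gene_ids", "max_gap_observed"])
            manifest["outputs"]["proximity"] = "proximity_clusters.tsv"
            stage("proximity", "ok", n_chains=len(all_chains), skipped_genes=skipped_total)
        else:
            stage("proximity", "skipped", reason="no gene coordinates supplied")

        # --- annotate ---------------------------------------------------
        if config.annotations_path:
            record_input("annotations", config.annotations_path)
            records = read_annotations(config.annotations_path)
            annotated, skipped = attach_annotations(clusters, records, design)
            ranked = prioritize(annotated, config.keyword_sets)
            write_table(prioritized_rows(ranked), out / "prioritized_clusters.tsv",
                        columns=["cluster_id", "category", "subject", "matched_sets",
                                 "matched_keywords", "representative_score",
                                 "representative_description", "members"])
            manifest["outputs"]["prioritized"] = "prioritized_clusters.tsv"
            stage("annotate", "ok", n_ranked=len(ranked), skipped_records=skipped)
        else:
            stage("annotate", "skipped", reason="no annotation table supplied")

        stage("report", "ok")
    except Exception as e:
        stage("failed", "error", error=str(e))
        write_manifest()
        raise
    write_manifest()
    return PipelineResult(out_dir=out, manifest=manifest)
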