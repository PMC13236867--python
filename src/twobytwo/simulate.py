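"""Synthetic two-by-two datasets with known truth.

Generates proteomes, gene coordinates, orthogroup tables, BGC hit
tables and annotation tables carrying exactly the statistical
structure the two-by-two analysis assumes: planted core /
species-specific / strain-specific families with controlled divergence
between strains, species and taxonomy families; gene layouts with
planted physical clusters satisfying the proximity gap rule (and all
other adjacent gaps exceeding it); and BGC reference profiles with
controlled strain/species overlap.  Every stage of the pipeline is
therefore testable against ground truth without downloading anything.

Sequence model: family root sequences are independent uniform draws
over the 20-residue alphabet; descendants substitute each site
independently with probability equal to the level rate (a uniformly
chosen different residue), no indels.  All randomness flows from one
integer seed; per-purpose sub-streams are derived with fixed offsets
so, e.g., adding a species does not perturb earlier strains' data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .classify import Category, classify_cluster
from .cluster import OrthoCluster, ProteinKey
from .design import TwoByTwoDesign, load_design, write_design_file
from .io import (
    AnnotationRecord,
    BgcRegionHit,
    GeneCoordinate,
    ProteinRecord,
    write_annotations,
    write_bgc_hits,
    write_orthogroups_long,
    write_protein_fasta,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

SINGLETON = "SINGLETON"


@dataclass
class BgcProfile:
    """One synthetic BGC reference: who carries it and how similar."""

    reference_id: str
    carriers: list[tuple[str, str]]  # (species_id, strain_id or "both")
    similarity_mean: float = 80.0
    similarity_sd: float = 10.0
    cluster_type: str = "NRPS"


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults define the standard test conditions.

    Divergence rates are expected substitutions per site on each branch
    of the family tree: between the two strains of a species (strain),
    between species ancestors (species), and between taxonomy-family
    ancestors on core-family lineages (family); they must be ordered
    strain < species < family.  Defaults (0.02 / 0.10 / 0.45) give wide
    separation between within-species similarity and unrelated-sequence
    noise relative to the clustering threshold.
    """

    n_species: int = 3
    species_families: Sequence[str] | None = None  # taxonomy family per species
    n_core_families: int = 20
    n_species_specific: int = 20     # per species
    n_strain_specific: int = 20      # per strain
    n_singletons: int = 20           # per strain
    paralog_probability: float = 0.1
    strain_rate: float = 0.02
    species_rate: float = 0.10
    family_rate: float = 0.45
    seq_length_mean: float = 120.0
    seq_length_sd: float = 20.0
    min_seq_length: int = 50
    genes_per_contig: int = 25
    intergene_gap_low: int = 5500    # > proximity threshold: no accidental chains
    intergene_gap_high: int = 15000
    n_planted_proximity: int = 2     # per species, placed in its reference strain
    planted_cluster_size: int = 3
    planted_gap_low: int = 200
    planted_gap_high: int = 4500     # <= proximity threshold
    bgc_profiles: list[BgcProfile] | None = None
    n_unmatched_regions: int = 2     # per strain, regions with no known reference
    seed: int = 1

    def validate(self) -> None:
        counts = [
            self.n_species, self.n_core_families, self.n_species_specific,
            self.n_strain_specific, self.n_singletons, self.n_planted_proximity,
            self.planted_cluster_size, self.n_unmatched_regions,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_species < 2:
            raise ValueError("need at least 2 species for a two-by-two design")
        if not 0.0 <= self.paralog_probability <= 1.0:
            raise ValueError("paralog_probability outside [0,1]")
        if not (self.strain_rate < self.species_rate < self.family_rate):
            raise ValueError("divergence rates must be ordered strain < species < family")
        if self.n_planted_proximity and self.planted_cluster_size > self.genes_per_contig:
            raise ValueError("planted cluster longer than a contig")
        if self.n_planted_proximity * self.planted_cluster_size > self.n_species_specific:
            raise ValueError(
                "planted proximity clusters need more species-specific families than simulated"
            )


@dataclass(frozen=True)
class TruthFamily:
    family_id: str
    category: str          # CORE / SPECIES_SELF / STRAIN_SELF / SINGLETON
    subject: str           # species or strain for the self categories
    members: frozenset[ProteinKey]


@dataclass(frozen=True)
class PlantedProximity:
    species_id: str
    strain_id: str
    contig: str
    gene_ids: tuple[str, ...]
    family_ids: tuple[str, ...]


@dataclass
class TruthTable:
    families: list[TruthFamily]
    proximity: list[PlantedProximity]
    bgc_presence: dict[str, set[str]]  # reference -> species present

    def families_by_category(self, category: str) -> list[TruthFamily]:
        return [f for f in self.families if f.category == category]


@dataclass
class SimulatedBundle:
    params: SimulationParams
    design: TwoByTwoDesign
    proteomes: dict[str, dict[str, str]]                 # strain -> pid -> seq
    coordinates: dict[str, dict[str, GeneCoordinate]]    # strain -> gene -> coord
    orthogroups: list[OrthoCluster]                      # truth composition table
    bgc_hits: list[BgcRegionHit]
    annotations: list[AnnotationRecord]
    truth: TruthTable


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution with a uniformly chosen different residue."""
    if rate <= 0:
        return seq.copy()
    hit = rng.random(seq.size) < rate
    if not hit.any():
        return seq.copy()
    out = seq.copy()
    # shift by 1..19 positions in the alphabet: always a different residue
    idx = np.searchsorted(AMINO_ACIDS, out[hit])
    shift = rng.integers(1, AMINO_ACIDS.size, size=int(hit.sum()))
    out[hit] = AMINO_ACIDS[(idx + shift) % AMINO_ACIDS.size]
    return out


def _random_seq(rng: np.random.Generator, params: SimulationParams) -> np.ndarray:
    n = max(params.min_seq_length, int(round(rng.normal(params.seq_length_mean, params.seq_length_sd))))
    return AMINO_ACIDS[rng.integers(0, AMINO_ACIDS.size, size=n)]


def _to_str(seq: np.ndarray) -> str:
    return "".join(seq.tolist())


def default_design(params: SimulationParams) -> TwoByTwoDesign:
    fams = list(params.species_families or [])
    rows = []
    for i in range(params.n_species):
        sp = f"species{i + 1}"
        fam = fams[i] if i < len(fams) else "simfam1"
        for j in (1, 2):
            rows.append(
                {
                    "strain_id": f"{sp}_s{j}",
                    "species_id": sp,
                    "family_id": fam,
                    "display_name": f"{sp} strain {j}",
                    "is_reference": "1" if j == 1 else "0",
                }
            )
    return load_design(rows)


def simulate_dataset(params: SimulationParams) -> SimulatedBundle:
    """Generate a full dataset bundle; deterministic given ``params.seed``."""
    params.validate()
    design = default_design(params)
    seed = int(params.seed)

    proteomes: dict[str, dict[str, str]] = {s: {} for s in design.strain_ids}
    families: list[TruthFamily] = []
    # per-species bookkeeping for planted proximity clusters
    species_specific_ids: dict[str, list[str]] = {sp: [] for sp in design.species_ids}

    def add_member(strain: str, pid: str, seq: np.ndarray) -> ProteinKey:
        proteomes[strain][pid] = _to_str(seq)
        return (strain, pid)

    # --- core families -------------------------------------------------
    rng = np.random.default_rng([seed, 1])
    multi_family = len(set(s.family_id for s in design.strains)) > 1
    for k in range(params.n_core_families):
        fid = f"fam_core_{k + 1:04d}"
        root = _random_seq(rng, params)
        members = []
        fam_anc: dict[str, np.ndarray] = {}
        for sp in design.species_ids:
            tax_fam = next(s.family_id for s in design.strains if s.species_id == sp)
            if multi_family:
                if tax_fam not in fam_anc:
                    fam_anc[tax_fam] = _mutate(root, params.family_rate, rng)
                base = fam_anc[tax_fam]
            else:
                base = root
            sp_anc = _mutate(base, params.species_rate, rng)
            for strain in design.strains_of(sp):
                seq = _mutate(sp_anc, params.strain_rate, rng)
                members.append(add_member(strain, fid, seq))
                if rng.random() < params.paralog_probability:
                    members.append(add_member(strain, f"{fid}.2", _mutate(seq, params.strain_rate, rng)))
        families.append(TruthFamily(fid, Category.CORE.value, "", frozenset(members)))

    # --- species-specific families ------------------------------------
    for si, sp in enumerate(design.species_ids):
        rng = np.random.default_rng([seed, 2, si])
        for k in range(params.n_species_specific):
            fid = f"fam_sp_{sp}_{k + 1:04d}"
            species_specific_ids[sp].append(fid)
            root = _random_seq(rng, params)
            members = []
            for strain in design.strains_of(sp):
                seq = _mutate(root, params.strain_rate, rng)
                members.append(add_member(strain, fid, seq))
                if rng.random() < params.paralog_probability:
                    members.append(add_member(strain, f"{fid}.2", _mutate(seq, params.strain_rate, rng)))
            families.append(TruthFamily(fid, Category.SPECIES_SELF.value, sp, frozenset(members)))

    # --- strain-specific paralog families and singletons ---------------
    for ti, strain in enumerate(design.strain_ids):
        rng = np.random.default_rng([seed, 3, ti])
        for k in range(params.n_strain_specific):
            fid = f"fam_st_{strain}_{k + 1:04d}"
            root = _random_seq(rng, params)
            members = [
                add_member(strain, f"{fid}.{i + 1}", _mutate(root, params.strain_rate, rng))
                for i in range(2)
            ]
            families.append(TruthFamily(fid, Category.STRAIN_SELF.value, strain, frozenset(members)))
        for k in range(params.n_singletons):
            fid = f"singleton_{strain}_{k + 1:04d}"
            key = add_member(strain, fid, _random_seq(rng, params))
            families.append(TruthFamily(fid, SINGLETON, strain, frozenset([key])))

    orthogroups = [
        OrthoCluster(cluster_id=f.family_id, members=f.members)
        for f in sorted(families, key=lambda f: f.family_id)
        if len(f.members) >= 2
    ]

    coordinates, planted = _layout_genomes(params, design, proteomes, species_specific_ids, seed)
    bgc_hits, bgc_presence = _simulate_bgc(params, design, seed)
    annotations = _simulate_annotations(params, design, species_specific_ids, seed)

    truth = TruthTable(families=families, proximity=planted, bgc_presence=bgc_presence)
    return SimulatedBundle(
        params=params,
        design=design,
        proteomes=proteomes,
        coordinates=coordinates,
        orthogroups=orthogroups,
        bgc_hits=bgc_hits,
        annotations=annotations,
        truth=truth,
    )


def _layout_genomes(
    params: SimulationParams,
    design: TwoByTwoDesign,
    proteomes: dict[str, dict[str, str]],
    species_specific_ids: dict[str, list[str]],
    seed: int,
) -> tuple[dict[str, dict[str, GeneCoordinate]], list[PlantedProximity]]:
    """Place genes on contigs so planted clusters obey the gap rule.

    Layout units are single genes plus planted blocks of consecutive
    species-specific genes; gaps inside a block stay at or below the
    proximity threshold, every other adjacent gap exceeds it, and a
    block never straddles a contig boundary.
    """
    coordinates: dict[str, dict[str, GeneCoordinate]] = {}
    planted: list[PlantedProximity] = []
    for ti, strain in enumerate(design.strain_ids):
        rng = np.random.default_rng([seed, 4, ti])
        species = design.species_of(strain)
        is_ref = design.reference_strain(species) == strain
        blocks: list[list[str]] = []
        in_block: set[str] = set()
        if is_ref and params.n_planted_proximity:
            fams = species_specific_ids[species]
            for b in range(params.n_planted_proximity):
                fam_slice = fams[
                    b * params.planted_cluster_size : (b + 1) * params.planted_cluster_size
                ]
                block = [fid for fid in fam_slice if fid in proteomes[strain]]
                if len(block) >= 2:
                    blocks.append(block)
                    in_block.update(block)

        singles = [pid for pid in sorted(proteomes[strain]) if pid not in in_block]
        units: list[list[str]] = [[p] for p in singles] + [list(b) for b in blocks]
        order = rng.permutation(len(units))
        units = [units[i] for i in order]

        coords: dict[str, GeneCoordinate] = {}
        contig_i, genes_on_contig, cursor = 1, 0, 1
        for unit in units:
            if genes_on_contig and genes_on_contig + len(unit) > params.genes_per_contig:
                contig_i += 1
                genes_on_contig, cursor = 0, 1
            contig = f"{strain}_contig{contig_i}"
            for j, pid in enumerate(unit):
                if j > 0:
                    gap = int(rng.integers(params.planted_gap_low, params.planted_gap_high + 1))
                    cursor += gap + 1
                glen = 3 * len(proteomes[strain][pid])
                strand = "+" if rng.random() < 0.5 else "-"
                coords[pid] = GeneCoordinate(strain, pid, contig, cursor, cursor + glen - 1, strand)
                cursor += glen
                genes_on_contig += 1
            cursor += int(rng.integers(params.intergene_gap_low, params.intergene_gap_high + 1))
        coordinates[strain] = coords
        for unit in units:
            if len(unit) > 1:
                ordered = sorted(unit, key=lambda pid: coords[pid].start)
                planted.append(
                    PlantedProximity(
                        species_id=species,
                        strain_id=strain,
                        contig=coords[ordered[0]].contig,
                        gene_ids=tuple(ordered),
                        family_ids=tuple(ordered),  # gene id == family id for planted genes
                    )
                )
    return coordinates, planted


def default_bgc_profiles(design: TwoByTwoDesign, rng: np.random.Generator) -> list[BgcProfile]:
    """A mix of species-unique, group-wide and one-strain-only references."""
    profiles = []
    types = ["NRPS", "T1PKS", "terpene", "NRPS-like"]
    i = 0
    for sp in design.species_ids:
        for k in range(3):
            i += 1
            profiles.append(
                BgcProfile(f"REF{i:04d}", [(sp, "both")], 80.0, 10.0, types[i % len(types)])
            )
    for k in range(2):
        i += 1
        profiles.append(
            BgcProfile(
                f"REF{i:04d}", [(sp, "both") for sp in design.species_ids], 70.0, 15.0,
                types[i % len(types)],
            )
        )
    for sp in design.species_ids:
        i += 1
        one = design.strains_of(sp)[int(rng.integers(0, 2))]
        profiles.append(BgcProfile(f"REF{i:04d}", [(sp, one)], 60.0, 15.0, types[i % len(types)]))
    return profiles


def _simulate_bgc(
    params: SimulationParams, design: TwoByTwoDesign, seed: int
) -> tuple[list[BgcRegionHit], dict[str, set[str]]]:
    rng = np.random.default_rng([seed, 5])
    profiles = params.bgc_profiles or default_bgc_profiles(design, rng)
    hits: list[BgcRegionHit] = []
    presence: dict[str, set[str]] = {}
    cursors = {st: 1 for st in design.strain_ids}

    def add_region(strain: str, ref: str, sim: int, ctype: str) -> None:
        length = int(rng.integers(20000, 40001))
        start = cursors[strain]
        hits.append(
            BgcRegionHit(strain, f"{strain}_bgc_scaffold", start, start + length - 1, ctype, ref, sim)
        )
        cursors[strain] = start + length + int(rng.integers(5000, 20001))

    for p in profiles:
        presence[p.reference_id] = set()
        for sp, which in p.carriers:
            strains = design.strains_of(sp) if which == "both" else (which,)
            presence[p.reference_id].add(sp)
            for st in strains:
                sim = int(np.clip(round(rng.normal(p.similarity_mean, p.similarity_sd)), 1, 100))
                add_region(st, p.reference_id, sim, p.cluster_type)
    for st in design.strain_ids:
        for _ in range(params.n_unmatched_regions):
            add_region(st, "", 0, "unknown")
    return hits, presence


_KEYWORD_DESCRIPTIONS = [
    ("Cuticle-degrading protease PR1", 85.0),
    ("Nonribosomal peptide synthetase", 78.0),
    ("Insecticidal toxin complex subunit", 90.0),
    ("Scytalone dehydratase-like protein", 70.0),
    ("ABC transporter", 60.0),
]


def _simulate_annotations(
    params: SimulationParams,
    design: TwoByTwoDesign,
    species_specific_ids: dict[str, list[str]],
    seed: int,
) -> list[AnnotationRecord]:
    """Homology/domain/signal-peptide records with planted keyword hits.

    The first few species-specific families of every species receive
    descriptions containing prioritization keywords; scores get small
    deterministic jitter so ranking is exercised.
    """
    rng = np.random.default_rng([seed, 6])
    records: list[AnnotationRecord] = []
    for sp in design.species_ids:
        for k, fid in enumerate(species_specific_ids[sp][: len(_KEYWORD_DESCRIPTIONS)]):
            desc, score = _KEYWORD_DESCRIPTIONS[k % len(_KEYWORD_DESCRIPTIONS)]
            for strain in design.strains_of(sp):
                records.append(
                    AnnotationRecord(
                        strain_id=strain,
                        protein_id=fid,
                        source="homology",
                        hit_id=f"SP{k + 1:05d}",
                        description=desc,
                        score=round(score + float(rng.normal(0, 3)), 2),
                    )
                )
                records.append(
                    AnnotationRecord(
                        strain_id=strain,
                        protein_id=fid,
                        source="domain",
                        hit_id=f"IPR{k + 1:06d}",
                        description="synthetic domain",
                        score=1.0,
                    )
                )
                if k == 0:
                    records.append(
                        AnnotationRecord(
                            strain_id=strain,
                            protein_id=fid,
                            source="signal_peptide",
                            hit_id="SP",
                            description="signal peptide predicted",
                            score=1.0,
                        )
                    )
    return records


def write_bundle(bundle: SimulatedBundle, outdir: str | Path) -> None:
    """Write the bundle as plain-text files (the simulate CLI output)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_design_file(bundle.design, outdir / "design.tsv")
    for strain, prots in bundle.proteomes.items():
        recs = [ProteinRecord(strain, pid, seq) for pid, seq in sorted(prots.items())]
        write_protein_fasta(recs, outdir / f"{strain}.faa")
        coords = bundle.coordinates[strain]
        lines = ["##gff-version 3"]
        for pid in sorted(coords, key=lambda p: (coords[p].contig, coords[p].start)):
            c = coords[pid]
            lines.append(
                f"{c.contig}\tsim\tgene\t{c.start}\t{c.end}\t.\t{c.strand}\t.\tID={pid}"
            )
        (outdir / f"{strain}.gff3").write_text("\n".join(lines) + "\n")
    write_orthogroups_long(bundle.orthogroups, outdir / "orthogroups.tsv")
    write_bgc_hits(bundle.bgc_hits, outdir / "bgc_hits.tsv")
    write_annotations(bundle.annotations, outdir / "annotations.tsv")
    truth = {
        "families": [
            {
                "family_id": f.family_id,
                "category": f.category,
                "subject": f.subject,
                "members": sorted(f"{s}|{p}" for s, p in f.members),
            }
            for f in bundle.truth.families
        ],
        "proximity": [asdict(p) for p in bundle.truth.proximity],
        "bgc_presence": {k: sorted(v) for k, v in bundle.truth.bgc_presence.items()},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, default=list) + "\n")


@dataclass
class RecoveryReport:
    """Exact-match precision/recall per category plus planted-cluster flags."""

    precision: dict[str, float]
    recall: dict[str, float]
    n_truth: dict[str, int]
    n_predicted: dict[str, int]
    proximity_results: list[dict]

    def proximity_conditional_ok(self) -> bool:
        """True iff every planted cluster whose families were recovered
        was itself recovered exactly."""
        return all(
            r["chain_exact"] for r in self.proximity_results if r["families_recovered"]
        )


def evaluate_recovery(
    truth: TruthTable,
    clusters: Sequence[OrthoCluster],
    singleton_proteins: Sequence[ProteinKey],
    design: TwoByTwoDesign,
    proximity_chains: Sequence | None = None,
) -> RecoveryReport:
    """Score a classification (and optional proximity run) against truth.

    A truth family is recovered iff some predicted cluster has exactly
    its member set and the matching category; singleton truth entries
    match entries of the singleton list.  Precision and recall default
    to 1.0 for categories with nothing predicted / no truth.
    """
    cats = [Category.CORE.value, Category.SPECIES_SELF.value, Category.STRAIN_SELF.value, SINGLETON]
    truth_by_cat: dict[str, set[frozenset[ProteinKey]]] = {c: set() for c in cats}
    for f in truth.families:
        truth_by_cat.setdefault(f.category, set()).add(f.members)

    pred_by_cat: dict[str, set[frozenset[ProteinKey]]] = {c: set() for c in cats}
    pred_other = 0
    for c in clusters:
        label = classify_cluster(c, design).label.value
        if label in pred_by_cat:
            pred_by_cat[label].add(c.members)
        else:
            pred_other += 1
    for key in singleton_proteins:
        pred_by_cat[SINGLETON].add(frozenset([key]))

    precision, recall, n_truth, n_pred = {}, {}, {}, {}
    recovered_families: set[str] = set()
    member_index = {f.members: f.family_id for f in truth.families}
    for cat in cats:
        t, p = truth_by_cat[cat], pred_by_cat[cat]
        tp = t & p
        for m in tp:
            recovered_families.add(member_index[m])
        precision[cat] = len(tp) / len(p) if p else 1.0
        recall[cat] = len(tp) / len(t) if t else 1.0
        n_truth[cat], n_pred[cat] = len(t), len(p)

    prox_results = []
    if proximity_chains is not None:
        found = {
            (ch.strain_id, ch.contig, tuple(ch.gene_ids)) for ch in proximity_chains
        }
        for planted in truth.proximity:
            fams_ok = all(fid in recovered_families for fid in planted.family_ids)
            exact = (planted.strain_id, planted.contig, planted.gene_ids) in found
            prox_results.append(
                {
                    "species_id": planted.species_id,
                    "strain_id": planted.strain_id,
                    "gene_ids": planted.gene_ids,
                    "families_recovered": fams_ok,
                    "chain_exact": exact,
                }
            )
    return RecoveryReport(precision, recall, n_truth, n_pred, prox_results)
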