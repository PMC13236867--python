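"""Bundled worked example: a published 16-strain Hypocreales survey.

Two curated plain-text tables ship with the package:

* a 16-strain / 8-species / 3-family two-by-two design covering
  entomopathogenic and mycoparasitic Hypocreales (Beauveria,
  Cordyceps, Metarhizium, Epichloe, Trichoderma), and
* 19 species-self ortholog clusters from that survey whose products
  (oosporein, cordycepin, swainsonine, sorbicillinoid and verlamelin
  biosynthesis proteins, cuticle-degrading proteases, ...) were
  previously demonstrated to be species-specific — the positive
  controls that validate the classification rules.

Also provided programmatically: the Cordyceps javanica BGC concordance
example, where 15 references match at least one strain, 11 replicate
in both strains and 2 are unique to each — the expected signature of
real presence calls surviving very different assembly qualities.
"""

from __future__ import annotations

from importlib import resources

from .cluster import OrthoCluster
from .design import TwoByTwoDesign, load_design
from .io import AnnotationRecord, BgcRegionHit, parse_member_list


def _data_text(name: str) -> str:
    return (resources.files("twobytwo.data") / name).read_text()


def hypocreales_design() -> TwoByTwoDesign:
    """The 16-strain, 8-species, 3-family Hypocreales design."""
    lines = _data_text("hypocreales_design.tsv").splitlines()
    header = lines[0].split("\t")
    rows = [dict(zip(header, ln.split("\t"))) for ln in lines[1:] if ln.strip()]
    return load_design(rows)


def curated_species_self_clusters() -> tuple[list[OrthoCluster], list[AnnotationRecord]]:
    """The 19 curated species-self clusters with their homology hits.

    Returns the clusters (member lists exactly as published) and
    per-member homology annotation records derived from the curated
    Swiss-Prot hits ("No hit" rows produce no record).
    """
    lines = _data_text("hypocreales_species_self_clusters.tsv").splitlines()
    header = lines[0].split("\t")
    clusters: list[OrthoCluster] = []
    annotations: list[AnnotationRecord] = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        row = dict(zip(header, ln.split("\t")))
        members = parse_member_list(row["members"])
        clusters.append(OrthoCluster(cluster_id=row["cluster_id"], members=members))
        if row["swissprot_hit"]:
            for strain, pid in sorted(members):
                annotations.append(
                    AnnotationRecord(
                        strain_id=strain,
                        protein_id=pid,
                        source="homology",
                        hit_id=row["swissprot_hit"],
                        description=row["protein_name"],
                        score=1.0,
                    )
                )
    return clusters, annotations


def javanica_concordance_hits() -> list[BgcRegionHit]:
    """BGC hits reproducing the C. javanica strain-concordance pattern.

    15 matched references across the two strains: CJ_REF01..CJ_REF11 in
    both, CJ_REF12/13 only in Apopka 97, CJ_REF14/15 only in IJ2G.
    Region coordinates are synthetic placeholders; only presence enters
    the concordance computation.
    """
    hits = []
    pos = {"Cj_Apopka97": 1, "Cj_IJ2G": 1}

    def add(strain: str, ref: str) -> None:
        start = pos[strain]
        hits.append(
            BgcRegionHit(
                strain_id=strain,
                contig=f"{strain}_scaffold1",
                start=start,
                end=start + 24999,
                cluster_type="NRPS",
                reference_id=ref,
                similarity_pct=80,
            )
        )
        pos[strain] = start + 30000

    for i in range(1, 12):
        add("Cj_Apopka97", f"CJ_REF{i:02d}")
        add("Cj_IJ2G", f"CJ_REF{i:02d}")
    for i in (12, 13):
        add("Cj_Apopka97", f"CJ_REF{i:02d}")
    for i in (14, 15):
        add("Cj_IJ2G", f"CJ_REF{i:02d}")
    return hits
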