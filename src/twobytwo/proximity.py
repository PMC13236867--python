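"""Chain species-unique genes within 5 kb into putative novel clusters.

Secondary-metabolite genes in fungi are physically clustered, so
species-unique genes that sit close together on one contig are strong
candidates for novel biosynthetic gene clusters that rule-based BGC
predictors miss.  Genes from a species' self-clusters are mapped back
to the genome of a designated reference strain and chained by
single-linkage whenever adjacent inter-gene gaps are <= 5 kb
(configurable, inclusive threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .classify import Category, classify_cluster
from .cluster import OrthoCluster
from .design import TwoByTwoDesign
from .io import GeneCoordinate


@dataclass(frozen=True)
class ProximityCluster:
    """A maximal chain of nearby species-unique genes on one contig."""

    species_id: str
    strain_id: str
    contig: str
    gene_ids: tuple[str, ...]  # ordered by start
    span_start: int
    span_end: int
    max_gap_observed: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def select_candidate_genes(
    clusters: Sequence[OrthoCluster],
    coordinates: Mapping[str, GeneCoordinate],
    design: TwoByTwoDesign,
    species: str,
    strain: str | None = None,
) -> tuple[list[GeneCoordinate], int]:
    """Species-self cluster members of one species, with coordinates.

    Restricted to the designated reference strain (``strain`` overrides
    the design's default).  ``coordinates`` maps gene/protein ID to its
    :class:`GeneCoordinate` for that strain.  Returns the located genes
    and the count of members skipped for lack of coordinates.
    """
    if species not in design.species_ids:
        raise ValueError(f"unknown species {species!r}")
    strain = strain or design.reference_strain(species)
    genes: list[GeneCoordinate] = []
    skipped = 0
    seen: set[str] = set()
    for c in clusters:
        cat = classify_cluster(c, design)
        if cat.label is not Category.SPECIES_SELF or cat.subject != species:
            continue
        for member_strain, pid in c.sorted_members():
            if member_strain != strain or pid in seen:
                continue
            seen.add(pid)
            coord = coordinates.get(pid)
            if coord is None:
                skipped += 1
            else:
                genes.append(coord)
    return genes, skipped


def chain_by_distance(
    genes: Sequence[GeneCoordinate],
    design: TwoByTwoDesign,
    max_gap_bp: int = 5000,
) -> list[ProximityCluster]:
    """Single-linkage chaining of genes per contig.

    Genes are sorted by start per contig; successive genes join the
    same chain iff the gap (next.start - prev.end - 1, negative when
    overlapping) is <= ``max_gap_bp``.  Strand is ignored.  Only chains
    of >= 2 genes are emitted, ordered by (contig, span_start).  Chains
    are maximal by construction and a chain's total span may exceed the
    gap threshold — the rule is pairwise-adjacent.
    """
    if max_gap_bp <= 0:
        raise ValueError("max_gap_bp must be positive")
    by_contig: dict[tuple[str, str], list[GeneCoordinate]] = {}
    for g in genes:
        by_contig.setdefault((g.strain_id, g.contig), []).append(g)

    out: list[ProximityCluster] = []
    for (strain, contig), glist in by_contig.items():
        glist = sorted(glist, key=lambda g: (g.start, g.end, g.gene_id))
        chain: list[GeneCoordinate] = []
        max_end = 0
        max_gap = 0
        for g in glist:
            if not chain:
                chain, max_end, max_gap = [g], g.end, 0
                continue
            gap = g.start - max_end - 1
            if gap <= max_gap_bp:
                chain.append(g)
                max_gap = max(max_gap, gap)
                max_end = max(max_end, g.end)
            else:
                out.extend(_emit(chain, design, max_gap))
                chain, max_end, max_gap = [g], g.end, 0
        out.extend(_emit(chain, design, max_gap))
    return sorted(out, key=lambda c: (c.strain_id, c.contig, c.span_start, c.span_end))


def _emit(
    chain: list[GeneCoordinate], design: TwoByTwoDesign, max_gap: int
) -> list[ProximityCluster]:
    if len(chain) < 2:
        return []
    strain = chain[0].strain_id
    return [
        ProximityCluster(
            species_id=design.species_of(strain),
            strain_id=strain,
            contig=chain[0].contig,
            gene_ids=tuple(g.gene_id for g in chain),
            span_start=min(g.start for g in chain),
            span_end=max(g.end for g in chain),
            max_gap_observed=max_gap,
        )
    ]


def proximity_rows(chains: Sequence[ProximityCluster]) -> list[dict]:
    return [
        {
            "species_id": c.species_id,
            "strain_id": c.strain_id,
            "contig": c.contig,
            "span_start": c.span_start,
            "span_end": c.span_end,
            "n_genes": c.n_genes,
            "gene_ids": ";".join(c.gene_ids),
            "max_gap_observed": c.max_gap_observed,
        }
        for c in chains
    ]


def to_bed_lines(chains: Sequence[ProximityCluster]) -> list[str]:
    """BED export (0-based half-open) for genome-browser viewing."""
    return [
        f"{c.contig}\t{c.span_start - 1}\t{c.span_end}\t"
        f"{c.species_id}_chain_{i + 1}\t{c.n_genes}\t."
        for i, c in enumerate(chains)
    ]
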