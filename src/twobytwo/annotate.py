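"""Join functional annotations onto clusters and rank by keyword relevance.

Annotations (homology hits, domain IDs, signal-peptide calls) are
consumed as precomputed tables.  Prioritization is a transparent,
configurable case-insensitive substring search over the homology-hit
descriptions — an explicit heuristic for shortlisting clusters likely
tied to pathogenesis, antibiotic production or distinctive catabolism,
not a stand-in for expert curation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .classify import ClusterCategory, classify_cluster
from .cluster import OrthoCluster, ProteinKey
from .design import TwoByTwoDesign
from .io import AnnotationRecord

NO_HIT = "No hit"

DEFAULT_KEYWORD_SETS: dict[str, list[str]] = {
    "pathogenesis": ["toxin", "protease", "serpin", "virulence", "cuticle", "appressori"],
    "biosynthesis": ["synthase", "synthetase", "polyketide", "dehydratase", "oxidoreductase",
                     "dioxygenase", "hydroxylase"],
    "transport": ["transporter", "permease", "efflux"],
}


@dataclass
class AnnotatedCluster:
    cluster_id: str
    category: ClusterCategory
    members: tuple[ProteinKey, ...]
    homology: dict[ProteinKey, AnnotationRecord] = field(default_factory=dict)
    domains: dict[ProteinKey, tuple[str, ...]] = field(default_factory=dict)
    signal_peptide: dict[ProteinKey, bool] = field(default_factory=dict)

    @property
    def representative(self) -> AnnotationRecord | None:
        """Best-scoring homology hit (tie -> lexicographic hit_id)."""
        hits = list(self.homology.values())
        if not hits:
            return None
        return min(hits, key=lambda h: (-h.score, h.hit_id))

    @property
    def representative_description(self) -> str:
        rep = self.representative
        return rep.description if rep is not None else NO_HIT

    def member_description(self, member: ProteinKey) -> str:
        rec = self.homology.get(member)
        return rec.description if rec is not None else NO_HIT


def attach_annotations(
    clusters: Sequence[OrthoCluster],
    records: Sequence[AnnotationRecord],
    design: TwoByTwoDesign,
) -> tuple[list[AnnotatedCluster], int]:
    """Annotate every cluster; members without hits carry "No hit".

    For a member with several homology records the best score wins.
    Records referencing proteins in no cluster are skipped; their count
    is returned so dataset-scale mismatches are visible.  Clusters are
    never dropped or duplicated.
    """
    member_to_cluster: dict[ProteinKey, AnnotatedCluster] = {}
    out = []
    for c in clusters:
        ac = AnnotatedCluster(
            cluster_id=c.cluster_id,
            category=classify_cluster(c, design),
            members=tuple(c.sorted_members()),
        )
        out.append(ac)
        for m in ac.members:
            member_to_cluster[m] = ac

    skipped = 0
    for rec in records:
        key = (rec.strain_id, rec.protein_id)
        ac = member_to_cluster.get(key)
        if ac is None:
            skipped += 1
            continue
        if rec.source == "homology":
            cur = ac.homology.get(key)
            if cur is None or rec.score > cur.score or (
                rec.score == cur.score and rec.hit_id < cur.hit_id
            ):
                ac.homology[key] = rec
        elif rec.source == "domain":
            ac.domains[key] = tuple(sorted(set(ac.domains.get(key, ())) | {rec.hit_id}))
        elif rec.source == "signal_peptide":
            ac.signal_peptide[key] = rec.score > 0
    return out, skipped


@dataclass(frozen=True)
class PrioritizedCluster:
    cluster: AnnotatedCluster
    matched_sets: tuple[str, ...]
    matched_keywords: tuple[str, ...]
    representative_score: float


def prioritize(
    annotated: Sequence[AnnotatedCluster],
    keyword_sets: Mapping[str, Sequence[str]] | None = None,
) -> list[PrioritizedCluster]:
    """Rank clusters by keyword relevance of their homology descriptions.

    A cluster matches a keyword if any member description contains it
    (case-insensitive substring).  Ranking key: number of distinct
    keyword sets matched (desc), representative score (desc), then
    cluster_id for determinism.  Output is a subset of the input and
    independent of annotation-record order.
    """
    if keyword_sets is None:
        keyword_sets = DEFAULT_KEYWORD_SETS
    if not keyword_sets:
        import warnings

        warnings.warn("empty keyword configuration; nothing to prioritize")
        return []
    out = []
    for ac in annotated:
        descriptions = [ac.member_description(m).lower() for m in ac.members]
        matched_sets: list[str] = []
        matched_kw: list[str] = []
        for set_name in sorted(keyword_sets):
            hit_kw = [
                kw for kw in keyword_sets[set_name]
                if any(kw.lower() in d for d in descriptions)
            ]
            if hit_kw:
                matched_sets.append(set_name)
                matched_kw.extend(hit_kw)
        if matched_sets:
            rep = ac.representative
            out.append(
                PrioritizedCluster(
                    cluster=ac,
                    matched_sets=tuple(matched_sets),
                    matched_keywords=tuple(sorted(set(matched_kw))),
                    representative_score=rep.score if rep else 0.0,
                )
            )
    return sorted(
        out,
        key=lambda p: (-len(p.matched_sets), -p.representative_score, p.cluster.cluster_id),
    )


def prioritized_rows(ranked: Sequence[PrioritizedCluster]) -> list[dict]:
    from .io import format_member_list

    return [
        {
            "cluster_id": p.cluster.cluster_id,
            "category": p.cluster.category.label.value,
            "subject": p.cluster.category.subject,
            "matched_sets": ";".join(p.matched_sets),
            "matched_keywords": ";".join(p.matched_keywords),
            "representative_score": p.representative_score,
            "representative_description": p.cluster.representative_description,
            "members": format_member_list(p.cluster.members),
        }
        for p in ranked
    ]
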