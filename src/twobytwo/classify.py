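"""The core two-by-two computation: classify cluster composition.

Every ortholog cluster is labelled by the SET of strains its members
come from, judged against the design:

* ``CORE`` — every strain of the design contributes at least one member
  (the pan-group gene set).
* ``SPECIES_SELF`` — members come from exactly the two strains of one
  species, both represented.  Because the signal replicates in two
  independent assemblies, these are the high-confidence species-unique
  families.  Paralog multiplicity (counts > 1 per strain) is allowed;
  what defines the category is the strain set.
* ``STRAIN_SELF`` — all members (>= 2) come from a single strain: a
  within-strain paralog family.
* ``PARTIAL`` — anything else.

Singleton proteins never enter a cluster and are tallied separately
per strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .cluster import OrthoCluster, ProteinKey
from .design import TwoByTwoDesign


class Category(str, Enum):
    CORE = "CORE"
    SPECIES_SELF = "SPECIES_SELF"
    STRAIN_SELF = "STRAIN_SELF"
    PARTIAL = "PARTIAL"


@dataclass(frozen=True)
class ClusterCategory:
    """A category label plus its subject (species or strain) where defined."""

    label: Category
    subject: str = ""

    def __post_init__(self) -> None:
        needs_subject = self.label in (Category.SPECIES_SELF, Category.STRAIN_SELF)
        if needs_subject != bool(self.subject):
            raise ValueError(f"subject set iff label is SPECIES_SELF/STRAIN_SELF, got {self}")


def composition_signature(
    cluster: OrthoCluster, design: TwoByTwoDesign
) -> dict[str, int]:
    """Per-strain member counts of a cluster (zero-count strains omitted)."""
    for strain in cluster.signature:
        if strain not in design:
            raise ValueError(
                f"cluster {cluster.cluster_id}: member strain {strain!r} not in design"
            )
    return dict(cluster.signature)


def classify_signature(
    signature: Mapping[str, int], design: TwoByTwoDesign
) -> ClusterCategory:
    """Classify a composition signature (strain -> member count >= 1).

    Rules, checked in order (mutually exclusive by construction):
    CORE if all design strains are present; SPECIES_SELF(s) if the
    strains present are exactly the two strains of species s;
    STRAIN_SELF(t) if exactly one strain t is present; else PARTIAL.
    """
    if not signature:
        raise ValueError("empty signature")
    present = set(signature)
    unknown = present - set(design.strain_ids)
    if unknown:
        raise ValueError(f"signature contains strains not in design: {sorted(unknown)}")
    if sum(signature.values()) < 2:
        raise ValueError("signature must cover >= 2 members")
    if present == set(design.strain_ids):
        return ClusterCategory(Category.CORE)
    if len(present) == 2:
        for species, pair in design.species_to_strains.items():
            if present == set(pair):
                return ClusterCategory(Category.SPECIES_SELF, subject=species)
    if len(present) == 1:
        return ClusterCategory(Category.STRAIN_SELF, subject=next(iter(present)))
    return ClusterCategory(Category.PARTIAL)


def classify_cluster(cluster: OrthoCluster, design: TwoByTwoDesign) -> ClusterCategory:
    return classify_signature(composition_signature(cluster, design), design)


@dataclass
class ClassificationSummary:
    """Counts behind the category bar chart plus per-strain tallies.

    ``total_clusters_any_strain[s]`` counts clusters with >= 1 member
    of strain s; ``total_clusters_species_any`` / ``_both`` are the two
    readings of a species' total cluster participation (>= 1 member
    from the species vs both strains represented) — both are reported.
    """

    core_count: int = 0
    partial_count: int = 0
    species_self_count: dict[str, int] = field(default_factory=dict)
    strain_self_count: dict[str, int] = field(default_factory=dict)
    singleton_count: dict[str, int] = field(default_factory=dict)
    total_clusters_any_strain: dict[str, int] = field(default_factory=dict)
    total_clusters_species_any: dict[str, int] = field(default_factory=dict)
    total_clusters_species_both: dict[str, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return (
            self.core_count
            + self.partial_count
            + sum(self.species_self_count.values())
            + sum(self.strain_self_count.values())
        )


def summarize(
    clusters: Sequence[OrthoCluster],
    unassigned: Iterable[ProteinKey],
    design: TwoByTwoDesign,
    proteomes: Mapping[str, Mapping[str, str]] | None = None,
) -> ClassificationSummary:
    """Classify every cluster and tally counts per category/species/strain.

    Singletons per strain = unassigned proteins + (when full proteomes
    are supplied) proteins appearing in no cluster and no unassigned
    entry.  The partition invariant (every cluster in exactly one
    category) is asserted.
    """
    s = ClassificationSummary()
    for sp in design.species_ids:
        s.species_self_count[sp] = 0
        s.total_clusters_species_any[sp] = 0
        s.total_clusters_species_both[sp] = 0
    for st in design.strain_ids:
        s.strain_self_count[st] = 0
        s.singleton_count[st] = 0
        s.total_clusters_any_strain[st] = 0

    for cluster in clusters:
        cat = classify_cluster(cluster, design)
        if cat.label is Category.CORE:
            s.core_count += 1
        elif cat.label is Category.SPECIES_SELF:
            s.species_self_count[cat.subject] += 1
        elif cat.label is Category.STRAIN_SELF:
            s.strain_self_count[cat.subject] += 1
        else:
            s.partial_count += 1
        present = set(cluster.signature)
        for st in present:
            s.total_clusters_any_strain[st] += 1
        for sp, pair in design.species_to_strains.items():
            if present & set(pair):
                s.total_clusters_species_any[sp] += 1
            if set(pair) <= present:
                s.total_clusters_species_both[sp] += 1

    assert s.n_clusters == len(clusters), "category partition invariant violated"

    clustered: set[ProteinKey] = set()
    for c in clusters:
        clustered |= c.members
    unassigned = list(unassigned)
    for strain, _ in unassigned:
        if strain not in design:
            raise ValueError(f"unassigned protein from unknown strain {strain!r}")
        s.singleton_count[strain] += 1
    if proteomes is not None:
        listed = clustered | set(unassigned)
        for strain, prots in proteomes.items():
            for pid in prots:
                if (strain, pid) not in listed:
                    s.singleton_count[strain] += 1
    return s


def shared_between_species(
    clusters: Sequence[OrthoCluster],
    species_a: str,
    species_b: str,
    design: TwoByTwoDesign,
    mode: str = "any_strain",
) -> list[OrthoCluster]:
    """Clusters drawn only from two species' strains, both species present.

    ``any_strain`` requires >= 1 member from each species;
    ``both_strains`` requires all four strains represented.  Useful for
    finding families shared by two closely related species but absent
    from the rest of the group.
    """
    if species_a == species_b:
        raise ValueError("species must be distinct")
    if mode not in {"any_strain", "both_strains"}:
        raise ValueError(f"unknown mode {mode!r}")
    pair_a = set(design.strains_of(species_a))
    pair_b = set(design.strains_of(species_b))
    allowed = pair_a | pair_b
    out = []
    for c in clusters:
        present = set(c.signature)
        if not present <= allowed:
            continue
        if mode == "any_strain":
            if present & pair_a and present & pair_b:
                out.append(c)
        else:
            if present == allowed:
                out.append(c)
    return out


def classification_rows(
    clusters: Sequence[OrthoCluster], design: TwoByTwoDesign
) -> list[dict]:
    """Per-cluster classification records for the output TSV."""
    rows = []
    for c in clusters:
        cat = classify_cluster(c, design)
        sig = ";".join(f"{k}:{v}" for k, v in sorted(c.signature.items()))
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "category": cat.label.value,
                "subject": cat.subject,
                "size": len(c.members),
                "signature": sig,
            }
        )
    return rows


def summary_rows(summary: ClassificationSummary, design: TwoByTwoDesign) -> list[dict]:
    """Long-format summary table mirroring the category bar data."""
    rows: list[dict] = [
        {"scope": "design", "entity": "", "metric": "core_clusters", "count": summary.core_count},
        {"scope": "design", "entity": "", "metric": "partial_clusters", "count": summary.partial_count},
    ]
    for sp in design.species_ids:
        rows.append({"scope": "species", "entity": sp, "metric": "species_self_clusters",
                     "count": summary.species_self_count[sp]})
        rows.append({"scope": "species", "entity": sp, "metric": "total_clusters_any_strain",
                     "count": summary.total_clusters_species_any[sp]})
        rows.append({"scope": "species", "entity": sp, "metric": "total_clusters_both_strains",
                     "count": summary.total_clusters_species_both[sp]})
    for st in design.strain_ids:
        rows.append({"scope": "strain", "entity": st, "metric": "strain_self_clusters",
                     "count": summary.strain_self_count[st]})
        rows.append({"scope": "strain", "entity": st, "metric": "singletons",
                     "count": summary.singleton_count[st]})
        rows.append({"scope": "strain", "entity": st, "metric": "total_clusters",
                     "count": summary.total_clusters_any_strain[st]})
    return rows
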