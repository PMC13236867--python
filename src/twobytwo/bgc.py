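"""Known-cluster presence matrix over strains and species.

Builds a reference-cluster x strain grid of best percent similarity to
characterized BGC references, rolls it up to species level (absent /
one strain / both strains), bins similarities for heatmap display, and
computes the two headline summaries: per-species strain concordance
(how many matched references replicate in both strains) and group-wide
species uniqueness (how many matched references occur in exactly one
species).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .design import TwoByTwoDesign
from .io import BgcRegionHit


class SimilarityBin(str, Enum):
    ABSENT = "ABSENT"
    LOW = "LOW"            # 1-25
    MID_LOW = "MID_LOW"    # 26-50
    MID_HIGH = "MID_HIGH"  # 51-75
    HIGH = "HIGH"          # 76-100


DEFAULT_BIN_EDGES = (25, 50, 75, 100)
_BIN_ORDER = (SimilarityBin.LOW, SimilarityBin.MID_LOW, SimilarityBin.MID_HIGH, SimilarityBin.HIGH)


def bin_similarity(pct: int, edges: Sequence[int] = DEFAULT_BIN_EDGES) -> SimilarityBin:
    """Map an integer percent similarity to its display bin.

    Bins are upper-inclusive on integer boundaries: 0 -> ABSENT,
    1-25 -> LOW, 26-50 -> MID_LOW, 51-75 -> MID_HIGH, 76-100 -> HIGH.
    """
    if not 0 <= pct <= 100:
        raise ValueError(f"similarity {pct} outside [0,100]")
    if pct == 0:
        return SimilarityBin.ABSENT
    for edge, label in zip(edges, _BIN_ORDER):
        if pct <= edge:
            return label
    return _BIN_ORDER[len(edges) - 1]


class Presence(str, Enum):
    ABSENT = "absent"
    ONE_STRAIN = "one_strain"
    BOTH_STRAINS = "both_strains"


@dataclass
class BgcMatrix:
    """Reference x strain best-similarity grid with species roll-ups."""

    design: TwoByTwoDesign
    references: list[str]
    cells: dict[tuple[str, str], int]          # (reference, strain) -> best pct
    region_counts: dict[str, int]              # strain -> total predicted regions
    matched_region_counts: dict[str, int]      # strain -> regions with a known hit
    species_presence: dict[tuple[str, str], Presence] = field(init=False)

    def __post_init__(self) -> None:
        self.species_presence = {}
        for ref in self.references:
            for sp, pair in self.design.species_to_strains.items():
                n = sum(1 for st in pair if self.cells.get((ref, st), 0) > 0)
                self.species_presence[(ref, sp)] = (
                    Presence.ABSENT, Presence.ONE_STRAIN, Presence.BOTH_STRAINS
                )[n]

    def cell(self, reference: str, strain: str) -> int:
        return self.cells.get((reference, strain), 0)

    def species_max_similarity(self, reference: str, species: str) -> int:
        return max(self.cell(reference, st) for st in self.design.strains_of(species))

    def species_count(self, reference: str) -> int:
        return sum(
            1
            for sp in self.design.species_ids
            if self.species_presence[(reference, sp)] is not Presence.ABSENT
        )


def build_matrix(hits: Sequence[BgcRegionHit], design: TwoByTwoDesign) -> BgcMatrix:
    """Aggregate region hits into the best-similarity matrix.

    A cell (reference, strain) holds the maximum similarity over all of
    that strain's regions matching the reference.  Regions with no
    known reference still count toward per-strain region totals (the
    bar-height denominator) but create no cell.  References are ordered
    by descending number of species present, then lexicographically.
    """
    cells: dict[tuple[str, str], int] = {}
    region_counts = {st: 0 for st in design.strain_ids}
    matched = {st: 0 for st in design.strain_ids}
    for h in hits:
        if h.strain_id not in design:
            raise ValueError(f"hit from unknown strain {h.strain_id!r}")
        region_counts[h.strain_id] += 1
        if h.reference_id:
            matched[h.strain_id] += 1
            key = (h.reference_id, h.strain_id)
            cells[key] = max(cells.get(key, 0), h.similarity_pct)

    refs = sorted({r for r, _ in cells})
    m = BgcMatrix(design, refs, cells, region_counts, matched)
    m.references = sorted(refs, key=lambda r: (-m.species_count(r), r))
    return m


def strain_concordance(matrix: BgcMatrix, species: str) -> tuple[int, int, int, int]:
    """(shared, unique_to_strain1, unique_to_strain2, union) for one species.

    Over references matched in at least one of the species' two
    strains: shared = matched in both, unique = matched in exactly one.
    A high shared fraction means the BGC calls replicate across
    independent assemblies.
    """
    s1, s2 = matrix.design.strains_of(species)
    set1 = {r for r in matrix.references if matrix.cell(r, s1) > 0}
    set2 = {r for r in matrix.references if matrix.cell(r, s2) > 0}
    shared = len(set1 & set2)
    u1 = len(set1 - set2)
    u2 = len(set2 - set1)
    return shared, u1, u2, shared + u1 + u2


@dataclass(frozen=True)
class UniquenessSummary:
    total_matched_references: int
    unique_to_single_species: int
    unique_pct: float | None  # None when no references matched

    def as_row(self) -> dict:
        return {
            "total_matched_references": self.total_matched_references,
            "unique_to_single_species": self.unique_to_single_species,
            "unique_pct": "" if self.unique_pct is None else self.unique_pct,
        }


def species_uniqueness(matrix: BgcMatrix) -> UniquenessSummary:
    """How many matched references occur in exactly one species.

    ``unique_pct`` = 100 * unique / total, rounded half-up to one
    decimal; undefined (None) for an empty matrix.
    """
    total = len(matrix.references)
    unique = sum(1 for r in matrix.references if matrix.species_count(r) == 1)
    if total == 0:
        return UniquenessSummary(0, 0, None)
    pct = _round_half_up_1dp(100.0 * unique / total)
    return UniquenessSummary(total, unique, pct)


def _round_half_up_1dp(x: float) -> float:
    from decimal import Decimal, ROUND_HALF_UP

    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def matrix_rows(matrix: BgcMatrix) -> list[dict]:
    """Wide TSV rows: one per reference, one similarity column per strain."""
    rows = []
    for ref in matrix.references:
        row: dict = {"reference_id": ref}
        for st in matrix.design.strain_ids:
            row[st] = matrix.cell(ref, st)
        row["species_count"] = matrix.species_count(ref)
        rows.append(row)
    return rows


def species_long_rows(matrix: BgcMatrix) -> list[dict]:
    """Heatmap-ready long rows: (reference, species, presence, bin)."""
    rows = []
    for ref in matrix.references:
        for sp in matrix.design.species_ids:
            best = matrix.species_max_similarity(ref, sp)
            rows.append(
                {
                    "reference_id": ref,
                    "species_id": sp,
                    "presence": matrix.species_presence[(ref, sp)].value,
                    "bin": bin_similarity(best).value,
                    "max_similarity": best,
                }
            )
    return rows
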