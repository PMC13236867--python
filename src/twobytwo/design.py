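"""Study-design registry for two-by-two comparisons.

A two-by-two design analyses a group of species using exactly two
independently assembled strains per species.  A gene family that
self-clusters between the two strains of one species — and no other
strain — is then a replicated, assembly-robust signal that the family
is unique to that species.  Every downstream stage consumes the design
built here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class DesignError(ValueError):
    """Raised when a strain table violates the two-by-two design rules."""


@dataclass(frozen=True)
class StrainRef:
    """One sequenced strain: its species and (optional) taxonomy family.

    ``strain_id`` is the token used throughout all input files (FASTA,
    GFF3, orthogroup and BGC tables) to refer to this strain.  IDs are
    case-sensitive; surrounding whitespace is trimmed on load.
    """

    strain_id: str
    species_id: str
    family_id: str = ""
    display_name: str = ""
    is_reference: bool = False


@dataclass
class TwoByTwoDesign:
    """A validated set of strains with exactly two strains per species."""

    strains: tuple[StrainRef, ...]
    species_to_strains: dict[str, tuple[str, str]] = field(init=False)
    family_to_species: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        violations = _violations(self.strains)
        if violations:
            raise DesignError("; ".join(violations))
        by_species: dict[str, list[str]] = {}
        by_family: dict[str, set[str]] = {}
        for s in self.strains:
            by_species.setdefault(s.species_id, []).append(s.strain_id)
            if s.family_id:
                by_family.setdefault(s.family_id, set()).add(s.species_id)
        self.species_to_strains = {sp: (ids[0], ids[1]) for sp, ids in by_species.items()}
        self.family_to_species = by_family

    @property
    def strain_ids(self) -> tuple[str, ...]:
        return tuple(s.strain_id for s in self.strains)

    @property
    def species_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.strains:
            seen.setdefault(s.species_id)
        return tuple(seen)

    def species_of(self, strain_id: str) -> str:
        for s in self.strains:
            if s.strain_id == strain_id:
                return s.species_id
        raise KeyError(f"unknown strain: {strain_id!r}")

    def strains_of(self, species_id: str) -> tuple[str, str]:
        try:
            return self.species_to_strains[species_id]
        except KeyError:
            raise KeyError(f"unknown species: {species_id!r}") from None

    def reference_strain(self, species_id: str) -> str:
        """The designated reference strain of a species.

        The strain flagged ``is_reference`` in the design file wins;
        otherwise the first strain listed for the species.
        """
        pair = self.strains_of(species_id)
        for s in self.strains:
            if s.species_id == species_id and s.is_reference:
                return s.strain_id
        return pair[0]

    def __contains__(self, strain_id: object) -> bool:
        return strain_id in self.strain_ids

    def to_rows(self) -> list[dict[str, str]]:
        return [
            {
                "strain_id": s.strain_id,
                "species_id": s.species_id,
                "family_id": s.family_id,
                "display_name": s.display_name,
                "is_reference": "1" if s.is_reference else "0",
            }
            for s in self.strains
        ]


def _violations(strains: Sequence[StrainRef]) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    for s in strains:
        if not s.strain_id:
            out.append("empty strain_id")
        if not s.species_id:
            out.append(f"strain {s.strain_id!r}: empty species_id")
        if s.strain_id in seen:
            out.append(f"duplicate strain_id {s.strain_id!r}")
        seen.add(s.strain_id)
    counts: dict[str, int] = {}
    for s in strains:
        counts[s.species_id] = counts.get(s.species_id, 0) + 1
    for sp, n in counts.items():
        if n != 2:
            out.append(f"species {sp!r} has {n} strain(s); exactly 2 required")
    if len(counts) < 2:
        out.append(f"design has {len(counts)} species; at least 2 required")
    return out


def load_design(rows: Iterable[Mapping[str, str]]) -> TwoByTwoDesign:
    """Build a validated :class:`TwoByTwoDesign` from table rows.

    Each row needs ``strain_id`` and ``species_id``; ``family_id``,
    ``display_name`` and ``is_reference`` are optional.  Strain order is
    preserved as given.  Raises :class:`DesignError` naming the offending
    species or strain if any two-by-two rule is broken.
    """
    strains = []
    rows = list(rows)
    if not rows:
        raise DesignError("empty design table")
    for r in rows:
        if "strain_id" not in r or "species_id" not in r:
            raise DesignError("design rows need strain_id and species_id columns")
        strains.append(
            StrainRef(
                strain_id=str(r["strain_id"]).strip(),
                species_id=str(r["species_id"]).strip(),
                family_id=str(r.get("family_id", "") or "").strip(),
                display_name=str(r.get("display_name", "") or "").strip(),
                is_reference=str(r.get("is_reference", "0")).strip() in {"1", "true", "True"},
            )
        )
    return TwoByTwoDesign(strains=tuple(strains))


def validate_design(strains: Sequence[StrainRef]) -> list[str]:
    """Report every design violation (empty list means valid).

    Unlike :func:`load_design` this never raises; each violation names
    the offending strain or species.
    """
    return _violations(strains)


def read_design_file(path: str | Path) -> TwoByTwoDesign:
    """Read a design from TSV (headered) or a JSON list of objects."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("["):
        return load_design(json.loads(text))
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise DesignError(f"empty design file: {path}")
    header = lines[0].rstrip("\n").split("\t")
    rows = [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]
    return load_design(rows)


def write_design_file(design: TwoByTwoDesign, path: str | Path) -> None:
    path = Path(path)
    cols = ["strain_id", "species_id", "family_id", "display_name", "is_reference"]
    lines = ["\t".join(cols)]
    for row in design.to_rows():
        lines.append("\t".join(row[c] for c in cols))
    path.write_text("\n".join(lines) + "\n")
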