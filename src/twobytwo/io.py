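"""Readers and writers for every external file the pipeline touches.

Protein FASTA, GFF3 gene coordinates, orthogroup tables (two dialects),
normalized BGC hit tables, annotation tables, and generic TSV/JSON
result output.  Coordinates are GFF3 1-based inclusive throughout the
toolkit.  Member tokens of the form ``strain|protein`` split on the
FIRST ``|`` so protein accessions may contain dots and dashes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .cluster import OrthoCluster, ProteinKey
from .design import TwoByTwoDesign

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    strain_id: str
    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"{self.strain_id}|{self.protein_id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneCoordinate:
    """1-based inclusive gene span on a contig, linked to a protein ID."""

    strain_id: str
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1 or self.start > self.end:
            raise ParseError(
                f"{self.gene_id}: bad coordinates {self.start}..{self.end} (1-based inclusive)"
            )


@dataclass(frozen=True)
class BgcRegionHit:
    """One predicted BGC region and its best known-cluster match.

    ``reference_id`` is empty and ``similarity_pct`` 0 for regions with
    no match to any characterized reference cluster.
    """

    strain_id: str
    contig: str
    start: int
    end: int
    cluster_type: str
    reference_id: str
    similarity_pct: int

    def __post_init__(self) -> None:
        if not 0 <= self.similarity_pct <= 100:
            raise ParseError(f"similarity_pct {self.similarity_pct} outside [0,100]")
        if (self.reference_id == "") != (self.similarity_pct == 0):
            raise ParseError(
                f"{self.strain_id} {self.contig}:{self.start}-{self.end}: "
                "reference_id must be empty iff similarity_pct is 0"
            )


ANNOTATION_SOURCES = ("homology", "domain", "signal_peptide")


@dataclass(frozen=True)
class AnnotationRecord:
    strain_id: str
    protein_id: str
    source: str
    hit_id: str
    description: str
    score: float

    def __post_init__(self) -> None:
        if self.source not in ANNOTATION_SOURCES:
            raise ParseError(f"unknown annotation source {self.source!r}")


def read_protein_fasta(path: str | Path, strain_id: str) -> list[ProteinRecord]:
    """Read one strain's proteome; IDs are the first header token.

    Sequences are uppercased; duplicate IDs and empty files are errors.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ParseError(f"{path}: duplicate protein ID {pid!r}")
        seen.add(pid)
        records.append(ProteinRecord(strain_id, pid, str(rec.seq).upper()))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return records


def split_member_token(token: str) -> ProteinKey:
    """Split 'strain|protein' on the FIRST '|' (accessions may contain '.')."""
    token = token.strip()
    if not token or "|" not in token:
        raise ParseError(f"bad member token {token!r}; expected 'strain|protein'")
    strain, protein = token.split("|", 1)
    if not strain or not protein:
        raise ParseError(f"bad member token {token!r}")
    return strain, protein


def format_member_token(key: ProteinKey) -> str:
    return f"{key[0]}|{key[1]}"


def read_gene_coordinates(path: str | Path, strain_id: str) -> list[GeneCoordinate]:
    """Extract one coordinate per protein-linked feature from a GFF3 file.

    Features of type gene/mRNA/CDS are scanned; the protein link is the
    first available of the ``protein_id``/``proteinId`` attribute, else
    the feature ``ID``.  CDS segments of one protein are merged to their
    overall span.  Features without any linkage are skipped (count
    logged).  Coordinates stay 1-based inclusive, verbatim from GFF3.
    """
    path = Path(path)
    spans: dict[str, list] = {}
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
            contig, _, ftype, start_s, end_s, _, strand, _, attrs = fields
            if ftype not in {"gene", "mRNA", "CDS"}:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            attr_map = _parse_attrs(attrs)
            pid = attr_map.get("protein_id") or attr_map.get("proteinId") or attr_map.get("ID")
            if not pid:
                skipped += 1
                continue
            cur = spans.get(pid)
            if cur is None:
                spans[pid] = [contig, start, end, strand]
            else:
                if cur[0] == contig:
                    cur[1] = min(cur[1], start)
                    cur[2] = max(cur[2], end)
    if skipped:
        logger.info("%s: skipped %d features without protein linkage", path, skipped)
    return [
        GeneCoordinate(strain_id, pid, contig, start, end, strand)
        for pid, (contig, start, end, strand) in spans.items()
    ]


def _parse_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        k, v = chunk.split("=", 1)
        out[k] = v
    return out


def read_orthogroups(
    path: str | Path,
    dialect: str,
    design: TwoByTwoDesign,
) -> tuple[list[OrthoCluster], list[ProteinKey]]:
    """Read an orthogroup table in the ``wide`` or ``long`` dialect.

    wide: TSV with a cluster_id column then one column per strain,
    cells holding comma-separated member protein IDs (or
    ``strain|protein`` tokens).  long: rows of
    ``cluster_id<TAB>strain_id<TAB>protein_id``.

    Groups with a single member are routed to the unassigned list, not
    returned as clusters.  Strain IDs must exist in the design.
    """
    path = Path(path)
    if dialect not in {"wide", "long"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    groups: dict[str, list[ProteinKey]] = {}
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if dialect == "long":
        start = 0
        if lines and lines[0].lower().startswith("cluster_id\t"):
            start = 1
        for ln in lines[start:]:
            parts = ln.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}: long dialect needs 3 columns, got {len(parts)}")
            cid, strain, pid = (p.strip() for p in parts)
            if not pid:
                raise ParseError(f"{path}: empty member token in cluster {cid}")
            _check_strain(strain, design, path)
            groups.setdefault(cid, []).append((strain, pid))
    else:
        if not lines:
            raise ParseError(f"{path}: empty orthogroup table")
        header = lines[0].split("\t")
        strain_cols = header[1:]
        for s in strain_cols:
            _check_strain(s, design, path)
        for ln in lines[1:]:
            parts = ln.split("\t")
            cid = parts[0]
            members: list[ProteinKey] = []
            for col, cell in zip(strain_cols, parts[1:]):
                for token in cell.split(","):
                    token = token.strip()
                    if not token:
                        continue
                    if "|" in token:
                        strain, pid = split_member_token(token)
                        _check_strain(strain, design, path)
                        members.append((strain, pid))
                    else:
                        members.append((col, token))
            groups[cid] = members
    clusters = []
    unassigned: list[ProteinKey] = []
    for cid in sorted(groups):
        members = groups[cid]
        if len(members) >= 2:
            clusters.append(OrthoCluster(cluster_id=cid, members=frozenset(members)))
        elif members:
            unassigned.extend(members)
    return clusters, sorted(unassigned)


def _check_strain(strain: str, design: TwoByTwoDesign, path: Path) -> None:
    if strain not in design:
        raise ParseError(f"{path}: strain {strain!r} not in design")


def write_orthogroups_long(
    clusters: Sequence[OrthoCluster], path: str | Path
) -> None:
    """Write clusters in the long dialect (interchangeable with external tables)."""
    lines = ["cluster_id\tstrain_id\tprotein_id"]
    for c in clusters:
        for strain, pid in c.sorted_members():
            lines.append(f"{c.cluster_id}\t{strain}\t{pid}")
    Path(path).write_text("\n".join(lines) + "\n")


BGC_COLUMNS = ["strain_id", "contig", "start", "end", "cluster_type", "reference_id", "similarity_pct"]


def read_bgc_hits(path: str | Path, design: TwoByTwoDesign) -> list[BgcRegionHit]:
    """Read the normalized BGC region hit TSV, validating every row."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in BGC_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    hits = []
    for row in df.itertuples(index=False):
        if row.strain_id not in design:
            raise ParseError(f"{path}: strain {row.strain_id!r} not in design")
        hits.append(
            BgcRegionHit(
                strain_id=row.strain_id,
                contig=row.contig,
                start=int(row.start),
                end=int(row.end),
                cluster_type=row.cluster_type,
                reference_id=row.reference_id,
                similarity_pct=int(row.similarity_pct),
            )
        )
    return hits


def write_bgc_hits(hits: Sequence[BgcRegionHit], path: str | Path) -> None:
    df = pd.DataFrame([asdict(h) for h in hits], columns=BGC_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


ANNOTATION_COLUMNS = ["strain_id", "protein_id", "source", "hit_id", "description", "score"]


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return [
        AnnotationRecord(
            strain_id=r.strain_id,
            protein_id=r.protein_id,
            source=r.source,
            hit_id=r.hit_id,
            description=r.description,
            score=float(r.score) if r.score != "" else 0.0,
        )
        for r in df.itertuples(index=False)
    ]


def write_annotations(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    df = pd.DataFrame([asdict(r) for r in records], columns=ANNOTATION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def write_table(
    records: Sequence[Mapping],
    path: str | Path,
    fmt: str = "tsv",
    columns: Sequence[str] | None = None,
) -> None:
    """Write result records as TSV or JSON with a deterministic column order.

    JSON output round-trips to identical records via :func:`read_table`.
    An empty record list yields a header-only TSV (columns required then).
    """
    path = Path(path)
    if fmt not in {"tsv", "json"}:
        raise ValueError(f"unknown format {fmt!r}")
    if columns is None:
        if not records:
            raise ValueError("empty record list requires explicit columns")
        columns = list(records[0].keys())
    if fmt == "json":
        payload = [{c: r.get(c) for c in columns} for r in records]
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        df = pd.DataFrame(list(records), columns=list(columns))
        df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> list[dict]:
    path = Path(path)
    if path.suffix == ".json":
        return json.loads(path.read_text())
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return df.to_dict(orient="records")


def format_member_list(members: Iterable[ProteinKey]) -> str:
    """Serialize members as 'strain|protein; strain|protein; ...'."""
    return "; ".join(format_member_token(m) for m in sorted(members))


def parse_member_list(text: str) -> frozenset[ProteinKey]:
    return frozenset(split_member_token(t) for t in text.split(";") if t.strip())


def write_protein_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.protein_id}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")
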