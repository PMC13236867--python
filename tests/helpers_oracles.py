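"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle restates a definition directly (quadratic DP, exhaustive
enumeration, transitive closure, group-by set algebra) without sharing
code with the implementation it checks.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_oracle(a: str, b: str, open_: float = 11, ext: float = 1) -> float:
    """Quadratic Gotoh local alignment: gap of length k costs open + (k-1)*ext."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s)
            Ix[i][j] = max(M[i - 1][j] - open_, Ix[i - 1][j] - ext, Iy[i - 1][j] - open_)
            Iy[i][j] = max(M[i][j - 1] - open_, Iy[i][j - 1] - ext, Ix[i][j - 1] - open_)
            best = max(best, M[i][j])
    return best


def normalized_sw_oracle(a: str, b: str) -> float:
    denom = min(sw_oracle(a, a), sw_oracle(b, b))
    if denom <= 0:
        return 0.0
    return max(0.0, sw_oracle(a, b)) / denom


def rbh_oracle(
    scores: dict[tuple[str, str], float],
    ids_a: list[str],
    ids_b: list[str],
    min_score: float,
) -> set[tuple[str, str]]:
    """Brute-force enumeration of the reciprocal-best-hit definition.

    ``scores[(x, y)]`` is the similarity of x in A and y in B.  Best
    partners take the maximum score with ties resolved to the smallest
    ID; an edge needs mutual best partners and score >= min_score.
    """
    edges = set()
    for x in ids_a:
        best_y = min(ids_b, key=lambda y: (-scores[(x, y)], y))
        if scores[(x, best_y)] < min_score:
            continue
        best_x = min(ids_a, key=lambda x2: (-scores[(x2, best_y)], x2))
        if best_x == x:
            edges.add((x, best_y))
    return edges


def components_oracle(edges, nodes) -> list[frozenset]:
    """Connected components by iterated transitive closure (no graph library)."""
    comp = {n: frozenset([n]) for n in nodes}
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            merged = comp[a] | comp[b]
            if merged != comp[a] or merged != comp[b]:
                for n in merged:
                    comp[n] = merged
                changed = True
    return sorted(set(comp.values()), key=lambda c: sorted(c))


def classify_oracle(signature: dict[str, int], design) -> tuple[str, str]:
    """Literal restatement of the category rules: (label, subject)."""
    present = {s for s, n in signature.items() if n > 0}
    all_strains = set(design.strain_ids)
    if present == all_strains:
        return "CORE", ""
    for species, pair in design.species_to_strains.items():
        if present == set(pair):
            return "SPECIES_SELF", species
    if len(present) == 1:
        return "STRAIN_SELF", next(iter(present))
    return "PARTIAL", ""


def chain_oracle(intervals, max_gap: int) -> list[frozenset]:
    """Transitive closure of the pairwise gap relation on one contig.

    ``intervals``: list of (gene_id, start, end).  Two genes relate iff
    the distance between their closest boundaries is <= max_gap
    (overlap counts).  Returns member-id sets of components with >= 2
    genes.
    """
    rel = []
    for i, (ga, sa, ea) in enumerate(intervals):
        for gb, sb, eb in intervals[i + 1 :]:
            gap = max(sa, sb) - min(ea, eb) - 1
            if gap <= max_gap:
                rel.append((ga, gb))
    comps = components_oracle(rel, [g for g, _, _ in intervals])
    return [c for c in comps if len(c) >= 2]


def bgc_cell_oracle(hits) -> dict[tuple[str, str], int]:
    """Group-by max of similarity over (reference, strain), matched hits only."""
    cells: dict[tuple[str, str], int] = {}
    for h in hits:
        if not h.reference_id:
            continue
        key = (h.reference_id, h.strain_id)
        cells[key] = max(cells.get(key, 0), h.similarity_pct)
    return cells


def concordance_oracle(hits, strain1: str, strain2: str) -> tuple[int, int, int, int]:
    set1 = {h.reference_id for h in hits if h.strain_id == strain1 and h.reference_id}
    set2 = {h.reference_id for h in hits if h.strain_id == strain2 and h.reference_id}
    return (
        len(set1 & set2),
        len(set1 - set2),
        len(set2 - set1),
        len(set1 | set2),
    )


def uniqueness_oracle(hits, design) -> tuple[int, int]:
    """(total matched references, references present in exactly one species)."""
    ref_species: dict[str, set[str]] = {}
    for h in hits:
        if h.reference_id:
            ref_species.setdefault(h.reference_id, set()).add(design.species_of(h.strain_id))
    unique = sum(1 for spp in ref_species.values() if len(spp) == 1)
    return len(ref_species), unique


def bin_oracle(pct: int) -> str:
    """Piecewise bin definition enumerated literally."""
    if pct == 0:
        return "ABSENT"
    if 1 <= pct <= 25:
        return "LOW"
    if 26 <= pct <= 50:
        return "MID_LOW"
    if 51 <= pct <= 75:
        return "MID_HIGH"
    return "HIGH"
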