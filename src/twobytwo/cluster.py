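"""Desk-scale ortholog clustering from raw proteomes.

Reciprocal-best-hit (RBH) edges are computed from normalized local
alignment scores (Smith–Waterman, BLOSUM62, affine gaps), and ortholog
clusters are the connected components of the resulting edge graph.
This is a deliberately simple, fully deterministic stand-in for
external orthogroup inference pipelines: downstream classification
accepts any orthogroup table, so nothing depends on this particular
algorithm.

The normalized score of two sequences is the local alignment score
divided by the smaller of the two self-alignment scores, giving a
value in [0, 1] that is 1.0 for identical sequences and near 0 for
unrelated random sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

ProteinKey = tuple[str, str]  # (strain_id, protein_id)


@dataclass(frozen=True)
class SimilarityEdge:
    """An undirected RBH edge between two proteins with its score."""

    a: ProteinKey
    b: ProteinKey
    score: float

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-edge not allowed")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0,1]")
        # canonical orientation so (a,b) == (b,a)
        if self.b < self.a:
            object.__setattr__(self, "a", self.b)
            object.__setattr__(self, "b", self.a)


@dataclass
class OrthoCluster:
    """A set of >=2 proteins inferred to share ancestry.

    ``signature`` maps each strain present to its member count; it is
    the composition classified by :mod:`twobytwo.classify`.
    """

    cluster_id: str
    members: frozenset[ProteinKey]
    signature: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError(f"cluster {self.cluster_id}: needs >=2 members")
        sig: dict[str, int] = {}
        for strain, _ in self.members:
            sig[strain] = sig.get(strain, 0) + 1
        self.signature = sig

    def sorted_members(self) -> list[ProteinKey]:
        return sorted(self.members)


class AlignmentScorer:
    """Normalized local-alignment similarity with a cached self-score table.

    Parameters mirror the common protein-search defaults: BLOSUM62 with
    affine gap penalties, open 11 / extend 1 (a gap of length k costs
    11 + (k-1)).
    """

    def __init__(self, matrix_name: str = "BLOSUM62", gap_open: int = 11, gap_extend: int = 1):
        self._aligner = Align.PairwiseAligner(
            mode="local",
            substitution_matrix=substitution_matrices.load(matrix_name),
            open_gap_score=-float(gap_open),
            extend_gap_score=-float(gap_extend),
        )
        self._self_scores: dict[str, float] = {}

    def raw_score(self, seq_a: str, seq_b: str) -> float:
        return float(self._aligner.score(seq_a, seq_b))

    def self_score(self, seq: str) -> float:
        s = self._self_scores.get(seq)
        if s is None:
            s = self.raw_score(seq, seq)
            self._self_scores[seq] = s
        return s

    def pairwise_score(self, seq_a: str, seq_b: str) -> float:
        """Local alignment score normalized to [0, 1].

        score(a, b) / min(self(a), self(b)); symmetric, 1.0 for
        identical sequences, 0.0 when no positive-scoring local
        alignment exists.
        """
        if not seq_a or not seq_b:
            raise ValueError("pairwise_score requires non-empty sequences")
        denom = min(self.self_score(seq_a), self.self_score(seq_b))
        if denom <= 0:
            return 0.0
        return max(0.0, self.raw_score(seq_a, seq_b)) / denom


def pairwise_score(seq_a: str, seq_b: str, **kwargs) -> float:
    """Convenience wrapper: one-off normalized similarity (see AlignmentScorer)."""
    return AlignmentScorer(**kwargs).pairwise_score(seq_a, seq_b)


def _best_partner(
    scores: Mapping[str, float],
) -> tuple[str, float] | None:
    """Highest-scoring partner; ties resolved to the smallest protein_id."""
    if not scores:
        return None
    best_id = min(scores, key=lambda pid: (-scores[pid], pid))
    return best_id, scores[best_id]


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _kmer_index(proteome: Mapping[str, str], k: int) -> dict[str, set[str]]:
    return {pid: _kmer_set(seq, k) for pid, seq in proteome.items()}


def reciprocal_best_hits(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    strain_a: str,
    strain_b: str,
    min_score: float = 0.3,
    scorer: AlignmentScorer | None = None,
    prefilter_kmer: int = 5,
) -> list[SimilarityEdge]:
    """RBH edges between two distinct strains' proteomes.

    An edge (x, y) is emitted iff y is x's best partner in proteome_b,
    x is y's best partner in proteome_a, and the normalized score is
    >= ``min_score``.  Score ties are broken by lexicographically
    smallest protein_id, so output is deterministic.

    ``prefilter_kmer``: only pairs sharing at least one exact k-mer are
    aligned (0 disables).  Pairs without a shared k-mer are far below
    any usable ``min_score``, so the prescreen changes no edges while
    skipping the all-vs-all alignment of unrelated sequences.
    """
    if strain_a == strain_b:
        raise ValueError("reciprocal_best_hits requires two distinct strains")
    scorer = scorer or AlignmentScorer()
    kmers_b = _kmer_index(proteome_b, prefilter_kmer) if prefilter_kmer else None
    score_ab: dict[str, dict[str, float]] = {}
    for pid_a, seq_a in proteome_a.items():
        row = {}
        kset_a = _kmer_set(seq_a, prefilter_kmer) if prefilter_kmer else None
        for pid_b, seq_b in proteome_b.items():
            if kset_a is not None and kmers_b is not None and not (kset_a & kmers_b[pid_b]):
                continue
            row[pid_b] = scorer.pairwise_score(seq_a, seq_b)
        score_ab[pid_a] = row

    best_in_b = {pid_a: _best_partner(row) for pid_a, row in score_ab.items()}
    score_ba: dict[str, dict[str, float]] = {pid_b: {} for pid_b in proteome_b}
    for pid_a, row in score_ab.items():
        for pid_b, s in row.items():
            score_ba[pid_b][pid_a] = s
    best_in_a = {pid_b: _best_partner(row) for pid_b, row in score_ba.items()}

    edges = []
    for pid_a in sorted(proteome_a):
        hit = best_in_b[pid_a]
        if hit is None:
            continue
        pid_b, s = hit
        if s < min_score:
            continue
        back = best_in_a[pid_b]
        if back is not None and back[0] == pid_a:
            edges.append(SimilarityEdge((strain_a, pid_a), (strain_b, pid_b), s))
    return edges


def within_strain_best_hits(
    proteome: Mapping[str, str],
    strain: str,
    min_score: float = 0.3,
    scorer: AlignmentScorer | None = None,
    prefilter_kmer: int = 5,
) -> list[SimilarityEdge]:
    """Mutual best non-self hits inside one proteome (paralog edges).

    A pair (x, y) is included iff each is the other's best non-self
    partner and the score clears ``min_score``; this lets within-strain
    paralog families (strain self-clusters) form.  ``prefilter_kmer``
    works as in :func:`reciprocal_best_hits`.
    """
    scorer = scorer or AlignmentScorer()
    pids = sorted(proteome)
    kmers = _kmer_index(proteome, prefilter_kmer) if prefilter_kmer else None
    scores: dict[str, dict[str, float]] = {p: {} for p in pids}
    for i, pa in enumerate(pids):
        for pb in pids[i + 1 :]:
            if kmers is not None and not (kmers[pa] & kmers[pb]):
                continue
            s = scorer.pairwise_score(proteome[pa], proteome[pb])
            scores[pa][pb] = s
            scores[pb][pa] = s
    edges = []
    for pa in pids:
        hit = _best_partner(scores[pa])
        if hit is None:
            continue
        pb, s = hit
        if s < min_score or pb < pa:
            continue
        back = _best_partner(scores[pb])
        if back is not None and back[0] == pa:
            edges.append(SimilarityEdge((strain, pa), (strain, pb), s))
    return edges


def build_clusters(
    edges: Iterable[SimilarityEdge],
    all_proteins: Iterable[ProteinKey],
) -> tuple[list[OrthoCluster], list[ProteinKey]]:
    """Connected components of the edge graph, plus singleton proteins.

    Every input protein lands in exactly one cluster (component of
    size >= 2) or in the singleton list; the partition is asserted.
    Cluster IDs are assigned in order of each component's smallest
    member, so identical inputs give identical tables.
    """
    all_proteins = set(all_proteins)
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(all_proteins)
    for e in edges:
        for node in (e.a, e.b):
            if node not in all_proteins:
                raise ValueError(f"edge references unknown protein {node!r}")
        g.add_edge(e.a, e.b)

    components = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    clusters: list[OrthoCluster] = []
    singletons: list[ProteinKey] = []
    i = 0
    for comp in components:
        if len(comp) == 1:
            singletons.append(comp[0])
        else:
            i += 1
            clusters.append(OrthoCluster(cluster_id=f"cluster{i:05d}", members=frozenset(comp)))

    covered = set(singletons)
    for c in clusters:
        covered |= c.members
    assert covered == all_proteins, "partition invariant violated"
    return clusters, sorted(singletons)


def cluster_proteomes(
    proteomes: Mapping[str, Mapping[str, str]],
    min_score: float = 0.3,
    matrix_name: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    prefilter_kmer: int = 5,
) -> tuple[list[OrthoCluster], list[ProteinKey]]:
    """Full built-in clustering: RBH across all strain pairs + paralog edges.

    ``proteomes`` maps strain_id -> {protein_id: sequence}.  Default
    ``min_score`` 0.3 sits well between typical within-species and
    unrelated-sequence similarity regimes; all scoring parameters are
    configurable.
    """
    scorer = AlignmentScorer(matrix_name=matrix_name, gap_open=gap_open, gap_extend=gap_extend)
    strains = sorted(proteomes)
    edges: list[SimilarityEdge] = []
    for i, sa in enumerate(strains):
        edges.extend(
            within_strain_best_hits(proteomes[sa], sa, min_score, scorer, prefilter_kmer)
        )
        for sb in strains[i + 1 :]:
            edges.extend(
                reciprocal_best_hits(
                    proteomes[sa], proteomes[sb], sa, sb, min_score, scorer, prefilter_kmer
                )
            )
    all_proteins = {(s, p) for s, prot in proteomes.items() for p in prot}
    return build_clusters(edges, all_proteins)
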