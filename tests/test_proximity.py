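import random

import pytest
from helpers_oracles import chain_oracle
from hypothesis import given, settings, strategies as st

from twobytwo.classify import Category
from twobytwo.cluster import OrthoCluster
from twobytwo.io import GeneCoordinate
from twobytwo.proximity import chain_by_distance, select_candidate_genes, to_bed_lines


def _gene(pid, start, end, strain="A1", contig="c1", strand="+"):
    return GeneCoordinate(strain, pid, contig, start, end, strand)


# --- candidate selection -------------------------------------------------

def test_select_candidates_filters_category_and_strain(design4):
    clusters = [
        OrthoCluster("sp", frozenset({("A1", "p1"), ("A2", "q1")})),     # SPECIES_SELF(A)
        OrthoCluster("st", frozenset({("A1", "m1"), ("A1", "m2")})),     # STRAIN_SELF
        OrthoCluster("pt", frozenset({("A1", "x"), ("B1", "y")})),       # PARTIAL
    ]
    coords = {"p1": _gene("p1", 100, 500), "m1": _gene("m1", 1000, 1500)}
    genes, skipped = select_candidate_genes(clusters, coords, design4, "A")
    assert [g.gene_id for g in genes] == ["p1"]
    assert skipped == 0


def test_select_candidates_counts_missing_coordinates(design4):
    clusters = [
        OrthoCluster("sp1", frozenset({("A1", "p1"), ("A2", "q1")})),
        OrthoCluster("sp2", frozenset({("A1", "p2"), ("A2", "q2")})),
        OrthoCluster("sp3", frozenset({("A1", "p3"), ("A2", "q3")})),
    ]
    coords = {"p1": _gene("p1", 1, 10), "p3": _gene("p3", 100, 200)}
    genes, skipped = select_candidate_genes(clusters, coords, design4, "A")
    assert len(genes) == 2 and skipped == 1
    with pytest.raises(ValueError):
        select_candidate_genes(clusters, coords, design4, "Z")


def test_select_candidates_empty_when_no_species_self(design4):
    clusters = [OrthoCluster("pt", frozenset({("A1", "x"), ("B1", "y")}))]
    genes, skipped = select_candidate_genes(clusters, {}, design4, "A")
    assert genes == [] and skipped == 0


# --- chaining ------------------------------------------------------------

def test_two_genes_within_gap_chain(design4):
    chains = chain_by_distance([_gene("g1", 1000, 2000), _gene("g2", 2500, 3500)], design4)
    assert len(chains) == 1
    c = chains[0]
    assert c.gene_ids == ("g1", "g2")
    assert (c.span_start, c.span_end) == (1000, 3500)
    assert c.max_gap_observed == 499
    assert c.species_id == "A"


def test_different_contigs_never_chain(design4):
    chains = chain_by_distance(
        [_gene("g1", 1000, 2000, contig="c1"), _gene("g2", 2500, 3500, contig="c2")], design4
    )
    assert chains == []


def test_gap_boundary_exactly_5000_joins_5001_splits(design4):
    a = _gene("a", 1000, 2000)
    joined = chain_by_distance([a, _gene("b", 7001, 8000)], design4)  # gap == 5000
    assert len(joined) == 1 and joined[0].max_gap_observed == 5000
    split = chain_by_distance([a, _gene("b", 7002, 8000)], design4)  # gap == 5001
    assert split == []


def test_overlapping_genes_join(design4):
    chains = chain_by_distance([_gene("a", 100, 900), _gene("b", 500, 1200)], design4)
    assert len(chains) == 1 and chains[0].span_end == 1200


def test_chains_match_transitive_closure_oracle(design4):
    rng = random.Random(21)
    for trial in range(500):
        n = rng.randint(2, 50)
        genes = []
        intervals = []
        for i in range(n):
            start = rng.randint(1, 200000)
            length = rng.randint(200, 8000)
            # bias some gaps to land exactly on the boundary
            if rng.random() < 0.1 and genes:
                start = genes[-1].end + 5001 if rng.random() < 0.5 else genes[-1].end + 5000 + 1
            g = _gene(f"g{i}", start, start + length - 1)
            genes.append(g)
            intervals.append((g.gene_id, g.start, g.end))
        chains = chain_by_distance(genes, design4)
        got = sorted(sorted(c.gene_ids) for c in chains)
        expected = sorted(sorted(c) for c in chain_oracle(intervals, 5000))
        assert got == expected


def test_output_invariant_to_gene_order(design4):
    rng = random.Random(2)
    genes = [_gene(f"g{i}", 1 + i * 4000, 3000 + i * 4000) for i in range(10)]
    shuffled = genes[:]
    rng.shuffle(shuffled)
    assert chain_by_distance(genes, design4) == chain_by_distance(shuffled, design4)


@settings(derandomize=True, max_examples=100)
@given(
    starts=st.lists(st.integers(min_value=1, max_value=100000), min_size=2, max_size=12),
    gap_small=st.integers(min_value=100, max_value=4000),
    gap_big=st.integers(min_value=4001, max_value=20000),
)
def test_gap_monotonicity(starts, gap_small, gap_big):
    """Raising max_gap_bp never shrinks the chain containing a gene."""
    from twobytwo.design import load_design

    design = load_design(
        [
            {"strain_id": "A1", "species_id": "A"},
            {"strain_id": "A2", "species_id": "A"},
            {"strain_id": "B1", "species_id": "B"},
            {"strain_id": "B2", "species_id": "B"},
        ]
    )
    genes = [_gene(f"g{i}", s, s + 500) for i, s in enumerate(sorted(set(starts)))]
    small = chain_by_distance(genes, design, max_gap_bp=gap_small)
    big = chain_by_distance(genes, design, max_gap_bp=gap_big)

    def chain_size(chains, gid):
        for c in chains:
            if gid in c.gene_ids:
                return c.n_genes
        return 1

    for g in genes:
        assert chain_size(big, g.gene_id) >= chain_size(small, g.gene_id)


def test_chains_are_maximal(design4):
    """No two emitted chains on one contig could merge under the gap rule."""
    rng = random.Random(33)
    genes = []
    pos = 1
    for i in range(30):
        length = rng.randint(500, 3000)
        genes.append(_gene(f"g{i}", pos, pos + length - 1))
        pos += length + rng.choice([1000, 3000, 6000, 10000])
    chains = chain_by_distance(genes, design4)
    spans = sorted((c.span_start, c.span_end) for c in chains)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert s2 - e1 - 1 > 5000


def test_bed_export_half_open(design4):
    chains = chain_by_distance([_gene("g1", 1000, 2000), _gene("g2", 2500, 3500)], design4)
    line = to_bed_lines(chains)[0].split("\t")
    assert (line[0], line[1], line[2]) == ("c1", "999", "3500")
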