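import itertools
import random

import pytest
from helpers_oracles import classify_oracle
from hypothesis import given, settings, strategies as st

from twobytwo.classify import (
    Category,
    classify_cluster,
    classify_signature,
    composition_signature,
    shared_between_species,
    summarize,
)
from twobytwo.cluster import OrthoCluster
from twobytwo.design import load_design
from twobytwo.examples import curated_species_self_clusters, hypocreales_design


def test_composition_signature_counts(design4):
    c = OrthoCluster("c", frozenset({("A1", "p1"), ("A2", "p2"), ("A2", "p3")}))
    sig = composition_signature(c, design4)
    assert sig == {"A1": 1, "A2": 2}
    assert sum(sig.values()) == len(c.members)


def test_composition_signature_unknown_strain(design4):
    c = OrthoCluster("c", frozenset({("ZZ", "p1"), ("A1", "p2")}))
    with pytest.raises(ValueError, match="ZZ"):
        composition_signature(c, design4)


@pytest.mark.parametrize(
    "signature,label,subject",
    [
        ({"A1": 1, "A2": 2}, Category.SPECIES_SELF, "A"),
        ({"A1": 2, "A2": 2}, Category.SPECIES_SELF, "A"),
        ({"A1": 3}, Category.STRAIN_SELF, "A1"),
        ({"A1": 1, "A2": 1, "B1": 1, "B2": 1}, Category.CORE, ""),
        ({"A1": 1, "B1": 1}, Category.PARTIAL, ""),
        ({"A1": 1, "A2": 1, "B1": 1}, Category.PARTIAL, ""),
    ],
)
def test_classify_rules_direct(design4, signature, label, subject):
    cat = classify_signature(signature, design4)
    assert (cat.label, cat.subject) == (label, subject)


def test_curated_clusters_classify_species_self():
    """The published worked examples: every curated cluster is a species
    self-cluster of its own species under the 16-strain design."""
    design = hypocreales_design()
    clusters, _ = curated_species_self_clusters()
    oosporein = next(c for c in clusters if c.cluster_id == "cluster10663")
    assert composition_signature(oosporein, design) == {"Bb_ERL836": 1, "Bb_JEF-350": 2}
    swn = next(c for c in clusters if c.cluster_id == "cluster10467")
    assert composition_signature(swn, design) == {"Mb_3297": 2, "Mb_4556": 2}
    for c in clusters:
        cat = classify_cluster(c, design)
        assert cat.label is Category.SPECIES_SELF

    summary = summarize(clusters, [], design)
    nonzero = {k: v for k, v in summary.species_self_count.items() if v}
    assert nonzero == {
        "Beauveria_bassiana": 4,
        "Cordyceps_militaris": 3,
        "Metarhizium_brunneum": 9,
        "Trichoderma_reesei": 1,
        "Epichloe_festucae": 2,
    }
    assert summary.n_clusters == len(clusters) == 19


def test_classify_agrees_with_oracle_exhaustively(design8):
    """Exhaustive check over all signatures of 8 strains with counts <= 3."""
    strains = design8.strain_ids
    for counts in itertools.product(range(4), repeat=8):
        sig = {s: n for s, n in zip(strains, counts) if n > 0}
        if not sig or sum(sig.values()) < 2:
            continue
        cat = classify_signature(sig, design8)
        assert (cat.label.value, cat.subject) == classify_oracle(sig, design8)


@settings(derandomize=True, max_examples=300)
@given(
    counts=st.lists(st.integers(min_value=0, max_value=5), min_size=8, max_size=8),
)
def test_partition_and_order_invariance(counts):
    design = load_design(
        [
            {"strain_id": f"{sp}{j}", "species_id": sp}
            for sp in "ABCD"
            for j in (1, 2)
        ]
    )
    sig = {s: n for s, n in zip(design.strain_ids, counts) if n > 0}
    if not sig or sum(sig.values()) < 2:
        return
    cat = classify_signature(sig, design)
    # exactly one category
    assert cat.label in set(Category)
    # permuting the design's strain order changes nothing
    shuffled_rows = [
        {"strain_id": s.strain_id, "species_id": s.species_id}
        for s in sorted(design.strains, key=lambda s: s.strain_id[::-1])
    ]
    cat2 = classify_signature(sig, load_design(shuffled_rows))
    assert (cat.label, cat.subject) == (cat2.label, cat2.subject)
    # relabeling the two strains within each species preserves species_self
    swapped = {}
    for strain, n in sig.items():
        sp = strain[0]
        other = f"{sp}1" if strain.endswith("2") else f"{sp}2"
        swapped[other] = n
    cat3 = classify_signature(swapped, design)
    if cat.label is Category.SPECIES_SELF:
        assert cat3.label is Category.SPECIES_SELF and cat3.subject == cat.subject
    assert (cat.label is Category.CORE) == (cat3.label is Category.CORE)


def test_summarize_counting(design4):
    clusters = [
        OrthoCluster("core", frozenset({(s, "p") for s in design4.strain_ids})),
        OrthoCluster("sa1", frozenset({("A1", "x"), ("A2", "y")})),
        OrthoCluster("sa2", frozenset({("A1", "u"), ("A2", "v"), ("A2", "w")})),
        OrthoCluster("st", frozenset({("A1", "m"), ("A1", "n")})),
    ]
    s = summarize(clusters, [("B1", "s1"), ("B1", "s2"), ("A2", "s3")], design4)
    assert s.core_count == 1
    assert s.species_self_count == {"A": 2, "B": 0}
    assert s.strain_self_count["A1"] == 1
    assert s.singleton_count == {"A1": 0, "A2": 1, "B1": 2, "B2": 0}
    assert s.partial_count == 0
    assert s.total_clusters_any_strain["A1"] == 4
    assert s.total_clusters_species_any["A"] == 4
    assert s.total_clusters_species_both["A"] == 3


def test_summarize_empty(design4):
    s = summarize([], [], design4)
    assert s.n_clusters == 0
    assert all(v == 0 for v in s.singleton_count.values())


def test_proteome_derived_singletons_counted(design4):
    clusters = [OrthoCluster("c", frozenset({("A1", "p1"), ("A2", "p2")}))]
    proteomes = {"A1": {"p1": "MK", "orphan": "MW"}, "A2": {"p2": "MK"}}
    s = summarize(clusters, [], design4, proteomes=proteomes)
    assert s.singleton_count["A1"] == 1  # orphan counted only via proteome


def test_shared_between_species_modes(design4):
    four = OrthoCluster("c4", frozenset({(s, "p") for s in ("A1", "A2", "B1", "B2")}))
    two = OrthoCluster("c2", frozenset({("A1", "p"), ("B2", "q")}))
    within = OrthoCluster("cw", frozenset({("A1", "p"), ("A2", "q")}))
    clusters = [four, two, within]
    any_mode = shared_between_species(clusters, "A", "B", design4, mode="any_strain")
    both_mode = shared_between_species(clusters, "A", "B", design4, mode="both_strains")
    assert {c.cluster_id for c in any_mode} == {"c4", "c2"}
    assert {c.cluster_id for c in both_mode} == {"c4"}
    with pytest.raises(ValueError):
        shared_between_species(clusters, "A", "A", design4)


def test_shared_between_species_matches_bruteforce(design8):
    rng = random.Random(3)
    strains = design8.strain_ids
    clusters = []
    for i in range(60):
        n = rng.randint(2, 6)
        members = frozenset((rng.choice(strains), f"p{i}_{j}") for j in range(n))
        if len(members) >= 2:
            clusters.append(OrthoCluster(f"c{i}", members))
    pa = set(design8.strains_of("A"))
    pb = set(design8.strains_of("C"))
    got = {c.cluster_id for c in shared_between_species(clusters, "A", "C", design8)}
    expected = set()
    for c in clusters:
        present = set(c.signature)
        if present <= (pa | pb) and present & pa and present & pb:
            expected.add(c.cluster_id)
    assert got == expected
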