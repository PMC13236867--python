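import filecmp

import pytest

from twobytwo.classify import Category, classify_cluster
from twobytwo.design import TwoByTwoDesign
from twobytwo.io import read_gene_coordinates, read_orthogroups, read_protein_fasta, read_bgc_hits
from twobytwo.proximity import chain_by_distance, select_candidate_genes
from twobytwo.simulate import (
    SINGLETON,
    SimulationParams,
    evaluate_recovery,
    simulate_dataset,
    write_bundle,
)


@pytest.fixture(scope="module")
def bundle():
    return simulate_dataset(SimulationParams(seed=11))


def test_params_validation():
    with pytest.raises(ValueError):
        SimulationParams(strain_rate=0.5, species_rate=0.1).validate()
    with pytest.raises(ValueError):
        SimulationParams(paralog_probability=1.5).validate()
    with pytest.raises(ValueError):
        SimulationParams(n_species=1).validate()
    with pytest.raises(ValueError):
        SimulationParams(planted_cluster_size=30, genes_per_contig=25).validate()


def test_truth_bookkeeping(bundle):
    p = bundle.params
    d = bundle.design
    assert isinstance(d, TwoByTwoDesign)
    core = bundle.truth.families_by_category(Category.CORE.value)
    assert len(core) == p.n_core_families
    for fam in core:
        assert {s for s, _ in fam.members} == set(d.strain_ids)
    sp_self = bundle.truth.families_by_category(Category.SPECIES_SELF.value)
    assert len(sp_self) == p.n_species_specific * p.n_species
    st_self = bundle.truth.families_by_category(Category.STRAIN_SELF.value)
    assert len(st_self) == p.n_strain_specific * 2 * p.n_species
    singles = bundle.truth.families_by_category(SINGLETON)
    assert len(singles) == p.n_singletons * 2 * p.n_species


def test_same_seed_byte_identical_different_seed_differs(tmp_path):
    params = SimulationParams(seed=5, n_core_families=4, n_species_specific=4,
                              n_strain_specific=2, n_singletons=2, n_planted_proximity=1,
                              planted_cluster_size=3)
    d1, d2, d3 = tmp_path / "r1", tmp_path / "r2", tmp_path / "r3"
    write_bundle(simulate_dataset(params), d1)
    write_bundle(simulate_dataset(SimulationParams(**{**params.__dict__, "seed": 5})), d2)
    write_bundle(simulate_dataset(SimulationParams(**{**params.__dict__, "seed": 6})), d3)
    files = sorted(p.name for p in d1.iterdir())
    match, mismatch, errors = filecmp.cmpfiles(d1, d2, files, shallow=False)
    assert mismatch == [] and errors == []
    _, mismatch3, _ = filecmp.cmpfiles(d1, d3, files, shallow=False)
    assert "species1_s1.faa" in mismatch3  # different seeds -> different sequences


def test_written_bundle_parses_with_package_readers(tmp_path, bundle):
    """Every file the generator writes is readable by the toolkit's own readers."""
    write_bundle(bundle, tmp_path)
    d = bundle.design
    for strain in d.strain_ids:
        recs = read_protein_fasta(tmp_path / f"{strain}.faa", strain)
        assert {r.protein_id for r in recs} == set(bundle.proteomes[strain])
        coords = read_gene_coordinates(tmp_path / f"{strain}.gff3", strain)
        assert {c.gene_id for c in coords} == set(bundle.coordinates[strain])
    clusters, unassigned = read_orthogroups(tmp_path / "orthogroups.tsv", "long", d)
    assert {c.members for c in clusters} == {c.members for c in bundle.orthogroups}
    hits = read_bgc_hits(tmp_path / "bgc_hits.tsv", d)
    assert hits == bundle.bgc_hits


def test_planted_proximity_clusters_satisfy_gap_rule(bundle):
    for planted in bundle.truth.proximity:
        coords = bundle.coordinates[planted.strain_id]
        genes = sorted((coords[g] for g in planted.gene_ids), key=lambda g: g.start)
        assert len(genes) >= 2
        for a, b in zip(genes, genes[1:]):
            assert b.start - a.end - 1 <= 5000
            assert a.contig == b.contig == planted.contig


def test_nonplanted_adjacent_gaps_exceed_threshold(bundle):
    """Chaining candidate genes recovers exactly the planted clusters."""
    for sp in bundle.design.species_ids:
        ref = bundle.design.reference_strain(sp)
        genes, skipped = select_candidate_genes(
            bundle.orthogroups, bundle.coordinates[ref], bundle.design, sp
        )
        assert skipped == 0
        chains = chain_by_distance(genes, bundle.design)
        planted = {
            p.gene_ids for p in bundle.truth.proximity if p.species_id == sp
        }
        assert {c.gene_ids for c in chains} == planted


def test_truth_bgc_presence_consistent_with_hits(bundle):
    by_ref: dict[str, set[str]] = {}
    for h in bundle.bgc_hits:
        if h.reference_id:
            by_ref.setdefault(h.reference_id, set()).add(
                bundle.design.species_of(h.strain_id)
            )
    assert by_ref == bundle.truth.bgc_presence


def test_noiseless_classification_recovers_truth_exactly(bundle):
    clustered = set()
    for c in bundle.orthogroups:
        clustered |= c.members
    singles = [
        (s, p)
        for s, prots in bundle.proteomes.items()
        for p in prots
        if (s, p) not in clustered
    ]
    rep = evaluate_recovery(bundle.truth, bundle.orthogroups, singles, bundle.design)
    assert all(v == 1.0 for v in rep.precision.values()), rep.precision
    assert all(v == 1.0 for v in rep.recall.values()), rep.recall


def test_recovery_report_detects_split_family(bundle):
    """Splitting one species-self family lowers its recall by 1/n."""
    from twobytwo.cluster import OrthoCluster

    clusters = list(bundle.orthogroups)
    victim_i = next(
        i for i, c in enumerate(clusters)
        if classify_cluster(c, bundle.design).label is Category.SPECIES_SELF
        and len(c.members) >= 2
    )
    victim = clusters.pop(victim_i)
    members = victim.sorted_members()
    # split into per-strain halves (each >= 1 member; may fall below size 2 -> drop)
    by_strain: dict[str, list] = {}
    for m in members:
        by_strain.setdefault(m[0], []).append(m)
    for j, (strain, ms) in enumerate(sorted(by_strain.items())):
        if len(ms) >= 2:
            clusters.append(OrthoCluster(f"{victim.cluster_id}_split{j}", frozenset(ms)))
    rep = evaluate_recovery(bundle.truth, clusters, [], bundle.design)
    n_truth = rep.n_truth[Category.SPECIES_SELF.value]
    assert rep.recall[Category.SPECIES_SELF.value] == pytest.approx(1.0 - 1.0 / n_truth)


def test_annotations_reference_real_proteins(bundle):
    for rec in bundle.annotations:
        assert rec.protein_id in bundle.proteomes[rec.strain_id]
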