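# twobytwo

Two-by-two comparative genomics for fungal (and fungus-like) genome mining.

## The problem

Fungal genomes are gene-dense and vary substantially even between closely
related strains, so naive one-genome-per-species comparisons confuse genuine
species-specific genes with assembly gaps and gene-prediction errors.  The
two-by-two design addresses this by analysing **exactly two independently
assembled strains per species**: a gene family called unique to a species must
self-cluster between both of its strains — replicating in two independent
assemblies — before it is believed.  The same replication logic applies to
biosynthetic gene cluster (BGC) presence calls.

`twobytwo` implements this analysis as a library plus a thin CLI, for
comparative genomicists shortlisting species-specific proteins and candidate
novel gene clusters before committing to expensive functional work.

## What it computes

Given a design (strain → species → taxonomy family, two strains per species),
an orthogroup table (external, e.g. OrthoFinder-style, or from the built-in
clusterer), gene coordinates (GFF3), BGC region hit tables and annotation
tables, the toolkit produces:

* **Cluster classification.**  Each ortholog cluster is labelled by the set
  of strains present: `CORE` (every strain represented — the pan-group gene
  set), `SPECIES_SELF(s)` (exactly the two strains of species *s*, both
  present — the high-confidence species-unique families), `STRAIN_SELF(t)`
  (≥ 2 members, all from one strain — paralog families), or `PARTIAL`.
  Singleton proteins are tallied per strain.  Built-in clustering is
  reciprocal-best-hit (Smith–Waterman, BLOSUM62, gaps 11/1, scores normalised
  by the smaller self-score) followed by connected components.
* **BGC presence matrix.**  A reference-cluster × strain grid of best percent
  similarity to known references, with 25-point similarity bins, species
  roll-ups (absent / one strain / both strains), per-species strain
  concordance (shared, unique-to-each, union) and group-wide species
  uniqueness (how many matched references occur in exactly one species).
* **Proximity clusters.**  Species-unique genes mapped back to a reference
  strain's genome and chained by single linkage whenever adjacent inter-gene
  gaps are ≤ 5 kb — candidates for novel gene clusters missed by rule-based
  BGC predictors.
* **Annotation & prioritisation.**  Precomputed homology/domain/signal-peptide
  tables joined onto clusters, ranked by configurable keyword sets
  (pathogenesis, biosynthesis, transport, ...).
* **Synthetic data.**  A generator that plants core/species/strain-specific
  families at controlled divergence, physical gene clusters obeying the gap
  rule, and BGC overlap structure — with a truth table, so every stage is
  testable offline (`twobytwo.simulate`).

## Worked example

Simulate a 3-species dataset and run the analyses:

```bash
twobytwo simulate --seed 1 --out demo/sim
twobytwo classify   --design demo/sim/design.tsv --orthogroups demo/sim/orthogroups.tsv --out demo/cls
twobytwo bgc-matrix --design demo/sim/design.tsv --hits demo/sim/bgc_hits.tsv --out demo/bgc
twobytwo proximity  --design demo/sim/design.tsv --orthogroups demo/sim/orthogroups.tsv \
                    --gff species1_s1=demo/sim/species1_s1.gff3 --out demo/prox.tsv
```

prints:

```
200 clusters: core=20, species_self=60, strain_self=120, partial=0
species1: shared=5 unique=0/1 union=6
species2: shared=5 unique=1/0 union=6
species3: shared=5 unique=1/0 union=6
matched references: 14, species-unique: 12 (85.7%)
2 proximity clusters -> demo/prox.tsv
```

The classification line is the category partition of the simulated orthogroup
table (20 core families, 20 species-self per species, 20 strain-self per
strain).  Each `shared=5 unique=…` line is one species' BGC strain
concordance: of the 6 references matched in at least one of its strains, 5
replicate in both and 1 is private to a single strain.  The last line is the
species-uniqueness summary over the 14 matched references.  The proximity
table lists maximal chains of species-unique genes with adjacent gaps ≤ 5 kb,
e.g.:

```
species_id  strain_id    contig               span_start  span_end  n_genes  gene_ids                                                         max_gap_observed
species1    species1_s1  species1_s1_contig2  86641       90518     3        fam_sp_species1_0001;fam_sp_species1_0002;fam_sp_species1_0003   1851
```

The package also ships a real worked example: a 16-strain / 8-species /
3-family Hypocreales design and 19 curated species-self ortholog clusters
whose products (oosporein, cordycepin and swainsonine pathway proteins,
cuticle-degrading proteases, sorbicillinoid and verlamelin biosynthesis
proteins, ...) are known to be species-specific:

```python
from twobytwo.examples import hypocreales_design, curated_species_self_clusters
from twobytwo.classify import summarize

design = hypocreales_design()
clusters, annotations = curated_species_self_clusters()
summary = summarize(clusters, [], design)
print({sp: n for sp, n in summary.species_self_count.items() if n})
# {'Cordyceps_militaris': 3, 'Beauveria_bassiana': 4, 'Metarhizium_brunneum': 9,
#  'Epichloe_festucae': 2, 'Trichoderma_reesei': 1}
```

Every curated cluster classifies as a species self-cluster of its own species
— the positive control validating the category rules.

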