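# Methods

## The two-by-two design

The unit of analysis is a *design*: an ordered set of strains in which every
species contributes exactly two independently assembled strains (at least two
species; taxonomy family is optional metadata with no cardinality rule).
The rationale is replication: a gene family or BGC presence call that is
observed in both strains of one species and in no other strain is unlikely to
be an assembly or gene-prediction artifact, because the two assemblies were
produced independently — often with different technologies and of different
quality.  Strain IDs are case-sensitive and whitespace-trimmed; design
violations (wrong strain count, duplicate IDs) are reported naming the
offending species or strain.

## Cluster classification

Each ortholog cluster is reduced to its *composition signature* — the map
from strain to member count — and classified by the **set** of strains
present, in this order:

1. `CORE`: every strain of the design has ≥ 1 member.  Core status is defined
   over strains, not species, so a family missing from a single strain is not
   core.
2. `SPECIES_SELF(s)`: the strains present are exactly the two strains of
   species *s*.  Paralog multiplicity is allowed (counts > 1 per strain);
   what defines the category is the strain set, and real species-unique
   families frequently carry 3–4 members from duplications.
3. `STRAIN_SELF(t)`: exactly one strain present (≥ 2 members) — a
   within-strain paralog family, tallied separately from species calls.
4. `PARTIAL`: everything else.

The rules are mutually exclusive by construction (a valid design has ≥ 2
species, so the CORE and SPECIES_SELF conditions cannot coincide); the
partition invariant — every cluster in exactly one category — is asserted on
every summary.  Singletons (proteins in no cluster) are a separate per-strain
tally, counted two ways and reported separately: members of one-member groups
in the orthogroup table ("unassigned"), plus, when full proteomes are
supplied, proteins appearing nowhere in the table.  Because the published
tally of total clusters per species is ambiguous between "≥ 1 member from
the species" and "both strains present", the summary reports both variants.

`shared_between_species` answers the pairwise query — clusters drawn only
from two species' strains with both species represented (`any_strain`) or
all four strains represented (`both_strains`).

## Built-in ortholog clustering

A deliberately simple, fully deterministic desk-scale stand-in for external
orthogroup pipelines, so the whole workflow is executable from raw FASTA:

* **Scoring.**  Local (Smith–Waterman) alignment with BLOSUM62 and affine
  gaps, open 11 / extend 1 (a gap of length *k* costs 11 + (k−1)); the
  normalized similarity is the alignment score divided by the smaller of the
  two self-alignment scores — 1.0 for identical sequences, ≈ 0 for unrelated
  ones.  Any substitution matrix and gap costs can be configured.
* **Edges.**  Reciprocal best hits between every strain pair: an edge needs
  each protein to be the other's unique best partner (score ties resolved to
  the lexicographically smallest protein ID, making output deterministic) at
  normalized score ≥ `min_score` (default 0.3).  Within-strain edges use the
  same rule against the proteome itself excluding self-pairs, so paralog
  (strain-self) families can form.
* **Prescreen.**  Only pairs sharing at least one exact 5-mer are aligned
  (`prefilter_kmer`, 0 disables).  A pair without a single shared 5-mer is
  far below any usable `min_score`, so this changes no edges while skipping
  the all-vs-all alignment of unrelated sequences.
* **Clusters.**  Connected components of the edge graph; components of size
  ≥ 2 become clusters (IDs assigned by sorted smallest member), the rest are
  singletons.  The partition property (every protein in exactly one cluster
  or the singleton list) is asserted on every run.

Connected components over RBH edges approximate, but do not promise to
match, MCL-based pipelines; downstream modules therefore accept any
orthogroup table (wide or long dialect) and never depend on this module.
The default `min_score` 0.3 sits with wide margin between the similarity of
two strains of one species (a few percent divergence → score ≈ 0.9) and
unrelated sequences (score ≈ 0) under the synthetic divergence defaults
below.

## BGC matrix

Input is a normalized region-hit TSV (one row per predicted region: strain,
coordinates, type, best known-reference ID, percent similarity; empty
reference iff similarity 0), rather than raw predictor output whose schema
is version-volatile.  The matrix cell (reference, strain) is the maximum
similarity over that strain's regions hitting the reference; unmatched
regions count toward per-strain region totals but create no cell.
Similarity display bins are upper-inclusive 25-point integer intervals
(0 absent, 1–25, 26–50, 51–75, 76–100) and are configurable cut points.
Species presence distinguishes `one_strain` from `both_strains` because
single-strain calls are exactly the ones that may reflect assembly quality
rather than biology.  Strain concordance for a species is computed over
references matched in ≥ 1 of its strains: (shared, unique-to-strain-1,
unique-to-strain-2, union).  Species uniqueness counts references present in
exactly one species; the percentage is rounded half-up to one decimal.
Reference identity is the opaque reference ID string; near-duplicate
references are not merged.

## Proximity clusters

Genes belonging to a species' self-clusters are mapped to the genome of one
designated reference strain per species (the `is_reference` flag in the
design file; default the first strain listed — in practice the most
contiguous assembly).  Genes are sorted by start per contig and chained by
single linkage: a gene joins the current chain iff the gap between its start
and the chain's rightmost end so far (exclusive of both genes) is ≤
`max_gap_bp`, default 5000, inclusive at the boundary; overlapping genes
(negative gap) always join.  Strand is ignored — fungal secondary-metabolite
clusters freely mix strands.  Chaining is transitive, so a chain's total
span may exceed the threshold; the rule is pairwise-adjacent, and emitted
chains (≥ 2 genes) are maximal.  Chains are not required to draw their genes
from different self-clusters.  The output orders chains by (strain, contig,
span start) and can be exported as BED (0-based half-open).

## Annotation and prioritisation

Homology, domain and signal-peptide calls are consumed as tables, never
computed.  Each cluster's representative is its best-scoring homology hit
(ties to the lexicographically smallest hit ID); members without hits carry
"No hit".  Prioritisation is transparent, case-insensitive substring search
over member descriptions against named keyword sets, ranked by (number of
distinct sets matched, representative score, cluster ID).  The default sets
(pathogenesis / biosynthesis / transport) are a starting point, not an
attempt to automate expert curation; no score threshold is applied by
default, and signal-peptide flags are propagated but do not affect rank.

## Synthetic data generator

The generator emits the full input bundle (per-strain FASTA and GFF3, a
long-dialect orthogroup table, BGC hit TSV, annotation TSV) plus a truth
table, with the structure the analysis assumes:

* **Families.**  Root sequences are independent uniform draws over the
  20-residue alphabet, length ~ Normal(120, 20) truncated at 50 — long
  enough for alignment scores to concentrate, short enough to keep the
  desk-scale runs fast.  Descendants substitute each site independently
  with probability equal to the branch rate, replacing it with a uniformly
  chosen *different* residue; no indels by default.  Rates: strain 0.02
  (between the two strains of a species), species 0.10 (between species
  ancestors within a taxonomy family), family 0.45 (between taxonomy-family
  ancestors on core-family lineages; exercised only by multi-family
  designs — the default design puts all species in one family).  Rates must
  be ordered strain < species < family.  Core families descend root →
  [family ancestor →] species ancestor → strain member; species-specific
  families root → two strain members; strain-specific families are two
  root-derived paralogs in one strain; singletons are fresh random
  sequences.  Each core/species member is duplicated into a paralog with
  probability 0.1 (strain-rate divergence).
* **Defaults.**  3 species × 2 strains, 20 families per category (core;
  species-specific per species; strain-specific per strain; singletons per
  strain) — ≈ 110 proteins per strain, enough for stable precision/recall
  estimates while a full 10-seed end-to-end run stays around ten seconds.
* **Layout.**  Genes are placed on contigs (25 genes each) in seeded-random
  unit order; gene length is 3× protein length.  Per species, the reference
  strain carries 2 planted proximity clusters of 3 consecutive
  species-specific genes with internal gaps Uniform(200, 4500) ≤ the 5 kb
  threshold; every other adjacent gap is Uniform(5500, 15000) > the
  threshold, so the planted chains are exactly the true positives and no
  accidental chain can form.  Blocks never straddle contig boundaries.
* **BGC.**  Reference profiles state which species/strains carry each
  reference and the similarity distribution (clipped to [1, 100]).  The
  default profile set per design: 3 references unique to each species (both
  strains), 2 present in all species, and 1 per species present in one
  strain only, plus 2 unmatched regions per strain — covering the unique /
  shared / discordant cases.
* **Randomness.**  All randomness flows from one integer seed;
  per-purpose/per-strain sub-streams are derived with fixed offsets
  (`default_rng([seed, stage, index])`), so adding a species does not
  perturb earlier strains.  Same seed ⇒ byte-identical bundle.

`evaluate_recovery` scores a classification against truth by exact matching:
a truth family is recovered iff some predicted cluster has exactly its
member set and the matching category (singletons match singleton-list
entries); precision/recall are reported per category and default to 1.0
where nothing was predicted / no truth exists.  Planted proximity clusters
are checked for exact member-sequence recovery, conditional on their
families having been recovered.

What the generator does *not* emulate: indel evolution (optional extension),
codon structure, gene gain/loss on a phylogeny, horizontal transfer,
contamination and fragmented assemblies.  Passing recovery tests therefore
demonstrates correctness of the bookkeeping and the separation logic under
the stated divergence model, not robustness to real-world assembly noise.

## Numerical and engineering choices

* Coordinates are GFF3 1-based inclusive everywhere; BED export converts at
  the boundary.  The proximity gap is `next.start − prev.end − 1`.
* Member tokens `strain|protein` split on the first `|` so accessions may
  contain dots/dashes.
* The uniqueness percentage uses decimal half-up rounding (not banker's).
* Alignment gap semantics follow the common convention where a length-*k*
  gap costs `open + (k−1)·extend`; the test oracle is an independently coded
  quadratic Gotoh DP with the same convention.
* All tabular output has deterministic column order; identical inputs and
  configuration reproduce byte-identical tables, recorded in a manifest with
  a configuration hash and input checksums.
* The pipeline logs skip counts (genes without coordinates, annotation
  records without a clustered protein) since dataset-scale discrepancies in
  practice usually trace to assembly/annotation quality.

## Known limitations

* The built-in clusterer is quadratic per strain pair and intended for
  desk-scale proteomes (≲ 10⁴ proteins per strain), not production
  orthology inference.
* Keyword prioritisation is substring matching; it neither stems nor
  disambiguates (a description containing "protease inhibitor" matches
  "protease").
* BGC references are compared as opaque IDs; similarity to references is an
  input, never computed here.
* The classification is purely compositional: it inherits whatever
  over/under-merging the upstream orthogroup inference commits.
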