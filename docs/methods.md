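# Methods

This note documents the models, conventions and numerical choices behind
`mgcompare`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coverage-weighted functional profiles

The unit of observation is a predicted coding sequence (CDS) on an assembled
contig. Read mapping gives each contig a mean depth per sample; a CDS
inherits its contig's depth. The weight of a functional label *f* in sample
*s* is

    w(f, s) = Σ_{CDS carrying f} depth(contig(CDS), s)
              ─────────────────────────────────────────
              Σ_{all CDS}        depth(contig(CDS), s)

The denominator runs over *all* CDSs, annotated or not, so unannotated genes
dilute every profile equally and multiplying all depths by a constant leaves
every profile unchanged (this scale invariance is property-tested). Using
contig mean depth rather than per-CDS depth is a deliberate standardisation:
the weighting signal available after co-assembly is the contig's coverage,
and per-CDS depths would add noise without changing the comparisons.

Two counting conventions matter for multi-domain CAZymes:

- A CDS with *k* domains from *distinct* families contributes its depth once
  to each family; repeated domains of the *same* family count once. This
  prevents domain-count inflation and matches the unique-CDS correction used
  when counting lignocellulolytic genes as a fraction of all ORFs.
- The "percent of all ORFs" statistic counts unique CDSs, not domains.

GH families map to four lignocellulose-degradation roles (cellulases,
endohemicellulases, accessory hemicellulases, oligosaccharide-degrading
enzymes) via a bundled 33-family table; the per-family percentages within a
community are renormalised over lignocellulolytic GH coverage only, so the
four role subtotals sum to 100% up to 1-decimal rounding. Families outside
the table classify as "other GH"; `AA*` families are auxiliary activities
(lignin/polyphenol-acting redox enzymes). Broad-class comparisons use five
classes — cellulose GH, hemicellulose GH (backbone + side-chain), oligosaccharide
GH, auxiliary activity, other GH — on the all-CDS scope. Averaging across
sample time-points is the unweighted arithmetic mean of per-sample profiles.
Rounding to one decimal happens only at presentation time.

The bundled cross-biome table (wallaby foregut, cow rumen, termite hindgut,
compost, plus the two marsupial fecal columns) ships as printed 1-decimal
constants; those literature columns are not re-derived from their raw data.

## Pathway profiles and differential testing

KO annotations weight exactly like CAZy labels. A KO belonging to *m*
metabolism pathways contributes its full weight to each (multi-assignment,
not splitting); pathways with fewer than three distinct observed KOs are
excluded (`min_kos_per_pathway = 3`). A pathway's cumulative normalised
abundance per sample is the sum over its observed member-KO weights.

Between two hosts, per-pathway proportions across sample time-points are
compared with Welch's unequal-variance *t*-test (two-sided, Satterthwaite
degrees of freedom) and Benjamini–Hochberg step-up FDR; pathways are flagged
at *q* < 0.05 and ranked by effect size = difference in mean proportions,
with a lexicographic feature-id tie-break for reproducibility. Taxon tables
use the same machinery but flag on raw *p* < 0.05, matching the convention
of reporting discriminating lineages by effect size among nominally
significant groups.

Compositional profiles routinely contain degenerate features, so the
conventions are explicit: all-zero features are dropped before testing (with
a logged count); two zero-variance groups with equal means give *p* = 1;
zero variance with unequal means gives *p* = 0. Two-sided tests throughout;
enrichment is reported in both directions.

A caution the synthetic experiments make visible: with a handful of
time-points from two *fixed* communities, the Welch test detects any stable
compositional difference between the communities, not only "interesting"
ones — many background pathways are flagged when two communities are drawn
independently. The false-positive control experiment therefore splits
samples of a *single* community (where the group null truly holds), while
the power experiment spikes a known pathway into one of two communities and
asks whether that specific pathway is recovered.

## Community structure

Taxon profiles are filtered at a minimum relative abundance of 0.05%
(retained if any sample passes), renormalised per sample (logged choice, as
the original order of operations is filter-then-cluster), optionally
aggregated at a rank (lineages unclassified at that rank aggregate under
their deepest classified ancestor with an `unc_` label), and compared with
abundance-weighted Bray–Curtis dissimilarity, *d = 1 − 2·Σmin(x,y)/Σ(x+y)*.
Two all-zero vectors are defined to have *d* = 0 with a warning. Sample
clustering is UPGMA (average linkage) on the Bray–Curtis matrix; samples are
sorted lexicographically before linkage so merge-height ties resolve
identically regardless of input order. Dendrograms export as ultrametric
Newick (leaf heights 0, node height = merge distance / 2).

## Population-genome metrics

- **Quality filter:** completeness ≥ 50% and contamination ≤ 10%, inclusive
  on both boundaries; rejects are logged with the failing criterion.
- **Abundance:** a bin's share of length-weighted contig coverage,
  Σ length·depth over bin contigs ÷ Σ over all contigs. Length-weighting
  makes the estimate equal the bin's fraction of sequenced bases — the
  quantity community-representation figures report — where an unweighted
  mean of contig depths would over-weight short contigs.
- **Top-N selection:** by median per-sample abundance, ties broken by mean
  (a genome whose median is 0 still ranks by its mean), then bin id.
- **Pathway coverage:** |bin KOs ∩ universe| / |universe|, where the
  universe is the union of the pathway's KOs across all passing bins from
  *both* communities, making coverages comparable across hosts. Pathways
  with empty universes are omitted.
- **PCA:** each genome is a composition of pathways (KO counts per pathway,
  ≥3 KOs, normalised per genome); the genome × pathway matrix is column
  centered (covariance PCA, not correlation — the inputs are already
  proportions on a common scale) and decomposed by SVD. Within each
  component the largest-magnitude pathway loading is made positive, fixing
  the sign deterministically. A constant matrix yields all-zero coordinates
  and variance fractions.
- **Contributor score:** |unique bin KOs belonging to ≥1 host-differential
  pathway| ÷ (completeness/100). The phrase "weighted by completeness" is
  ambiguous between multiplication and division; division is adopted so
  that an incomplete genome's observed KO count is scaled up to an
  estimated-complete value (a 50%-complete genome's count doubles), which
  is the direction that makes incomplete genomes comparable to complete
  ones. The ranking is invariant to expressing completeness as percent or
  fraction.
- **Urea screen:** transport requires the complete five-subunit Urt ABC
  transporter or the monomeric Utp channel; ureolysis requires all three
  structural urease subunits; accessory (maturation) completeness is
  reported separately. Because the underlying literature names gene
  products rather than KO identifiers, the KO sets ship as an editable YAML
  config with documented defaults (Urt = K11959–K11963, Utp = K08717,
  urease = K01428/K01429/K01430, accessories = K03187–K03190).
- **Average genome size:** abundance-weighted mean of size/(completeness
  fraction) over passing bins — a deliberately simple, assembly-based
  companion readout, not a read-level estimator.

## AAI

Ortholog detection uses exact affine-gap Smith–Waterman local alignment
(BLOSUM62, gap open 11, extend 1 — the common protein-search defaults) in
place of a heuristically seeded database search: the semantics are
deterministic and dependency-free, at O(n²·L²) cost, so the CLI caps
proteome size (deterministic id-order subsampling) for large inputs.
"Best-scoring" uses the raw substitution score (ties break by identity then
subject id). Identity is exact matches over aligned columns; gap columns
count toward coverage (aligned columns ÷ shorter sequence length, capped at
1) but not identity. Hits must reach 30% identity and 70% coverage; a
reciprocal pair of best hits is an ortholog. AAI is the mean of ortholog
identities with the population (n-denominator) standard deviation; zero
orthologs yield an explicit `None` mean rather than a silent 0. Because
matrix and gap penalties are symmetric, the score matrix is computed once
and reused for both directions, making aai(A,B) ≡ aai(B,A) exactly.

## Synthetic community generator

The generator emulates the target study design: two host communities, host A
sampled at 3 time-points and host B at 5, each with (by default) 12
population genomes of 6–10 contigs (20–80 kb, 15–25 CDSs per contig).
Choices and rationale:

- **Abundances** are lognormal(0, 1) across genomes, normalised — the
  standard model for rank-abundance in gut communities. Ground-truth
  "abundance" is recorded as the genome's fraction of sequenced bases
  (abundance × genome length, renormalised), the same quantity the
  estimator measures, so zero-noise recovery is exact by construction.
- **Coverage noise** is multiplicative lognormal per contig per sample with
  mean exactly 1 and a single CV knob (default 0.2, a moderate level for
  repeated fecal sampling). The pipeline consumes mean depths, not reads,
  so Poisson read-count noise is out of scope.
- **Function content:** 40 shared pathways plus 5 differential pathways per
  host, 5 KOs each, carried per genome with probability 0.2 (baseline) or
  min(1, 0.2 × effect) in the differential host (default fold-effect 4).
  CDSs additionally receive a GH family with probability 0.10 and an
  auxiliary-activity family at a host-specific rate (0.03 vs 0.01),
  mirroring the lignin-degradation asymmetry between a folivore and a
  grazer.
- **Bin corruption:** completeness removes whole contigs (drawn from
  60–100%), mirroring how incomplete bins actually lose sequence;
  contamination (0–5%) donates other genomes' removed contigs. Realised
  values, recomputed from the contig content, are what the metadata
  reports.
- **Proteomes** are i.i.d. residues from fixed background amino-acid
  frequencies; divergent pairs are created by per-site substitution to a
  random different residue with probability *d*, so expected identity is
  1−*d*. This is adequate for AAI-recovery testing (identity is the
  target statistic) but deliberately not an alignment benchmark: real
  proteins have conserved domains, indels and compositional bias.

What passing tests show: the pipeline's estimators recover known truth
under the stated noise model, its statistics control false positives under
a true group null, and its conventions are internally consistent. What they
do not show: behaviour under assembly artifacts, chimeric bins, strain
mixtures, read-level biases, or annotation error — none of which the
generator models — and no dataset-scale number from any real study is
asserted anywhere in the suite.

## Problem sizes

Default experiment sizes (null: 20 replicates of a 100-pathway community;
power: 50 replicates; AAI: 200 proteins × 300 aa across five divergence
levels; weighting oracle: 100 random micro-communities) keep the full test
suite and the acceptance script each within a few minutes on one CPU while
leaving Monte-Carlo error well inside the asserted tolerances.
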