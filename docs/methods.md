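# Methods

## Problem and model

Given a set of genome assemblies annotated with six taxonomic ranks
(species, genus, family, order, class, phylum), every unordered pair of
genomes is assigned to the stratum of the most specific rank the two
lineages share: pairs of the same species form the species stratum; pairs
of different species within one genus form the genus stratum; and so on.
Pairs differing at the phylum level belong to no stratum. If genomic
distance tracks taxonomic depth, the strata form ordered, largely disjoint
distance distributions, and a single fixed cut between two adjacent strata
is an operational criterion for that rank — for the species|genus pair, a
genomic species boundary analogous to the ANI thresholds used in bacterial
taxonomy.

## Distance estimators

All three estimators operate on the set of distinct canonical k-mers of a
genome (the lexicographic minimum of each length-k window and its reverse
complement; windows containing an ambiguous base are skipped, and k-mers
never span record boundaries). Default k = 16 — a compromise between
resolution at low ranks (large k) and sensitivity between divergent genomes
(small k). Inputs are uppercased, so soft-masked assemblies are handled.

1. **mash** (orientation: distance). A bottom-s MinHash sketch keeps the s
   smallest distinct 64-bit hashes of the k-mers (default s = 100,000 —
   large sketches keep the estimator usable between divergent genomes).
   The Jaccard index j is estimated from the merged sketch: of the s
   smallest values of the union of the two hash lists, the fraction present
   in both (the low-bias merged-sketch estimator; its error scales as
   sqrt(j(1−j)/s)). The Mash distance D = −(1/k)·ln(2j/(1+j)) is a proxy
   for per-site divergence (1 − ANI): under independent substitutions at
   rate d each k-mer survives with probability ≈ e^{−kd}, giving
   E[j] ≈ 1/(2e^{kd} − 1), which the transform inverts. j = 0 maps to the
   cap D = 1 rather than infinity.
2. **hll_similarity** (orientation: similarity). HyperLogLog sketches with
   2^p registers (default p = 20) estimate the cardinalities of each k-mer
   set and of their union (register-wise maximum); the Jaccard estimate is
   (Ĉ(A)+Ĉ(B)−Ĉ(A∪B))/Ĉ(A∪B), clamped at 0. The estimator is the classic
   harmonic-mean form with the small-range linear-counting correction
   (relative error ≈ 1.04/√2^p); the maximum-likelihood refinements in the
   literature are deliberately not implemented. Identical sketches give
   exactly 1 by construction.
3. **kmer_overlap** (orientation: similarity). The exact, slow reference
   path: (|A∩B| − |A|·|B|/4^k)/min(|A|,|B|). The subtracted term is the
   expected overlap of two independent uniform-random k-mer sets of those
   sizes (a capture–recapture argument), so unrelated genomes score ≈ 0 —
   slightly negative values are legitimate. A set against itself scores
   exactly 1 − |A|/4^k.

Hashing is a seedable splitmix64 finalizer over the 2-bit k-mer encoding
(default seed 42). Any high-quality 64-bit hash would do: thresholds depend
on the statistics of the estimates, not on particular hash values, so no
bit-compatibility with other tools' sketch files is intended. Sketches are
deterministic, serialisable to JSON, computed once per genome and reused
across all strata; an optional cache directory persists them between runs
without changing any value.

## Threshold search

The equal-error cut between a lower (more specific) and higher stratum is
found by bisection over the closed interval between the two stratum
medians. At each midpoint the wrong-side shares are computed — for a
distance, the lower stratum is wrong above the cut and the higher below it;
mirrored for a similarity — and the boundary moves toward the wrongly
classified values of the stratum with the larger share. The search stops
when the shares differ by less than 1e-4 or after 100 halvings (then
`converged` is False; with finite samples the shares are step functions and
exact equalisation may be unattainable). Ties exactly at the threshold
count as correct for the lower stratum — floating-point equality has to be
assigned somewhere, and this choice is fixed and tested. The pooled
misclassified fraction (wrong pairs over all pairs) is reported alongside
the two per-stratum shares: the search equalises the shares rather than
minimising the pooled error, but the two notions coincide as the shares
equalise, and pooled remains well-defined when the search does not
converge. The threshold always lies within the span of the two medians.

## Dataset shaping and curation

Species with fewer than 3 genomes are dropped (a pair within a 2-genome
species carries no information about within-species spread beyond a single
value); species with more than 10 are down-sampled uniformly at random
(seeded) to cap the weight of intensely sequenced taxa. Records lacking a
species annotation are dropped at this stage, since their species count is
unknowable. Curation then removes, with an audit trail: species in a
user-supplied outlier list, genera in an outlier-genus list, hybrid-named
species (" x " or the word "hybrid" in the name) and strain-coded species
("sp." followed by an alphanumeric code). The name-pattern rules are
regex-based and auditable; the default exclusion lists name fungal taxa
documented as threshold violators but are fully overridable. Taxa are
compared as exact strings; pairs involving a genome with a missing
intermediate rank are skipped for the strata that need that rank.

## Synthetic clades

The generator emulates a registry of genomes whose divergence is layered by
rank. A random ancestor genome (i.i.d. bases at a configurable GC content)
roots a taxon tree built top-down; each rank has a per-site divergence
(defaults: strain 0.002, species 0.03, genus 0.08, family 0.12, order 0.16,
class 0.20, phylum 0.25 — strictly increasing toward the root, with the
species value in the range of observed between-sibling-species ANI gaps and
the strain value representing typical conspecific divergence). The first
child of every taxon inherits the parent ancestor unchanged — the parent's
type lineage persists, as in peripatric budding — and every further child
is an independently mutated copy. This star-like, type-lineage model is far
simpler than a coalescent and has two useful exact properties: the minimum
between-species distance within a genus equals the species divergence, so
the default profile guarantees clean species|genus separation; and pushing
the species divergence down to about twice the strain divergence makes the
type-genome pairs of sibling species exactly as close as two strains of one
species, reproducing the overlapping regime where a fixed threshold must
fail (pooled misclassification ≈ 6% at the default registry shape).

Mutations are independent per-site substitutions (uniform over the three
alternative bases). Indels (1–10 bp, insertion or deletion with equal
odds) exist for robustness experiments but default to zero so closed-form
k-mer survival arguments hold exactly. Optional edge cases for curation
tests append to the first genus: a hybrid-named species and a strain-coded
species, both with inflated within-species divergence (hybrids are
divergent from their parents; strain-coded entries mimic mislabelled
entities), and an overdispersed but normally named outlier species that
name-based curation cannot catch. Everything — registry, FASTA bytes
(gzip mtime pinned to 0), lineage and truth TSVs — is byte-identical for a
fixed seed. The generator records the true pairwise divergence (sum of
nominal branch rates below the last shared taxon) for every pair.

What the simulation does *not* emulate: repeats, ploidy, chromosome
structure, horizontal transfer, rate variation among lineages, and the
skewed species composition of real archives. Passing tests therefore show
that the estimators and the threshold machinery behave correctly on
rank-layered divergence, not that any particular numeric threshold carries
over to real genomes — thresholds are dataset-dependent by nature and the
pipeline recomputes them for whatever input it is given.

## Numerical choices and problem sizes

* k-mers are held as 2-bit encodings in sorted unique uint64 arrays;
  set operations are array merges, so the "exact" path is feasible well
  beyond the sizes used in tests.
* HLL leading-zero ranks are computed with integer bit-length bisection
  (no float log2, which mis-rounds near 2^53).
* The default test/validation registry is 2 phyla × 5 genera × 3 species ×
  3 genomes of 50 kb — enough pairs (90 within-species, 270 genus, 1620
  family) for stable medians and shares while keeping a full three-method
  run under a minute on one core. Estimator-accuracy checks use 100 kb–1 Mb
  sequences where the binomial bounds being tested are tight.
* Equal-error bisection is validated against a 10⁶-point grid-scan oracle
  on random two-Gaussian instances in the overlapping regime, where the
  equal-error point is dense in data and the comparison is meaningful to
  ±10⁻³.

## Known limitations

* The MinHash and HLL estimates degrade for highly divergent genome pairs
  (tiny Jaccard): mash values near the cap of 1.0 compress the upper strata,
  which is visible in the family/order summaries and is inherent to sketch
  methods at fixed k.
* `hll_similarity` of near-disjoint sets can be a small positive value
  (estimator noise clamped at 0), so similarity thresholds very close to 0
  are less reliable than mid-range ones.
* Curation acts on name patterns and explicit lists only; it cannot detect
  a mislabelled genome with a well-formed name.
* Lineages are compared as strings; synonymy and rank inconsistencies in
  the input propagate into the strata (pairs with inconsistent lineages may
  land in more than one stratum, which the partition tests exclude by
  construction but real registries do not guarantee).
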