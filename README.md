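# taxodist

Fixed genomic-distance thresholds for delineating species (and higher
taxonomic ranks) from whole-genome assemblies.

Mycologists and microbial taxonomists increasingly ask whether two sequenced
strains belong to the same species. `taxodist` implements the alignment-free
answer: summarise each genome as its set of canonical k-mers, estimate a
pairwise genomic distance, stratify all genome pairs by the most specific
taxonomic rank they share (within species / between species of one genus /
between genera of one family / …), and search for a single *equal-error
threshold* that separates adjacent strata — most usefully the within-species
from the between-species stratum, where such a cut acts as an operational
species criterion analogous to the ~95% ANI rule used for bacteria.

## Methods

Three distance estimators over the canonical k-mer sets *A*, *B* (default
k = 16):

| method | value | orientation |
|---|---|---|
| `mash` | D = −(1/k)·ln(2j/(1+j)) from a bottom-s MinHash estimate of the Jaccard index j (s = 100,000) | distance (same species *below* threshold) |
| `hll_similarity` | Jaccard estimate (Ĉ(A)+Ĉ(B)−Ĉ(A∪B))/Ĉ(A∪B) from HyperLogLog cardinalities, 2^p registers (p = 20) | similarity (same species *above* threshold) |
| `kmer_overlap` | (\|A∩B\| − \|A\|·\|B\|/4^k) / min(\|A\|,\|B\|) — exact overlap minus the capture–recapture chance expectation, as a share of the smaller set | similarity |

The Mash distance is a proxy for 1 − ANI: under independent point
substitutions at per-site rate d, E[j] ≈ 1/(2e^{kd} − 1), so D ≈ d.

Thresholds between two strata are found by bisecting the interval between
the stratum medians until both strata have a nearly identical share of pairs
on the wrong side of the cut (share difference < 10⁻⁴, at most 100
halvings); the pooled misclassified fraction at that cut is reported
alongside (accuracy = 1 − pooled).

A synthetic-clade generator produces registries of genomes with
rank-layered divergence (plus hybrid-named, strain-coded and overdispersed
outlier species for curation tests), so the whole pipeline is testable
without downloading any assembly.

## Worked example

```python
from taxodist import CladeConfig, RunConfig, generate_registry, run_all

registry = generate_registry(
    CladeConfig(genome_length=20_000, n_phyla=1, n_genera=2,
                n_species=3, genomes_per_species=3, seed=11),
    out_dir="demo",            # writes *.fna.gz + lineage.tsv + truth.tsv
)
result = run_all(list(registry.records), RunConfig(seed=11))
print(result.summaries[result.summaries.method == "mash"].to_string(index=False))
print(result.thresholds[["level_pair", "method", "threshold",
                         "pooled_misclassified", "converged"]].to_string(index=False))
```

prints

```
method   level  n_pairs   median     mean
  mash species       18 0.002133 0.002644
  mash   genus       54 0.033940 0.041602
  mash  family       81 0.113328 0.122151
   level_pair         method  threshold  pooled_misclassified  converged
species|genus           mash   0.018036                   0.0       True
 genus|family           mash   0.073634                   0.0       True
species|genus hll_similarity   0.672170                   0.0       True
 genus|family hll_similarity   0.169357                   0.0       True
species|genus   kmer_overlap   0.773713                   0.0       True
 genus|family   kmer_overlap   0.319816                   0.0       True
```

The stratum medians climb with rank (0.002 within species, 0.034 between
species of a genus, 0.113 between genera of a family — mash distance
approximates per-site divergence), and every adjacent-rank threshold
converged with 0% of pairs misclassified: at these simulated divergences a
single fixed cut cleanly separates each rank from the next.

The same pipeline runs from a shell on any directory of FASTA files plus a
lineage TSV (columns: accession, species, genus, family, order, class,
phylum):

```sh
taxodist run-all --input-dir genomes/ --lineage-table lineage.tsv \
    --output-dir out/ --method mash --method hll_similarity
```

producing `distances.tsv` (one row per genome pair and method),
`summaries.tsv` (per-rank pair counts, medians, means), `thresholds.tsv`
(one row per method and adjacent rank pair, with wrong-side shares,
iteration count and convergence flag) and `audit.tsv` (every genome dropped
by the ≥3-genomes filter, the ≤10-genomes down-sampling or curation, with a
reason). Subcommands `simulate`, `sketch`, `dist`, `pairs` and `threshold`
expose the individual stages; see `taxodist <cmd> --help`.

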