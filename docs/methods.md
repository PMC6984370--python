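# Methods

## The problem and the model

When a human genome is assembled de novo, a fraction of the contigs
cannot be placed on the reference assembly.  After quality control,
those unmappable contigs contain *novel sequence* (NS): haplotypes
segregating in the population but absent from the reference.  This
package re-creates the full population-scale characterisation of such
sequence — discovery, frequency estimation, repeat composition,
genomic positioning, unmapped-read (UR) recapture, and the ancestral
subset visible as deletions relative to a chimpanzee-like genome — as a
tested pipeline over a synthetic cohort with complete ground truth.

The stages and their governing rules:

1. **QC + clustering.**  Contigs from all individuals are clustered
   greedily, longest first, CD-HIT style: a contig joins the first
   existing cluster whose representative it matches at identity ≥ c
   (0.95) with aligned coverage ≥ aS (0.90) of the shorter and ≥ aL
   (0.90) of the longer sequence; otherwise it founds a cluster.
   Contaminant clusters (a significant non-primate BLAST-like hit,
   E < 1e-40, and no significant primate hit) and clusters represented
   by sequences < 301 bp are removed.  A cluster's allele frequency is
   the number of distinct individuals contributing members divided by
   the cohort size N; "rare" means AF < 5%.
2. **Classification.**  Cluster representatives are aligned to the
   human-like and chimp-like references.  A hit is *confident* iff
   identity > 95% and query coverage > 90% (strict inequalities); a
   cluster is *NS* iff no human-reference hit has identity > 80% and
   coverage > 50%.  A hit failing either criterion is not a
   significant match and does not block NS status.
3. **Repeat enrichment.**  Per-class composition is base-weighted:
   percent of pooled masked bases over pooled sequence length, classes
   LINE, SINE, LTR, DNA, Simple_repeat, Satellite, RNA,
   Low_complexity, Other and the implicit Unmasked complement.  Two
   sets A, B (|A| ≥ 2|B|, else swapped) are compared per class by
   Diff = |A% − B%|; the null re-draws R ⊂ A without replacement with
   |R| = |B| and scores |A% − R%| against the *full* A, exactly as the
   observed statistic; p = fraction of 10,000 subsets with a strictly
   larger difference.  Ties do not count, making the test slightly
   anti-conservative at coarse resolution; an add-one correction
   ((k+1)/(n+1)) is available behind a flag, off by default.  The
   reference genome enters as 500,000 random intervals sampled
   uniformly (chromosome weighted by length) with sizes drawn from the
   empirical cluster-size distribution.
4. **Positioning.**  Per-individual breakpoint calls are merged with
   one-dimensional DBSCAN (eps = 150 bp, ≥ 3 *other* neighbors to be
   core) run per (chromosome, NS) so only same-type insertions merge;
   border points attach to the first core reached scanning left to
   right.  Events supported by < 5 distinct individuals are discarded,
   calls whose NS matches the human reference are dropped, and any two
   surviving events of different NS whose spans come within eps are
   both removed as hybrid-insertion artifacts (the hybrid definition is
   the package's operationalisation of "multiple NS at a single genomic
   position"; no detection rule is prescribed elsewhere).
5. **Feature enrichment.**  For each feature track, 10,000 iterations
   of n random size-1,000 regions (n = the observed event count) give a
   pooled null overlap fraction; an exact two-sided binomial test
   compares the observed fraction of events overlapping the track
   against it.  Two-sided was chosen because the direction (enrichment
   vs depletion) is part of the question; no multiple-testing
   correction is applied by default, matching per-feature reporting.
6. **UR mapping.**  Read counting follows the samtools flag logic:
   records with the secondary (0x100) or supplementary (0x800) bit are
   excluded from totals and mapped counts, so each read counts once
   through its primary record.  Depletion curves report the fraction of
   mapped reads whose cluster has AF ≥ t for t ∈ {0.005, 0.01, 0.025,
   0.05, 0.075, 0.10} (boundary inclusive, denominator fixed at the
   total mapped count).  Populations are compared by one-way ANOVA with
   Tukey HSD; two catalogs by a two-sided Mann–Whitney U (exact for
   combined n ≤ 20 without ties, normal approximation with tie
   correction otherwise).
7. **Ancestral deletions.**  PASS, symbolic-`<DEL>` records are merged
   across individuals by reciprocal overlap ≥ 0.7 (single-linkage
   components; representative = longest member, ties leftmost; an
   individual with several linked calls keeps its most-deleted
   genotype).  Merged deletions overlapping no NS interval, or whose
   region lifts over to the human reference (status ≠ "deleted_in_new"),
   are excluded.  The chimpanzee reference allele (CRA) carrier count is
   N minus the number of hom-deletion individuals: het, hom-ref,
   missing, and uncalled individuals all carry ≥ 1 CRA copy.  Counting
   missing genotypes as carriers is a deliberate choice (absence of a
   deletion call is evidence for the allele's presence); an
   allele-frequency estimate (2N − 2·hom − het)/2N is reported
   alongside, clearly labelled as a different quantity.

## The synthetic cohort

The generator plants everything the pipeline is supposed to find, so
each stage is testable against truth without external data.  Defaults
(all `SimConfig` knobs):

| knob | default | meaning |
|---|---|---|
| `n_individuals` | 100 | cohort size N |
| `ref_length` / `n_chromosomes` | 2 Mb / 2 | human-like reference |
| `n_ns` | 300 | planted NS catalog |
| AF spectrum | 90% AF ~ U(1/N, 0.05), 10% ~ U(0.05, 0.5) | skewed, most NS rare |
| `ns_length_range` | 301–22,701 bp (log-uniform) | NS sizes |
| `repeat_mix` | Simple_repeat .28, Satellite .15, LINE .10, SINE .03, Unmasked .44 | per-NS Dirichlet around this mix |
| `min_unmasked` | 0.15 | every NS keeps unique sequence |
| `mutation_rate` | 0.005 | assembly-error substitutions per carried copy |
| `fragmentation_prob` | 0.1 | carried contig emitted as two ≥ 301 bp pieces |
| `n_decoys_per_individual` | 6 | human-reference slices (mappable contigs) |
| `contaminant_len_range` | 22.7–60 kb | contaminant contigs, non-primate hits |
| `ancestral_fraction` / `positioned_fraction` | 0.10 / 0.30 | NS inserted into the chimp-like reference / NS with an insertion site |
| `breakpoint_jitter_sd` | 30 bp | breakpoint noise around the true site |
| `deletion_pad_max` | 2,000 bp | per-side padding of deletion calls |
| `ur_mapped_fraction` | 0.074 | expected UR mapping rate |

Design choices worth stating:

* **One seed, named substreams.**  Each emission (references, catalog,
  individuals, calls, deletions, reads, hits) draws from its own child
  stream of the global seed, so stages regenerate independently and a
  fixed seed gives byte-identical files.
* **Repeat composition is recorded, not re-detected.**  NS are built
  from class-pure blocks and the block table is the annotation; running
  a repeat masker is out of scope.  Consequently NS repeat blocks are
  *sequence-private*: 20% diverged from the library consensus, with
  simple-repeat motifs ≥ 4 bp drawn per NS.  Novel satellite or LINE
  arrays that aligned at > 80% identity to planted reference copies
  would truthfully stop being NS under the classification rule; private
  blocks keep the planted truth table and the rule consistent.
* **Decoy load.**  Six human-reference slices per individual put the NS
  share of kept clusters near 35–40%, the regime reported for real
  unmappable-contig sets.
* **Diploidy** only matters for deletion genotypes.  Cluster AF is a
  carrier frequency, so the per-allele frequency is p = 1 − √(1 − AF);
  carriers hold two ancestral copies with probability p/(2 − p).  This
  keeps the carrier sets and the genotype draws mutually consistent.
* **What the generator does not emulate:** read-level sequencing error,
  realistic repeat phylogenies, assembly artifacts other than uniform
  substitutions and two-way fragmentation, indel polymorphism, and
  population structure beyond a per-population bias in which NS a
  mapped read derives from.  Passing tests therefore demonstrate
  algorithmic correctness and statistical calibration under these
  conditions — not robustness to every artifact of real assemblies.

## Numerical choices

* **Pairwise identity/coverage** (clustering) comes from a
  minimum-edit-distance infix alignment (edlib; shorter sequence as the
  query, both strands) from which the maximum-scoring contiguous
  segment under match +1 / mismatch −1 / gap −2 is extracted; identity
  = matches/columns, coverage = aligned span over each sequence's
  length.  Two exact bounds keep the greedy pass fast without changing
  any join decision: representatives longer than len_short/(c·aL) are
  skipped (the longer sequence's coverage cannot reach aL), and the
  edit-distance search stops at ⌈len_short·((1−c)/c + (1−aS))⌉ + 2,
  the largest distance any pair passing the join rule can attain.
* **The anchor aligner** (classification) uses exact 31-mer anchors,
  grouped per target and strand into ±50 diagonal bands; within a band
  the best-supported diagonals are scored separately (tandem repeats
  anchor one band on many shifted diagonals) and the best is kept after
  ungapped extension.  Coverage is the extended chain span over the
  query length.  Anchors occurring more than 100 times in a target are
  skipped.  The aligner is ungapped by design; hits spanning genuine
  indels split into separate bands, a documented caveat checked against
  a full Smith–Waterman oracle (agreement within 2 identity points for
  queries ≤ 2 kb).
* **Strictness at thresholds** is exactly as printed: 95/90 and 80/50
  fail their criteria at the boundary; the 301 bp size filter keeps
  301; AF thresholds are boundary-inclusive (AF ≥ t).
* **Permutation subsets** are drawn without replacement via rejection
  sampling (exact, and fast when |R| ≪ |A|); the comparison is strict
  `>` as printed, with p reported together with its resolution
  1/n_permutations.
* **Degenerate inputs:** empty sequence sets, zero-trial binomial
  tests, groups with < 2 observations, unknown cluster ids and
  oversized genotype maps all raise errors; an all-constant ANOVA input
  returns F = 0, p = 1 rather than 0/0.

## Problem sizes used by tests and the acceptance script

The unit suite runs on a reduced cohort (N = 20, 30 NS, 200 kb
reference).  The acceptance tests use the study-scale defaults (N =
100, 300 NS, 2 Mb reference) for truth recovery, 200 planted contigs
for the clustering oracle, 500 points for the DBSCAN oracle, 200
deletions for the merge oracle, 1,000×1,000 intervals for the
intersection oracle, 1,000 replicates × 1,000 permutations for type-I
calibration, and 500 replicates for the p-uniformity, binomial-null and
ANOVA-null checks.  `scripts/acceptance.py` runs the full default
pipeline once, including the 500,000-interval background and 10,000
permutations/iterations.

## Known limitations

* The greedy clustering reproduces CD-HIT's documented contract, not
  its heuristics; partitions can differ from CD-HIT on borderline pairs.
* The anchor aligner underestimates coverage across large indels and
  reports no hits for queries sharing no exact 31-mer with the target.
* The permutation test fixes A's profile (R is compared against full
  A), inducing the mild dependence the printed equations imply.
* The binomial enrichment test compares point-like event spans against
  size-1,000 null regions; geometry alone therefore biases observed
  overlap slightly downward for narrow events, an inherent property of
  the procedure as specified.
* CRA carrier counts treat missing genotypes and absent calls as
  carriers, which inflates carrier frequency when calls are dropped by
  quality filters.
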