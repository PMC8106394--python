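# Methods

## The dereplication model

`kderep` treats a genome as the set of distinct words (k-mers) it
contains and clusters genomes whose word dictionaries are similar. The
procedure has three layers:

1. **Distance layer.** For genomes A and B with k-mer sets `A`, `B`:
   JI = |A∩B|/|A∪B| and IGF = |A∩B|/min(|A|,|B|); the working distance
   is 1 − similarity. Sets are presence/absence only — word
   multiplicities carry assembly-repeat signal that is irrelevant to
   identity at this granularity and would break the set algebra.
   Windows containing any non-ACGT character are skipped whole (no
   ambiguity-code expansion), the convention of standard k-mer
   counters. The IGF is preferred when one genome of a pair may be
   partial or streamlined: the union in the JI penalises size
   difference, the min() denominator does not.

2. **Ranking layer.** Representatives should be the best genomes, so
   genomes are ordered by an equal-weight sum of per-metric ranks
   (rank 1 = best, ties get the average rank, residual ties break on
   accession). Equal weights avoid privileging any one quality axis;
   the default metric set combines N rate per 100 kbp (lower better),
   largest-contig ratio (higher better), annotation certainty (higher
   better) and two external contamination indicators (lower better).
   Fractional tie ranks plus the lexicographic final tie-break make the
   order total and deterministic, which the greedy clustering requires
   to be reproducible.

3. **Clustering layer.** Greedy single linkage over the rank-ordered
   list: the best genome founds cluster 1; each later genome scans
   clusters in creation order and joins the first one within the
   threshold (strictly below — threshold 0 therefore yields
   singletons), else founds its own cluster. Founders, being first in
   rank order, are automatically each cluster's best member and become
   the representatives. Loose mode compares against members in join
   order (pure single linkage); strict mode compares against founders
   only, which costs fewer distance evaluations and breaks
   transitive chains through low-quality or chimeric bridge genomes.
   The member/cluster scan order is fixed (creation order, join order,
   first hit wins) purely for determinism.

Scaling comes from divide and conquer: each round sorts the surviving
genomes — taxonomically (lexicographic on the semicolon-joined lineage,
unclassified last, accession tie-break) or by seeded shuffle — slices
them into packs (default 200), clusters packs independently, and
carries the merged representatives into the next round. Pack results
are independent of pack execution order by construction, so per-pack
parallelism cannot change the answer; the serial implementation is the
reference behaviour. Membership is composed transitively across rounds
(a genome's chain of representatives ends at its final
representative), so the final map is idempotent and representative
sets are nested from round to round.

Stopping: a round cap (default 20), an optional representative-count
target, a clustering-ratio floor (default 0.1%, where the clustering
ratio is 100·(in − out)/in for a round), and an always-active fixed
point stop when a round merges nothing. The defaults exist to
guarantee termination; in practice well-structured inputs reach the
fixed point in a handful of rounds.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| k | 12 | word length, bp. 4^12 ≈ 16.8M words keeps large genomes (≤ ~7.5M distinct words) far from vocabulary saturation; k = 11 (4.2M words) saturates for big genomes, larger k trades speed for strain-level specificity. Tests and examples use k = 7–10 with proportionally smaller genomes. |
| strandedness | specific | canonical (lexicographic min of word and reverse complement) is recommended for scaffold-stage assemblies where strand is arbitrary; it halves the vocabulary (exactly, for odd k). |
| threshold | per run | the main aggressiveness knob, on the 1 − JI / 1 − IGF scale (or Mash-distance scale for that engine). Must sit between the within-group and between-group distance distributions of the input. |
| pack_size | 200 | smaller packs are faster per round but can only split, never merge, across-pack relatives: the final representative count is non-decreasing as pack size shrinks. |
| mode | loose | see above; strict yields ≥ representatives but resists bridging. |
| sketch s / seed | 1000 / 42 | bottom-sketch size and hash seed; the estimator's binomial-style error is ~sqrt(j(1−j)/s), and it is exact when both dictionaries fit in the sketch. |
| SSU identity threshold | 0.975 | species-level identity for the chimera flag (0.99 supported as the stricter modern convention). |
| size filter | 100 kbp – 15 Mbp | assemblies below are unlikely to be complete, above unlikely to be uncontaminated. |

The sketch hash is a seeded SplitMix64 finalizer over 2-bit-packed
words, vectorised with numpy; the seed is stored in every sketch so
estimates are reproducible and incompatible sketches are rejected.

## Numerical and edge-case choices

- JI of two empty sets and IGF with any empty set are errors
  (undefined), not 0.
- The Mash distance is capped at 1 when the estimated JI is 0 (the
  logarithm is undefined there).
- Nx/Lx: contigs sorted descending; Nx is the length at which the
  cumulative sum first reaches x% of the total, a tie (exactly x%)
  counting as reached; Lx is its 1-based rank. The ">1 kbp" and
  ">500 bp" size classes are strict inequalities.
- GC% excludes ambiguity characters from numerator and denominator.
- Annotation certainty = 1 − uncertain/total and completeness = 1 −
  undescribed/total over protein description lines; "uncertain" is a
  case-insensitive whole-word match against a configurable vocabulary
  (default: probable, putative, hypothetical, unknown, uncharacterized,
  predicted, possible). Both are undefined for an empty proteome, and
  genomes without proteomes are dropped when annotation metrics are
  ranked on.
- SSU chimera flagging greedily clusters SSUs (longest first) against
  cluster founders at ≥ the identity threshold; identity is global
  alignment (match +1, mismatch −1, linear gap −2) over the shorter
  sequence, so a perfect fragment scores 1.0.
- The direction of the `42.added.ali` ranking metric is treated as
  lower-better (a contamination indicator); it is configurable and this
  is an assumption, not a property of the metric.
- When no metric table is provided and no ranking spec is set, genomes
  are ordered by accession: an arbitrary but total and deterministic
  order, which preserves every clustering guarantee except
  "representatives are the best genomes".

## The synthetic generator

`kderep.synth` generates family sets with known structure: one random
root genome, per-group ancestors diverged from it at the between-group
substitution rate (default 0.30), members diverged from their ancestor
at the within-group rate (default 0.01), 10 groups × 5 members of
50 kb by default. Lineage strings encode group labels so the taxonomic
sort and the diversity report run end-to-end, and a truth table
supports purity scoring. Proteomes with exact uncertain/blank
description fractions and SSU pairs (near-identical, or diverged for
chimeras) exercise the annotation and chimera metrics; whole-genome
chimeras concatenate halves of two ancestors.

Mutation is substitution-only (uniform over the three alternative
bases), so expected k-mer overlap is analytically tractable:
relatives at divergence d share ≈ (1−d)^k of their windows. The
generator does not emulate indels, rearrangement, lateral transfer,
repeat structure or GC skew — passing recovery tests shows the engine
separates well-structured divergence classes, not that any threshold
generalises to real collections, where the within/between distance
distributions must be inspected per dataset.

A deliberate small-scale effect: at k = 7 a 50 kb genome nearly
saturates the 16 384-word vocabulary, compressing all similarities
upward (within-family JI ≈ 0.97, between ≈ 0.91). The default
benchmark threshold of 0.06 on 1 − JI sits midway in that predicted
gap; engine-level tests use k = 10, where saturation vanishes and the
gap is wide (JI ≈ 0.7 vs ≈ 0.01, threshold 0.5). This mirrors, in
miniature, why word length must be matched to genome size at full
scale.

## Problem sizes used in the checks

The verification suite runs entirely on generated data: 1000 random
set pairs for the similarity oracles, 500 random well-separated
instances (≤ 30 genomes) for the clustering-vs-connected-components
oracle, 20 taxonomic-sort and 8 random-sort replicates of the
10 × 5 family benchmark, and 1000 sketch trials at s = 1000. The
acceptance script uses the same conditions with 10 + 4 recovery
replicates.

## Known limitations

- Exact engines hold full k-mer sets in memory as Python string sets;
  at k = 12 and genome scale a run needs the sketch engine or the
  on-disk cache to stay modest.
- No average/complete linkage, no centroid update, no re-assignment:
  representatives can sit on the "outskirts" of their cluster, which
  is partly why shrinking packs inflates representative counts.
- Pure vs mixed is the only group taxonomic classification reported;
  distinguishing paraphyletic from polyphyletic mixtures would require
  a curated phylogeny.
- The pairwise SSU identity is a full O(nm) global alignment —
  appropriate for the handful of SSUs per genome, not a general-purpose
  identity clusterer.
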