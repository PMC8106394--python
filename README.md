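# kderep

k-mer based dereplication of prokaryotic genome collections.

Public genome repositories are dominated by a handful of hyper-sampled
phyla and species, which makes it hard to assemble genome sets that are
both broadly sampled and small enough for comparative genomics or
phylogenomics. `kderep` reduces a redundant collection to one
high-quality representative per cluster of similar genomes. It is aimed
at aggressive, high-taxonomic-level (phylum/class) dereplication of
thousands of assemblies, entirely alignment-free.

## Method

Each genome is summarised by the set of its distinct nucleotide
*k*-mers (default *k* = 12, optionally canonical, i.e.
strand-insensitive). Two set similarities are supported:

- **Jaccard index** — JI(A, B) = |A ∩ B| / |A ∪ B|
- **Identical genome fraction** — IGF(A, B) = |A ∩ B| / min(|A|, |B|),
  a containment-style measure robust to partial or streamlined genomes

with distance = 1 − similarity. The JI can also be estimated from
bottom-*s* MinHash sketches (seeded 64-bit hashing, *s* = 1000 by
default), optionally transformed to the Mash log-distance
d = −(1/k)·ln(2j/(1+j)).

Clustering is greedy single linkage over a rank-ordered genome list:
genomes are ordered best-to-worst by an equal-weight **sum of ranks**
over quality metrics (assembly contiguity, N rate, annotation certainty,
external contamination estimates), the best genome founds the first
cluster, and each subsequent genome joins the first cluster it is within
the distance threshold of — compared against any member (*loose* mode)
or against founders only (*strict* mode, which suppresses single-linkage
chaining through chimeric "bridge" genomes). Cluster founders are the
representatives.

To scale, each round partitions the list into packs (200 genomes by
default, sorted taxonomically or shuffled), clusters every pack
independently, and feeds the merged representatives into the next
round. Iteration stops on a round cap, a target representative count, a
clustering-ratio floor, or a fixed point. Quality metrics
(N50/L50-style assembly statistics, annotation certainty/completeness
from protein description lines, SSU rRNA identity clustering for
chimera flagging, a 100 kbp–15 Mbp size filter) drive both hard filters
and representative choice, and a diversity report summarises the output
(phyla represented, redundancy index = groups per phylum, mixed groups).

## Worked example

```bash
python examples/03_dereplicate_synthetic.py
```

```text
generated 50 genomes in 10 families
round 1: 50 genomes -> 10 representatives (clustering ratio 80.0%)
round 2: 10 genomes -> 10 representatives (clustering ratio 0.0%)
stop reason: fixed_point
final representatives: 10
groups mixing two true families: 0
diversity: 10 phyla represented, redundancy index 1.00
```

Fifty synthetic genomes from ten families (1% within-family, 30%
between-family divergence) collapse to exactly one representative per
family in one effective round; the clustering ratio is the percentage
of genomes removed in a round, and a redundancy index of 1.0 means one
group per represented phylum — no redundancy, no mixing. The other
example scripts demonstrate the distance layer
(`01_kmer_distances.py`), quality ranking with priority lists
(`02_quality_and_ranking.py`), and loose- vs strict-mode bridging
(`04_loose_vs_strict.py`).

The same workflow is available from the shell:

```bash
kderep make-fixtures --out fixtures/ --groups 10 --members 5
kderep prepare --manifest fixtures/manifest.tsv --out metrics.tsv
kderep dereplicate --manifest fixtures/manifest.tsv --metrics metrics.tsv \
    --config config.yaml --out-dir run/
kderep report --manifest fixtures/manifest.tsv \
    --membership run/membership.tsv --out report.tsv
```

Real collections are described the same way: a TSV manifest with
`accession`, `genome_path`, optional `proteome_path` / `ssu_path` /
`lineage` / `source` columns, plus any numeric columns (e.g.
`42.contam.perc`, `checkm.contamination`) ingested as external metrics.

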