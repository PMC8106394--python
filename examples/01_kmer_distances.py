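"""Compare two related genomes with exact and sketch-estimated k-mer distances.

Builds a 20 kb random genome and a 2%-diverged relative, then prints the
Jaccard index (shared word fraction of the union), the identical genome
fraction (shared fraction of the smaller dictionary), their distances
(1 - similarity), a bottom-1000 sketch estimate of the JI, and the Mash
log-distance derived from it.
"""

from kderep import (
    KmerIndex,
    build_sketch,
    estimate_jaccard,
    identical_genome_fraction,
    jaccard_index,
    mash_distance,
    similarity_to_distance,
)
from kderep.synth import mutate_sequence, random_sequence

K = 12
genome_a = random_sequence(20_000, seed=1)
genome_b = mutate_sequence(genome_a, rate=0.02, seed=2)

idx_a = KmerIndex.from_sequences("A", [genome_a], k=K)
idx_b = KmerIndex.from_sequences("B", [genome_b], k=K)

ji = jaccard_index(idx_a, idx_b)
igf = identical_genome_fraction(idx_a, idx_b)
print(f"distinct {K}-mers: A={len(idx_a)}, B={len(idx_b)}")
print(f"Jaccard index          JI  = {ji:.4f}   distance 1-JI  = {similarity_to_distance(ji):.4f}")
print(f"identical genome frac. IGF = {igf:.4f}   distance 1-IGF = {similarity_to_distance(igf):.4f}")

sk_a = build_sketch(idx_a.kmers, s=1000, seed=42, genome_id="A", k=K)
sk_b = build_sketch(idx_b.kmers, s=1000, seed=42, genome_id="B", k=K)
j_est = estimate_jaccard(sk_a, sk_b)
print(f"sketch estimate (s=1000)    = {j_est:.4f}   Mash distance = {mash_distance(j_est, K):.4f}")
print()
print("At 2% divergence roughly (1-0.02)^12 ~ 78% of 12-mer windows are")
print("unchanged; JI is lower than IGF because the union exceeds the")
print("smaller dictionary, and the sketch estimate tracks the exact JI")
print("to within a few percent.")
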