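"""k-mer sets, bottom-s sketches and the set-similarity metrics.

A genome is summarised as the set of its distinct nucleotide k-mers (its
word "dictionary").  Two genomes are compared either exactly, via the
Jaccard index  JI = |A∩B| / |A∪B|  or the identical genome fraction
IGF = |A∩B| / min(|A|,|B|)  over their k-mer sets, or approximately via
a bottom-s MinHash sketch that estimates the JI.  Distances are
1 − similarity (or the Mash log-transform of the estimated JI).

Multiplicities are deliberately ignored: the comparison is between
dictionaries of observed words, not word counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT = frozenset("ACGT")

#: 2-bit base codes used for hashing (A=0, C=1, G=2, T=3)
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement of an ACGT string."""
    if not _ACGT.issuperset(seq):
        bad = sorted(set(seq) - _ACGT)
        raise ValueError(f"non-ACGT character(s) in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_form(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Canonical k-mers make comparisons strand-insensitive, at the cost of
    halving the vocabulary (exactly, for odd k, where no k-mer is its
    own reverse complement).
    """
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def extract_kmers(seq: str, k: int, strandedness: str = "specific") -> set[str]:
    """All distinct length-k windows of ``seq`` over {A,C,G,T}.

    Windows containing any other character (N, ambiguity codes, ...) are
    skipped entirely.  In canonical mode each window is replaced by its
    canonical form before deduplication.  ``k > len(seq)`` yields the
    empty set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if strandedness not in ("specific", "canonical"):
        raise ValueError(f"unknown strandedness {strandedness!r}")
    n = len(seq) - k + 1
    if n <= 0:
        return set()
    if _ACGT.issuperset(seq):
        kmers = {seq[i : i + k] for i in range(n)}
    else:
        # positions of invalid characters rule out every window covering them
        bad = [i for i, c in enumerate(seq) if c not in _ACGT]
        kmers = set()
        prev = -1
        for b in bad + [len(seq)]:
            for i in range(prev + 1, b - k + 1):
                kmers.add(seq[i : i + k])
            prev = b
    if strandedness == "canonical":
        kmers = {canonical_form(km) for km in kmers}
    return kmers


@dataclass
class KmerIndex:
    """The distinct-k-mer set of one genome (exact engine)."""

    genome_id: str
    k: int
    strandedness: str
    kmers: set[str]

    @classmethod
    def from_sequences(
        cls, genome_id: str, sequences: Iterable[str], k: int,
        strandedness: str = "specific",
    ) -> "KmerIndex":
        kmers: set[str] = set()
        for seq in sequences:
            kmers |= extract_kmers(seq, k, strandedness)
        return cls(genome_id=genome_id, k=k, strandedness=strandedness, kmers=kmers)

    def __len__(self) -> int:
        return len(self.kmers)


def _check_compatible(a: KmerIndex, b: KmerIndex) -> None:
    if a.k != b.k or a.strandedness != b.strandedness:
        raise ValueError(
            f"incompatible k-mer indexes: (k={a.k}, {a.strandedness}) vs "
            f"(k={b.k}, {b.strandedness})"
        )


def jaccard_index(a: KmerIndex | set, b: KmerIndex | set) -> float:
    """|A∩B| / |A∪B| over two k-mer sets; undefined when both are empty."""
    sa, sb = _as_sets(a, b)
    union = len(sa | sb)
    if union == 0:
        raise ValueError("Jaccard index undefined for two empty sets")
    return len(sa & sb) / union


def identical_genome_fraction(a: KmerIndex | set, b: KmerIndex | set) -> float:
    """|A∩B| / min(|A|,|B|): containment-style similarity.

    Robust to genome pairs where one member is partial or strongly
    reduced, since the smaller dictionary sets the denominator.
    """
    sa, sb = _as_sets(a, b)
    if not sa or not sb:
        raise ValueError("identical genome fraction undefined for an empty set")
    return len(sa & sb) / min(len(sa), len(sb))


def _as_sets(a, b) -> tuple[set, set]:
    if isinstance(a, KmerIndex) and isinstance(b, KmerIndex):
        _check_compatible(a, b)
        return a.kmers, b.kmers
    return set(a), set(b)


def similarity_to_distance(sim: float) -> float:
    """Distance = 1 − similarity."""
    if not 0.0 <= sim <= 1.0:
        raise ValueError(f"similarity {sim} outside [0, 1]")
    return 1.0 - sim


# ---------------------------------------------------------------------------
# sketching


_CODE_LUT = np.zeros(256, dtype=np.uint64)
for _c, _v in _BASE_CODE.items():
    _CODE_LUT[ord(_c)] = _v


def encode_kmers(kmers: Iterable[str]) -> np.ndarray:
    """2-bit pack equal-length k-mers (k ≤ 31) into uint64 codes."""
    kmer_list = list(kmers)
    if not kmer_list:
        return np.empty(0, dtype=np.uint64)
    k = len(kmer_list[0])
    flat = np.frombuffer("".join(kmer_list).encode(), dtype=np.uint8)
    codes = _CODE_LUT[flat].reshape(len(kmer_list), k)
    weights = np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64)
    return codes @ weights


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer: a fast, well-mixed 64-bit hash (vectorised)."""
    z = x + _GOLDEN
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def hash_kmers(kmers: Iterable[str], seed: int) -> np.ndarray:
    """Seeded 64-bit hash values of a k-mer collection (distinct, unsorted)."""
    codes = encode_kmers(list(kmers))
    seed_mix = np.uint64((seed * 0x9E3779B97F4A7C15) % (1 << 64))
    return _splitmix64(codes ^ seed_mix)


@dataclass
class Sketch:
    """Bottom-s sketch: the s smallest distinct hash values of a genome.

    If the genome has fewer than s distinct k-mers the sketch holds all
    of them and downstream estimates are exact.
    """

    genome_id: str
    k: int
    s: int
    seed: int
    hashes: np.ndarray = field(repr=False)  # sorted, strictly increasing uint64

    def __post_init__(self) -> None:
        h = np.asarray(self.hashes, dtype=np.uint64)
        if h.size and not np.all(h[1:] > h[:-1]):
            raise ValueError("sketch hashes must be strictly increasing")
        if h.size > self.s:
            raise ValueError("sketch larger than its nominal size")
        self.hashes = h


def build_sketch(
    kmers: Iterable[str], s: int, seed: int, *, genome_id: str = "", k: int | None = None,
) -> Sketch:
    """Hash each k-mer and keep the s smallest distinct values, sorted."""
    if s < 1:
        raise ValueError("sketch size must be >= 1")
    kmer_list = list(kmers)
    if k is None:
        k = len(kmer_list[0]) if kmer_list else 0
    hashes = np.unique(hash_kmers(kmer_list, seed))  # unique() sorts
    return Sketch(genome_id=genome_id, k=k, s=s, seed=seed, hashes=hashes[:s])


def estimate_jaccard(sa: Sketch, sb: Sketch) -> float:
    """Merge-bottom Jaccard estimator.

    Take the s smallest values of the union of the two sketches (fewer
    if fewer exist) and return the fraction of them present in both.
    Exact whenever both genomes fit entirely in their sketches.
    """
    if (sa.k, sa.s, sa.seed) != (sb.k, sb.s, sb.seed):
        raise ValueError(
            f"incompatible sketches: (k={sa.k}, s={sa.s}, seed={sa.seed}) vs "
            f"(k={sb.k}, s={sb.s}, seed={sb.seed})"
        )
    union = np.union1d(sa.hashes, sb.hashes)[: sa.s]
    if union.size == 0:
        raise ValueError("Jaccard estimate undefined for two empty sketches")
    shared = np.intersect1d(union, sa.hashes, assume_unique=True)
    shared = np.intersect1d(shared, sb.hashes, assume_unique=True)
    return shared.size / union.size


def mash_distance(j_est: float, k: int) -> float:
    """Mash's log-scaled distance from an (estimated) Jaccard index.

    d = −(1/k)·ln(2j / (1+j)); 0 when j = 1, capped at 1 when j = 0
    (the logarithm is undefined there).
    """
    if not 0.0 <= j_est <= 1.0:
        raise ValueError(f"Jaccard estimate {j_est} outside [0, 1]")
    if j_est == 1.0:
        return 0.0
    if j_est == 0.0:
        return 1.0
    return -math.log(2.0 * j_est / (1.0 + j_est)) / k


# ---------------------------------------------------------------------------
# on-disk cache (replaces precomputed word-count indexes): one text file
# per genome, keyed by the parameters that determine its content


def _index_cache_path(cache_dir: Path, genome_id: str, k: int, strandedness: str) -> Path:
    return cache_dir / f"{genome_id}.k{k}.{strandedness}.kmers.txt"


def _sketch_cache_path(cache_dir: Path, genome_id: str, k: int, strandedness: str,
                       s: int, seed: int) -> Path:
    return cache_dir / f"{genome_id}.k{k}.{strandedness}.s{s}.seed{seed}.sketch.txt"


def save_index(index: KmerIndex, cache_dir: str | Path) -> Path:
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = _index_cache_path(cache_dir, index.genome_id, index.k, index.strandedness)
    path.write_text("\n".join(sorted(index.kmers)) + "\n")
    return path

def load_index(cache_dir: str | Path, genome_id: str, k: int,
               strandedness: str = "specific") -> KmerIndex | None:
    path = _index_cache_path(Path(cache_dir), genome_id, k, strandedness)
    if not path.exists():
        return None
    kmers = {line for line in path.read_text().splitlines() if line}
    return KmerIndex(genome_id=genome_id, k=k, strandedness=strandedness, kmers=kmers)


def save_sketch(sketch: Sketch, cache_dir: str | Path, strandedness: str = "specific") -> Path:
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = _sketch_cache_path(cache_dir, sketch.genome_id, sketch.k, strandedness,
                              sketch.s, sketch.seed)
    path.write_text("\n".join(str(int(h)) for h in sketch.hashes) + "\n")
    return path

def load_sketch(cache_dir: str | Path, genome_id: str, k: int, s: int, seed: int,
                strandedness: str = "specific") -> Sketch | None:
    path = _sketch_cache_path(Path(cache_dir), genome_id, k, strandedness, s, seed)
    if not path.exists():
        return None
    hashes = np.array(
        [int(line) for line in path.read_text().splitlines() if line], dtype=np.uint64
    )
    return Sketch(genome_id=genome_id, k=k, s=s, seed=seed, hashes=hashes)
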