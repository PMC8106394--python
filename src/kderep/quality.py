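"""Per-genome quality metrics: assembly statistics, annotation richness,
SSU-based chimera flagging and ingestion of external contamination values.

These metrics feed two places downstream: hard filters (assembly size
range, SSU presence, chimera exclusion) and the sum-of-ranks ordering
used to pick cluster representatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import re

from Bio import Align

from .io import GenomeRecord, SequenceRecord

#: size range for a plausibly complete, uncontaminated prokaryotic genome
DEFAULT_MIN_GENOME_BP = 100_000
DEFAULT_MAX_GENOME_BP = 15_000_000

#: description words that mark a protein annotation as uncertain
DEFAULT_UNCERTAINTY_VOCABULARY = (
    "probable",
    "putative",
    "hypothetical",
    "unknown",
    "uncharacterized",
    "predicted",
    "possible",
)

#: SSU rRNA identity thresholds commonly used for species delineation
SSU_IDENTITY_CLASSIC = 0.975
SSU_IDENTITY_STRICT = 0.99

#: names under which external tools' contamination/completeness values
#: are expected in the manifest
KNOWN_EXTERNAL_METRICS = (
    "42.contam.perc",
    "42.added.ali",
    "checkm.completeness",
    "checkm.contamination",
)


@dataclass(frozen=True)
class AssemblyMetrics:
    n_seqs: int
    n_seqs_gt1kb: int
    total_len: int
    total_len_gt1kb: int
    total_len_gt500bp: int
    largest_contig: int
    gc_percent: float
    n50: int
    n75: int
    l50: int
    l75: int
    n_per_100kbp: float
    largest_contig_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {
            "quast.n.seqs": self.n_seqs,
            "quast.n.seqs.1000.bp": self.n_seqs_gt1kb,
            "quast.total.len": self.total_len,
            "quast.total.len.1000.bp": self.total_len_gt1kb,
            "quast.total.len.500.bp": self.total_len_gt500bp,
            "quast.largest.contig": self.largest_contig,
            "quast.GC": self.gc_percent,
            "quast.N50": self.n50,
            "quast.N75": self.n75,
            "quast.L50": self.l50,
            "quast.L75": self.l75,
            "quast.N.per.100.kbp": self.n_per_100kbp,
            "quast.largest.contig.ratio": self.largest_contig_ratio,
        }


@dataclass(frozen=True)
class AnnotationMetrics:
    n_proteins: int
    n_uncertain: int
    n_unannotated: int

    @property
    def certainty(self) -> float:
        """1 − (uncertain proteins / total proteins)."""
        return 1.0 - self.n_uncertain / self.n_proteins

    @property
    def completeness(self) -> float:
        """1 − (proteins without any description / total proteins)."""
        return 1.0 - self.n_unannotated / self.n_proteins

    def as_dict(self) -> dict[str, float]:
        return {"annot.certainty": self.certainty,
                "annot.completeness": self.completeness}


@dataclass(frozen=True)
class ChimeraAssessment:
    n_ssu: int
    n_clusters: int
    identity_threshold: float

    @property
    def flagged(self) -> bool:
        """True when the SSUs fall into ≥ 2 species-level identity clusters."""
        return self.n_clusters >= 2


def _nx_lx(sorted_lengths: Sequence[int], total: int, x: float) -> tuple[int, int]:
    # Nx = length of the contig at which the descending cumulative length
    # first reaches x% of the total; Lx = its 1-based rank.  A cumulative
    # sum landing exactly on x% counts as reached.
    target = x * total
    cum = 0
    for rank, length in enumerate(sorted_lengths, start=1):
        cum += length
        if cum >= target:
            return length, rank
    return sorted_lengths[-1], len(sorted_lengths)  # unreachable for x <= 1


def compute_assembly_metrics(contigs: Sequence[SequenceRecord]) -> AssemblyMetrics:
    """Standard assembly statistics over a contig set.

    Size-class cutoffs (">1 kbp", ">500 bp") are strict inequalities.
    GC% is computed over unambiguous bases only; the N rate is N count
    per 100 kbp of total assembly length.
    """
    if not contigs:
        raise ValueError("cannot compute assembly metrics for an empty contig list")
    lengths = sorted((len(c) for c in contigs), reverse=True)
    total = sum(lengths)
    gt1kb = [x for x in lengths if x > 1000]
    gt500 = [x for x in lengths if x > 500]
    n50, l50 = _nx_lx(lengths, total, 0.50)
    n75, l75 = _nx_lx(lengths, total, 0.75)
    n_count = sum(c.seq.count("N") for c in contigs)
    gc = sum(c.seq.count("G") + c.seq.count("C") for c in contigs)
    at = sum(c.seq.count("A") + c.seq.count("T") for c in contigs)
    unambiguous = gc + at
    total_gt1kb = sum(gt1kb)
    largest = lengths[0]
    return AssemblyMetrics(
        n_seqs=len(lengths),
        n_seqs_gt1kb=len(gt1kb),
        total_len=total,
        total_len_gt1kb=total_gt1kb,
        total_len_gt500bp=sum(gt500),
        largest_contig=largest,
        gc_percent=100.0 * gc / unambiguous if unambiguous else float("nan"),
        n50=n50,
        n75=n75,
        l50=l50,
        l75=l75,
        n_per_100kbp=100_000.0 * n_count / total,
        largest_contig_ratio=largest / total_gt1kb if total_gt1kb else float("nan"),
    )


def size_range_filter(
    total_len: int,
    min_bp: int = DEFAULT_MIN_GENOME_BP,
    max_bp: int = DEFAULT_MAX_GENOME_BP,
) -> bool:
    """True iff the assembly length is plausible for a complete genome:
    not too small to be complete, not too large to be uncontaminated."""
    return min_bp <= total_len <= max_bp


def annotation_metrics(
    descriptions: Sequence[str],
    uncertainty_vocabulary: Iterable[str] = DEFAULT_UNCERTAINTY_VOCABULARY,
) -> AnnotationMetrics:
    """Count uncertain and blank protein descriptions.

    A protein is *uncertain* when its description contains any
    vocabulary word as a case-insensitive whole word; *unannotated* when
    the description is empty or whitespace.  An empty proteome is an
    error: both metrics are undefined without proteins, and genomes
    lacking predicted proteomes are discarded upstream when annotation
    metrics participate in the ranking.
    """
    if not descriptions:
        raise ValueError("annotation metrics undefined for an empty proteome")
    vocab = [w.lower() for w in uncertainty_vocabulary]
    pattern = re.compile(
        r"\b(?:" + "|".join(re.escape(w) for w in vocab) + r")\b", re.IGNORECASE
    )
    n_uncertain = sum(1 for d in descriptions if pattern.search(d or ""))
    n_unannotated = sum(1 for d in descriptions if not (d or "").strip())
    return AnnotationMetrics(
        n_proteins=len(descriptions),
        n_uncertain=n_uncertain,
        n_unannotated=n_unannotated,
    )


def annotation_certainty(
    descriptions: Sequence[str],
    uncertainty_vocabulary: Iterable[str] = DEFAULT_UNCERTAINTY_VOCABULARY,
) -> float:
    return annotation_metrics(descriptions, uncertainty_vocabulary).certainty


def annotation_completeness(descriptions: Sequence[str]) -> float:
    return annotation_metrics(descriptions).completeness


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -2


def pairwise_identity(seq1: str, seq2: str) -> float:
    """Global-alignment identity over the shorter sequence.

    Alignment scores: match +1, mismatch −1, linear gap −2.  Identity is
    the number of identical aligned positions divided by the length of
    the shorter input (the convention used by greedy identity-clustering
    tools), so a perfect substring scores 1.0.
    """
    if not seq1 or not seq2:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner.align(seq1, seq2)[0]
    matches = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        sub1 = seq1[s1:e1]
        sub2 = seq2[s2:e2]
        matches += sum(a == b for a, b in zip(sub1, sub2))
    return matches / min(len(seq1), len(seq2))


def flag_chimeric_genome(
    ssu_records: Sequence[SequenceRecord],
    identity_threshold: float = SSU_IDENTITY_CLASSIC,
) -> ChimeraAssessment:
    """Flag genomes whose SSU (16S) rRNAs belong to different species.

    SSUs are greedily clustered (longest first): each sequence joins the
    first cluster whose founder it matches at ≥ ``identity_threshold``,
    else founds a new cluster.  Two or more clusters mean the genome
    carries SSUs from distinct species — likely chimeric or at least
    contaminated.  Zero or one SSU can never be flagged.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError(f"identity threshold {identity_threshold} outside (0, 1]")
    ordered = sorted(ssu_records, key=lambda r: (-len(r.seq), r.id))
    founders: list[SequenceRecord] = []
    for rec in ordered:
        for rep in founders:
            if pairwise_identity(rec.seq, rep.seq) >= identity_threshold:
                break
        else:
            founders.append(rec)
    return ChimeraAssessment(
        n_ssu=len(ssu_records),
        n_clusters=len(founders),
        identity_threshold=identity_threshold,
    )


def ingest_external_metrics(
    record: GenomeRecord, required: Sequence[str] = ()
) -> tuple[dict[str, float], bool]:
    """Pass through externally computed metrics from the manifest.

    Returns (metric map, eligible) where ``eligible`` is False when any
    ``required`` metric is absent — such genomes cannot take part in
    rankings that use the missing metric.  Non-numeric values were
    already rejected at manifest-parsing time.
    """
    metrics = dict(record.external_metrics)
    eligible = all(name in metrics for name in required)
    return metrics, eligible


def metrics_row(
    record: GenomeRecord,
    contigs: Sequence[SequenceRecord] | None = None,
    protein_descriptions: Sequence[str] | None = None,
    ssu_records: Sequence[SequenceRecord] | None = None,
    *,
    uncertainty_vocabulary: Iterable[str] = DEFAULT_UNCERTAINTY_VOCABULARY,
    ssu_identity_threshold: float = SSU_IDENTITY_CLASSIC,
) -> dict[str, float]:
    """Assemble the full per-genome metric row (one genome, all metrics)."""
    row: dict[str, float] = {}
    if contigs is not None:
        row.update(compute_assembly_metrics(contigs).as_dict())
    if protein_descriptions is not None and len(protein_descriptions) > 0:
        row.update(annotation_metrics(protein_descriptions, uncertainty_vocabulary).as_dict())
    if ssu_records is not None:
        assessment = flag_chimeric_genome(ssu_records, ssu_identity_threshold)
        row["ssu.count"] = assessment.n_ssu
        row["ssu.n.clusters"] = assessment.n_clusters
        row["ssu.flagged"] = float(assessment.flagged)
    row.update(record.external_metrics)
    return row
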