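"""Synthetic genome families with known group structure.

The generator emulates the hierarchical relatedness the dereplicator is
built to exploit: a random root genome is diverged into per-group
ancestors at a high substitution rate (between-group divergence), and
each group's members are derived from their ancestor at a low rate
(within-group divergence).  Lineage strings encode the group labels so
the taxonomic sort and the diversity report can be tested end-to-end,
and a truth table records every genome's group for recovery scoring.

Substitutions only — no indels, rearrangements or lateral transfer — so
the expected k-mer overlap between relatives stays analytically
tractable.  Optional "chimeras" concatenate halves of two groups'
ancestors, caricaturing the bridge genomes that chain clusters together
under single linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenomeRecord, SequenceRecord, write_fasta, write_manifest

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic family set.

    Defaults describe ten well-separated groups of five members each:
    50 kb genomes, 1% within-group and 30% between-group substitution —
    divergences at which within-group k-mer similarity cleanly exceeds
    between-group similarity for k around 7.
    """

    n_groups: int = 10
    members_per_group: int = 5
    genome_length: int = 50_000
    within_group_sub_rate: float = 0.01
    between_group_sub_rate: float = 0.30
    seed: int = 0
    chimera_count: int = 0
    n_contigs: int = 1
    f_uncertain: float = 0.0
    f_blank: float = 0.0
    ssu_length: int = 1500
    ssu_divergence: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.within_group_sub_rate < self.between_group_sub_rate <= 1.0:
            raise ValueError("need 0 <= within-group rate < between-group rate <= 1")
        if self.chimera_count > self.n_groups:
            raise ValueError("at most one chimera per group pair start")


@dataclass
class TruthTable:
    """Ground truth: accession → group label, with chimeras flagged."""

    group_of: dict[str, str]
    chimeras: set[str] = field(default_factory=set)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession": list(self.group_of),
                "group": [self.group_of[a] for a in self.group_of],
                "chimera": [int(a in self.chimeras) for a in self.group_of],
            }
        )

    def write(self, path: str | Path) -> None:
        self.as_frame().to_csv(path, sep="\t", index=False)


def _rng(seed: int, *salts: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(s) for s in salts])


def random_sequence(length: int, seed: int) -> str:
    rng = _rng(seed)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def mutate_sequence(seq: str, rate: float, seed: int) -> str:
    """Substitute each position independently with probability ``rate``.

    A substituted base is drawn uniformly from the three alternatives,
    so rate 1 changes every position.  Length is preserved; output is a
    pure function of (seq, rate, seed).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"substitution rate {rate} outside [0, 1]")
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if np.any(codes == 255):
        raise ValueError("mutate_sequence requires a pure-ACGT sequence")
    rng = _rng(seed)
    hit = rng.random(codes.size) < rate
    shift = rng.integers(1, 4, size=codes.size).astype(np.uint8)
    mutated = np.where(hit, (codes + shift) % 4, codes)
    return _BASES[mutated].tobytes().decode()


def _accession(group: int, member: int) -> str:
    return f"SYN{group:02d}M{member:02d}"


def generate_family_set(
    spec: SynthSpec, out_dir: str | Path
) -> tuple[list[GenomeRecord], TruthTable]:
    """Generate genomes, a manifest and a truth table under ``out_dir``.

    Group ancestors diverge from a common root at the between-group
    rate; members diverge from their ancestor at the within-group rate.
    Lineages read ``Bacteria;Group<i>;Member<j>`` so rank index 1 is the
    group (phylum-like) label.  Chimeras (if requested) splice the first
    half of group i's ancestor to the second half of group i+1's, carry
    group i's lineage, and are flagged in the truth table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = random_sequence(spec.genome_length, spec.seed)
    ancestors = [
        mutate_sequence(root, spec.between_group_sub_rate, _derived_seed(spec.seed, 1, g))
        for g in range(spec.n_groups)
    ]

    records: list[GenomeRecord] = []
    group_of: dict[str, str] = {}
    chimeras: set[str] = set()
    for g, ancestor in enumerate(ancestors):
        for m in range(spec.members_per_group):
            acc = _accession(g, m)
            seq = mutate_sequence(
                ancestor, spec.within_group_sub_rate, _derived_seed(spec.seed, 2, g, m)
            )
            records.append(
                _write_genome(out_dir, acc, seq, spec, group=g, member=m)
            )
            group_of[acc] = f"Group{g:02d}"

    half = spec.genome_length // 2
    for c in range(spec.chimera_count):
        g1, g2 = c % spec.n_groups, (c + 1) % spec.n_groups
        acc = f"SYNCHI{c:02d}"
        seq = ancestors[g1][:half] + ancestors[g2][half:]
        records.append(
            _write_genome(out_dir, acc, seq, spec, group=g1, member=-1, chimeric=True)
        )
        group_of[acc] = f"Group{g1:02d}"
        chimeras.add(acc)

    truth = TruthTable(group_of=group_of, chimeras=chimeras)
    write_manifest(records, out_dir / "manifest.tsv")
    truth.write(out_dir / "truth.tsv")
    return records, truth


def _derived_seed(seed: int, *salts: int) -> int:
    # stable child seed below 2^31 (numpy SeedSequence-style spawning is
    # avoided so seeds remain human-readable in file names and logs)
    x = seed & 0x7FFFFFFF
    for s in salts:
        x = (x * 1_000_003 + s + 1) % (1 << 31)
    return x


def _write_genome(
    out_dir: Path,
    accession: str,
    seq: str,
    spec: SynthSpec,
    *,
    group: int,
    member: int,
    chimeric: bool = False,
) -> GenomeRecord:
    contigs = _split_contigs(accession, seq, spec.n_contigs)
    genome_path = out_dir / f"{accession}.fna"
    write_fasta(contigs, genome_path)

    proteome_path = None
    if spec.f_uncertain or spec.f_blank:
        proteome = generate_proteome(
            100, spec.f_uncertain, spec.f_blank, _derived_seed(spec.seed, 3, group, member)
        )
        proteome_path = out_dir / f"{accession}.faa"
        write_fasta(proteome, proteome_path)

    ssu = generate_ssu_set(
        group_seq_seed=_derived_seed(spec.seed, 4, group),
        length=spec.ssu_length,
        divergence=spec.ssu_divergence,
        chimeric=chimeric,
        seed=_derived_seed(spec.seed, 5, group, member),
    )
    ssu_path = out_dir / f"{accession}.ssu.fna"
    write_fasta(ssu, ssu_path)

    lineage = ["Bacteria", f"Group{group:02d}", f"Member{member:02d}" if member >= 0 else "Chimera"]
    return GenomeRecord(
        accession=accession,
        genome_path=genome_path,
        proteome_path=proteome_path,
        ssu_path=ssu_path,
        lineage=lineage,
        source="custom",
    )


def _split_contigs(accession: str, seq: str, n_contigs: int) -> list[SequenceRecord]:
    if n_contigs <= 1:
        return [SequenceRecord(id=f"{accession}_c1", seq=seq)]
    size = len(seq) // n_contigs
    pieces = [seq[i * size : (i + 1) * size] for i in range(n_contigs - 1)]
    pieces.append(seq[(n_contigs - 1) * size :])
    return [
        SequenceRecord(id=f"{accession}_c{i + 1}", seq=p) for i, p in enumerate(pieces) if p
    ]


_INFORMATIVE = (
    "DNA polymerase III subunit alpha",
    "50S ribosomal protein L2",
    "elongation factor Tu",
    "ATP synthase subunit beta",
    "chaperonin GroEL",
)


def generate_proteome(
    n_proteins: int, f_uncertain: float, f_blank: float, seed: int
) -> list[SequenceRecord]:
    """Protein records with controlled description composition.

    Exactly ``round(n·f_uncertain)`` descriptions read "hypothetical
    protein", exactly ``round(n·f_blank)`` are blank, the rest are
    informative — so annotation certainty is 1 − round(n·f_u)/n and
    completeness 1 − round(n·f_b)/n by construction.
    """
    if f_uncertain + f_blank > 1.0:
        raise ValueError("uncertain + blank fractions exceed 1")
    n_unc = round(n_proteins * f_uncertain)
    n_blank = round(n_proteins * f_blank)
    rng = _rng(seed)
    aa = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
    records = []
    for i in range(n_proteins):
        if i < n_unc:
            desc = "hypothetical protein"
        elif i < n_unc + n_blank:
            desc = ""
        else:
            desc = _INFORMATIVE[i % len(_INFORMATIVE)]
        seq = aa[rng.integers(0, aa.size, size=120)].tobytes().decode()
        records.append(SequenceRecord(id=f"prot{i:04d}", seq=seq, description=desc))
    return records


def generate_ssu_set(
    *,
    group_seq_seed: int,
    length: int = 1500,
    divergence: float = 0.10,
    chimeric: bool = False,
    seed: int = 0,
) -> list[SequenceRecord]:
    """One or two SSU rRNA sequences for a genome.

    Non-chimeric genomes get two near-identical copies (a handful of
    substitutions, identity > 0.99).  Chimeric genomes get one native
    copy and one foreign copy at ≈ (1 − divergence) identity, which the
    species-level identity clustering should split into two clusters.
    """
    base = random_sequence(length, group_seq_seed)
    first = SequenceRecord(id="ssu1", seq=base, description="16S ribosomal RNA")
    if chimeric:
        second_seq = mutate_sequence(base, divergence, _derived_seed(seed, 7))
    else:
        # a couple of within-operon substitutions, far above any species threshold
        second_seq = mutate_sequence(base, 2.0 / length, _derived_seed(seed, 8))
    second = SequenceRecord(id="ssu2", seq=second_seq, description="16S ribosomal RNA")
    return [first, second]
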