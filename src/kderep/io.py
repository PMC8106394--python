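"""Reading and writing the flat-file formats the pipeline consumes.

Genome collections are described by a tab-separated manifest (one row per
assembly) pointing at plain FASTA files, optionally accompanied by
predicted proteomes and SSU rRNA sequences.  Accession lists (include /
exclude / priority) are plain text, one accession per line.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: manifest columns that are not free-form numeric metrics
_RESERVED_COLUMNS = {
    "accession",
    "genome_path",
    "proteome_path",
    "ssu_path",
    "lineage",
    "source",
}

_VALID_SOURCES = {"refseq", "genbank", "custom"}


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry: id, free-text description and upper-cased sequence."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomeRecord:
    """One genome assembly as described by a manifest row.

    ``lineage`` is an ordered list of taxon names, highest rank first
    (empty list = unclassified).  ``external_metrics`` carries numeric
    per-genome values ingested from the manifest (e.g. contamination
    estimates computed by outside tools).
    """

    accession: str
    genome_path: Path
    proteome_path: Path | None = None
    ssu_path: Path | None = None
    lineage: list[str] = field(default_factory=list)
    source: str = "custom"
    external_metrics: dict[str, float] = field(default_factory=dict)

    def lineage_string(self) -> str:
        return ";".join(self.lineage)

    def taxon_at(self, rank_index: int) -> str | None:
        """Taxon name at ``rank_index`` (0 = domain, 1 ≈ phylum), or None."""
        if rank_index < len(self.lineage):
            name = self.lineage[rank_index].strip()
            return name or None
        return None


@dataclass(frozen=True)
class AccessionList:
    """A curated accession list with a purpose tag."""

    purpose: str  # include | exclude | priority
    accessions: frozenset[str]

    def __post_init__(self) -> None:
        if self.purpose not in {"include", "exclude", "priority"}:
            raise ValueError(f"unknown list purpose: {self.purpose!r}")
        if any(not a for a in self.accessions):
            raise ValueError("accession lists may not contain empty strings")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are upper-cased and U is mapped to T.  A record with an
    empty sequence is an error (it would silently poison every
    downstream metric).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty sequence for record {rec.id!r} in {path}")
        records.append(SequenceRecord(id=rec.id, seq=seq, description=_description_of(rec)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def _description_of(rec: _BioSeqRecord) -> str:
    # Biopython's .description includes the id token; strip it off.
    desc = rec.description
    if desc == rec.id:
        return ""
    if desc.startswith(rec.id):
        return desc[len(rec.id) :].strip()
    return desc.strip()


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA (fixed line width; round-trips read_fasta)."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        for rec in bio:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(str(rec.seq[i : i + width]) + "\n")


def read_manifest(path: str | Path) -> list[GenomeRecord]:
    """Parse a manifest TSV into :class:`GenomeRecord` objects.

    Required columns: ``accession``, ``genome_path``.  Optional:
    ``proteome_path``, ``ssu_path``, ``lineage`` (semicolon-joined,
    highest rank first), ``source``.  Any other column whose value is
    numeric is stored in ``external_metrics`` under the column name.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("accession", "genome_path"):
        if col not in df.columns:
            raise ValueError(f"manifest {path} is missing required column {col!r}")
    dup = df["accession"][df["accession"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate accession(s) in manifest: {sorted(set(dup))}")

    metric_cols = [c for c in df.columns if c not in _RESERVED_COLUMNS]
    base = path.parent
    records: list[GenomeRecord] = []
    for row in df.itertuples(index=False, name=None):
        # plain tuples: metric names like "42.contam.perc" are not valid
        # namedtuple fields
        d = dict(zip(df.columns, row))
        lineage_raw = d.get("lineage")
        lineage = (
            [t.strip() for t in str(lineage_raw).split(";")]
            if isinstance(lineage_raw, str) and lineage_raw.strip()
            else []
        )
        source = d.get("source")
        source = source.strip().lower() if isinstance(source, str) and source.strip() else "custom"
        if source not in _VALID_SOURCES:
            raise ValueError(f"unknown source {source!r} for accession {d['accession']}")
        metrics: dict[str, float] = {}
        for col in metric_cols:
            val = d.get(col)
            if val is None or (isinstance(val, float) and math.isnan(val)):
                continue
            sval = str(val).strip()
            if not sval:
                continue
            try:
                metrics[col] = float(sval)
            except ValueError as exc:
                raise ValueError(
                    f"non-numeric value {sval!r} in metric column {col!r} "
                    f"for accession {d['accession']}"
                ) from exc
        records.append(
            GenomeRecord(
                accession=str(d["accession"]),
                genome_path=_resolve(base, d["genome_path"]),
                proteome_path=_resolve_optional(base, d.get("proteome_path")),
                ssu_path=_resolve_optional(base, d.get("ssu_path")),
                lineage=lineage,
                source=source,
                external_metrics=metrics,
            )
        )
    return records


def _resolve(base: Path, value: object) -> Path:
    p = Path(str(value))
    return p if p.is_absolute() else base / p


def _resolve_optional(base: Path, value: object) -> Path | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if not s or s.lower() == "nan":
        return None
    return _resolve(base, s)


def write_manifest(records: Sequence[GenomeRecord], path: str | Path) -> None:
    """Write records back to manifest TSV form (paths as given)."""
    metric_names = sorted({m for r in records for m in r.external_metrics})
    rows = []
    for r in records:
        row: dict[str, object] = {
            "accession": r.accession,
            "genome_path": str(r.genome_path),
            "proteome_path": str(r.proteome_path) if r.proteome_path else "",
            "ssu_path": str(r.ssu_path) if r.ssu_path else "",
            "lineage": r.lineage_string(),
            "source": r.source,
        }
        for m in metric_names:
            row[m] = r.external_metrics.get(m, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_accession_list(path: str | Path, purpose: str) -> AccessionList:
    """Read a plain-text accession list (one per line, '#' comments)."""
    accs: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            accs.add(line)
    return AccessionList(purpose=purpose, accessions=frozenset(accs))


def apply_list_filters(
    records: Sequence[GenomeRecord], lists: Sequence[AccessionList]
) -> tuple[list[GenomeRecord], set[str]]:
    """Apply include/exclude/priority lists to a record set.

    If any include list is present only its members are kept; exclusions
    are applied afterwards and win on conflict.  Returns the surviving
    records (input order preserved) and the set of surviving priority
    accessions.  Accessions in a list that match no record are ignored
    with a warning (lists are hand-curated and drift).
    """
    include: set[str] = set()
    exclude: set[str] = set()
    priority: set[str] = set()
    for lst in lists:
        target = {"include": include, "exclude": exclude, "priority": priority}[lst.purpose]
        target.update(lst.accessions)

    known = {r.accession for r in records}
    for name, accs in (("include", include), ("exclude", exclude), ("priority", priority)):
        unknown = accs - known
        if unknown:
            logger.warning("%s list names %d unknown accession(s): %s",
                           name, len(unknown), sorted(unknown)[:5])

    kept = list(records)
    if include:
        kept = [r for r in kept if r.accession in include]
    if exclude:
        kept = [r for r in kept if r.accession not in exclude]
    surviving = {r.accession for r in kept}
    return kept, priority & surviving
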