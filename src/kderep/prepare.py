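"""Per-genome preparation: compute every metric the dereplication phase
needs and assemble them into one accession-indexed table."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import GenomeRecord, read_fasta
from .quality import (
    DEFAULT_UNCERTAINTY_VOCABULARY,
    SSU_IDENTITY_CLASSIC,
    metrics_row,
)

logger = logging.getLogger(__name__)


def compute_metric_table(
    records: Sequence[GenomeRecord],
    *,
    uncertainty_vocabulary: Iterable[str] = DEFAULT_UNCERTAINTY_VOCABULARY,
    ssu_identity_threshold: float = SSU_IDENTITY_CLASSIC,
) -> pd.DataFrame:
    """One row per genome, one column per metric.

    Assembly metrics always; annotation metrics when a proteome file is
    present; SSU count / chimera flag when an SSU file is present;
    external manifest metrics passed through.  Missing inputs leave the
    corresponding cells NaN — the ranking layer decides eligibility.
    """
    rows: dict[str, dict[str, float]] = {}
    for rec in records:
        contigs = read_fasta(rec.genome_path)
        descriptions = None
        if rec.proteome_path is not None and Path(rec.proteome_path).exists():
            descriptions = [r.description for r in read_fasta(rec.proteome_path)]
        ssu = None
        if rec.ssu_path is not None and Path(rec.ssu_path).exists():
            ssu = read_fasta(rec.ssu_path)
        rows[rec.accession] = metrics_row(
            rec,
            contigs=contigs,
            protein_descriptions=descriptions,
            ssu_records=ssu,
            uncertainty_vocabulary=uncertainty_vocabulary,
            ssu_identity_threshold=ssu_identity_threshold,
        )
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "accession"
    return table


def write_metric_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def read_metric_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="accession")
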