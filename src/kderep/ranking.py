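"""Sum-of-ranks ordering of genomes from best to worst representative.

Each metric is ranked independently across all genomes (rank 1 = best
under the metric's stated direction, ties averaged), and a genome's
total score is the unweighted sum of its per-metric ranks — no metric is
favoured over another.  Lower totals come first; residual ties break on
accession so the order is fully deterministic, which the downstream
greedy clustering requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import rankdata

HIGHER_BETTER = "higher_better"
LOWER_BETTER = "lower_better"

#: the default five-metric ranking: two assembly-quality metrics, one
#: annotation-richness metric and two contamination indicators
DEFAULT_RANKING_METRICS: tuple[tuple[str, str], ...] = (
    ("quast.N.per.100.kbp", LOWER_BETTER),
    ("quast.largest.contig.ratio", HIGHER_BETTER),
    ("annot.certainty", HIGHER_BETTER),
    ("42.contam.perc", LOWER_BETTER),
    ("42.added.ali", LOWER_BETTER),
)


@dataclass(frozen=True)
class RankingSpec:
    """Ordered list of (metric name, direction) pairs, equal weights."""

    metrics: tuple[tuple[str, str], ...] = DEFAULT_RANKING_METRICS

    def __post_init__(self) -> None:
        if not self.metrics:
            raise ValueError("a ranking spec needs at least one metric")
        for name, direction in self.metrics:
            if direction not in (HIGHER_BETTER, LOWER_BETTER):
                raise ValueError(
                    f"metric {name!r}: direction must be "
                    f"{HIGHER_BETTER!r} or {LOWER_BETTER!r}, got {direction!r}"
                )

    @classmethod
    def from_strings(cls, entries: Iterable[str]) -> "RankingSpec":
        """Parse "metric:direction" entries (config-file form)."""
        metrics = []
        for entry in entries:
            name, _, direction = entry.rpartition(":")
            metrics.append((name, direction))
        return cls(metrics=tuple(metrics))

    @property
    def metric_names(self) -> list[str]:
        return [name for name, _ in self.metrics]


@dataclass
class GlobalRanking:
    """Best-to-worst ordering with scores and per-genome exclusion reasons."""

    order: list[str]
    total_scores: dict[str, float]
    per_metric_ranks: pd.DataFrame
    excluded: dict[str, str] = field(default_factory=dict)

    def position(self, accession: str) -> int:
        """0-based position in the order (best = 0)."""
        return self.order.index(accession)

    def as_frame(self) -> pd.DataFrame:
        df = self.per_metric_ranks.loc[self.order].copy()
        df["total"] = [self.total_scores[a] for a in self.order]
        df["position"] = range(1, len(self.order) + 1)
        df.index.name = "accession"
        return df


def rank_single_metric(values: Mapping[str, float], direction: str) -> dict[str, float]:
    """Rank one metric across genomes; rank 1 = best, ties averaged."""
    if direction not in (HIGHER_BETTER, LOWER_BETTER):
        raise ValueError(f"unknown direction {direction!r}")
    accessions = list(values)
    vals = [values[a] for a in accessions]
    if direction == HIGHER_BETTER:
        vals = [-v for v in vals]
    ranks = rankdata(vals, method="average")
    return dict(zip(accessions, ranks.tolist()))


def sum_of_ranks(metric_table: pd.DataFrame, spec: RankingSpec) -> GlobalRanking:
    """Equal-weight sum-of-ranks over ``spec``'s metrics.

    ``metric_table`` is indexed by accession, one column per metric.
    Genomes missing any spec metric (absent or NaN) are excluded with a
    reason; ranks are computed over the eligible genomes only.
    """
    missing_cols = [m for m in spec.metric_names if m not in metric_table.columns]
    excluded: dict[str, str] = {}
    table = metric_table
    if missing_cols:
        # every genome lacks these metrics entirely
        raise ValueError(f"metric table lacks column(s): {missing_cols}")
    sub = table[spec.metric_names]
    bad = sub.isna().any(axis=1)
    for acc in sub.index[bad]:
        gaps = [m for m in spec.metric_names if pd.isna(sub.at[acc, m])]
        excluded[str(acc)] = f"missing metric(s): {', '.join(gaps)}"
    eligible = sub[~bad]
    if eligible.empty:
        raise ValueError("no genome has values for every ranking metric")

    ranks = {}
    for name, direction in spec.metrics:
        ranks[name] = rank_single_metric(eligible[name].to_dict(), direction)
    rank_df = pd.DataFrame(ranks, index=eligible.index)
    totals = rank_df.sum(axis=1)
    order = sorted(eligible.index, key=lambda a: (totals[a], a))
    return GlobalRanking(
        order=[str(a) for a in order],
        total_scores={str(a): float(totals[a]) for a in eligible.index},
        per_metric_ranks=rank_df,
        excluded=excluded,
    )


def apply_priority(ranking: GlobalRanking, priority: Iterable[str]) -> GlobalRanking:
    """Move priority genomes to the head of the order.

    Relative order within the priority block, and among the rest, is
    preserved (stable partition).  Useful for pinning model organisms as
    representatives without sacrificing dereplication of the rest.
    """
    prio = set(priority)
    head = [a for a in ranking.order if a in prio]
    tail = [a for a in ranking.order if a not in prio]
    return GlobalRanking(
        order=head + tail,
        total_scores=ranking.total_scores,
        per_metric_ranks=ranking.per_metric_ranks,
        excluded=ranking.excluded,
    )
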