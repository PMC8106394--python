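"""Iterative divide-and-conquer dereplication driver.

Each round: sort the surviving genomes (taxonomically or at random),
slice them into packs, greedily cluster each pack independently under
the distance threshold, and keep only the cluster representatives for
the next round.  Rounds repeat until a stop criterion fires: a round
cap, a target representative count, a clustering ratio (the percentage
of genomes removed in a round) falling below a floor, or a fixed point
(no genome merged at all).

Packs are independent by construction — the result never depends on the
order packs are processed in, which is what makes per-pack execution
parallelisable without changing the answer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import kmers as _kmers
from .clustering import LOOSE, PackResult, cluster_pack
from .io import AccessionList, GenomeRecord, apply_list_filters, read_fasta
from .quality import DEFAULT_MAX_GENOME_BP, DEFAULT_MIN_GENOME_BP
from .ranking import GlobalRanking, RankingSpec, apply_priority, sum_of_ranks

logger = logging.getLogger(__name__)

EXACT_JI = "exact_ji"
EXACT_IGF = "exact_igf"
SKETCH_JI = "sketch_ji"
SKETCH_MASH = "sketch_mash"
ENGINES = (EXACT_JI, EXACT_IGF, SKETCH_JI, SKETCH_MASH)

TAXONOMIC = "taxonomic"
RANDOM = "random"


@dataclass(frozen=True)
class StopCriteria:
    """Any satisfied criterion ends the run; the fixed-point stop (a
    round that merged nothing) is always active."""

    max_rounds: int | None = 20
    max_representatives: int | None = None
    min_clustering_ratio: float | None = 0.1  # percent

    def __post_init__(self) -> None:
        if (
            self.max_rounds is None
            and self.max_representatives is None
            and self.min_clustering_ratio is None
        ):
            raise ValueError("at least one stop criterion must be set")


@dataclass(frozen=True)
class EngineConfig:
    """Everything a dereplication run depends on.

    ``threshold`` is a distance: 1 − JI or 1 − IGF for the exact
    engines and the sketch JI engine, a Mash distance for sketch_mash.
    ``ranking`` may be None, in which case genomes are ordered by
    accession (a deterministic stand-in when no metric table exists).
    """

    k: int = 12
    strandedness: str = "specific"
    engine: str = EXACT_JI
    sketch_size: int = 1000
    sketch_seed: int = 42
    threshold: float = 0.1
    pack_size: int = 200
    sort_scheme: str = TAXONOMIC
    random_seed: int = 0
    mode: str = LOOSE
    stop: StopCriteria = field(default_factory=StopCriteria)
    size_filter: bool = False
    min_genome_bp: int = DEFAULT_MIN_GENOME_BP
    max_genome_bp: int = DEFAULT_MAX_GENOME_BP
    require_ssu: bool = False
    chimera_exclude: bool = False
    ranking: RankingSpec | None = None

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.pack_size < 2:
            raise ValueError("pack size must be >= 2")
        if self.sort_scheme not in (TAXONOMIC, RANDOM):
            raise ValueError(f"unknown sort scheme {self.sort_scheme!r}")
        if self.threshold < 0:
            raise ValueError("distance threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EngineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        stop = StopCriteria(**raw.pop("stop", {}))
        ranking = raw.pop("ranking", None)
        spec = RankingSpec.from_strings(ranking) if ranking else None
        return cls(stop=stop, ranking=spec, **raw)


@dataclass(frozen=True)
class RoundStats:
    round_index: int
    genomes_in: int
    representatives_out: int
    packs: int

    @property
    def clustering_ratio(self) -> float:
        """Percent of genomes dereplicated this round, relative to the
        genomes entering the round."""
        return 100.0 * (self.genomes_in - self.representatives_out) / self.genomes_in


@dataclass
class DereplicationResult:
    final_representatives: list[str]
    membership: dict[str, str]
    rounds: list[RoundStats]
    stop_reason: str
    provenance: list[list[PackResult]] = field(default_factory=list)
    round_joined: dict[str, int] = field(default_factory=dict)
    prefilter_reasons: dict[str, str] = field(default_factory=dict)
    ranking: GlobalRanking | None = None

    def groups(self) -> dict[str, list[str]]:
        """Final representative → sorted original members (itself included)."""
        out: dict[str, list[str]] = {rep: [] for rep in self.final_representatives}
        for acc, rep in self.membership.items():
            out[rep].append(acc)
        return {rep: sorted(members) for rep, members in out.items()}


@dataclass(frozen=True)
class DiversityReport:
    rank_name: str
    n_phyla_represented: int
    n_groups: int
    n_pure: int
    n_mixed: int
    n_singletons: int

    @property
    def redundancy_index(self) -> float:
        """Groups per represented phylum; lower = less redundant."""
        return self.n_groups / self.n_phyla_represented

    def as_dict(self) -> dict[str, float]:
        return {
            "rank": self.rank_name,
            "n_phyla_represented": self.n_phyla_represented,
            "n_groups": self.n_groups,
            "redundancy_index": self.redundancy_index,
            "n_pure": self.n_pure,
            "n_mixed": self.n_mixed,
            "n_singletons": self.n_singletons,
        }


# ---------------------------------------------------------------------------
# distance backends


class DistanceBackend:
    """Builds and caches per-genome k-mer summaries, serves distances."""

    def __init__(self, records: Sequence[GenomeRecord], config: EngineConfig):
        self.config = config
        self._records = {r.accession: r for r in records}
        self._indexes: dict[str, object] = {}

    def _sequences(self, accession: str) -> list[str]:
        return [r.seq for r in read_fasta(self._records[accession].genome_path)]

    def _summary(self, accession: str):
        if accession not in self._indexes:
            cfg = self.config
            index = _kmers.KmerIndex.from_sequences(
                accession, self._sequences(accession), cfg.k, cfg.strandedness
            )
            if cfg.engine in (SKETCH_JI, SKETCH_MASH):
                self._indexes[accession] = _kmers.build_sketch(
                    index.kmers, cfg.sketch_size, cfg.sketch_seed,
                    genome_id=accession, k=cfg.k,
                )
            else:
                self._indexes[accession] = index
        return self._indexes[accession]

    def distance(self, a: str, b: str) -> float:
        cfg = self.config
        sa, sb = self._summary(a), self._summary(b)
        if cfg.engine == EXACT_JI:
            return _kmers.similarity_to_distance(_kmers.jaccard_index(sa, sb))
        if cfg.engine == EXACT_IGF:
            return _kmers.similarity_to_distance(_kmers.identical_genome_fraction(sa, sb))
        j = _kmers.estimate_jaccard(sa, sb)
        if cfg.engine == SKETCH_JI:
            return _kmers.similarity_to_distance(j)
        return _kmers.mash_distance(j, cfg.k)

    def drop_except(self, keep: set[str]) -> None:
        for acc in list(self._indexes):
            if acc not in keep:
                del self._indexes[acc]


# ---------------------------------------------------------------------------
# engine operations


def prefilter(
    records: Sequence[GenomeRecord],
    config: EngineConfig,
    metrics: pd.DataFrame | None = None,
    lists: Sequence[AccessionList] = (),
) -> tuple[list[GenomeRecord], set[str], dict[str, str]]:
    """Drop genomes failing the active hard filters.

    Returns (eligible records, priority accessions, reason per dropped
    genome).  Metric-based filters (size range, SSU presence, chimera
    flag) need the corresponding columns in ``metrics``; a genome with
    the column missing is dropped with a reason naming the gap.
    """
    kept, priority = apply_list_filters(records, lists)
    kept_accs = {r.accession for r in kept}
    reasons: dict[str, str] = {
        r.accession: "excluded by accession list"
        for r in records
        if r.accession not in kept_accs
    }

    def metric(acc: str, name: str) -> float | None:
        if metrics is None or name not in metrics.columns or acc not in metrics.index:
            return None
        val = metrics.at[acc, name]
        return None if pd.isna(val) else float(val)

    out: list[GenomeRecord] = []
    for rec in kept:
        acc = rec.accession
        if config.size_filter:
            total = metric(acc, "quast.total.len")
            if total is None:
                reasons[acc] = "size filter active but quast.total.len missing"
                continue
            if not (config.min_genome_bp <= total <= config.max_genome_bp):
                reasons[acc] = (
                    f"assembly length {int(total)} outside "
                    f"[{config.min_genome_bp}, {config.max_genome_bp}]"
                )
                continue
        if config.require_ssu:
            count = metric(acc, "ssu.count")
            if not count:
                reasons[acc] = "no SSU rRNA sequence"
                continue
        if config.chimera_exclude:
            flagged = metric(acc, "ssu.flagged")
            if flagged:
                reasons[acc] = "SSU identity clustering flags genome as chimeric"
                continue
        out.append(rec)
    for acc, why in reasons.items():
        logger.info("prefilter dropped %s: %s", acc, why)
    return out, priority & {r.accession for r in out}, reasons


def partition_into_packs(
    records: Sequence[GenomeRecord],
    pack_size: int,
    sort_scheme: str = TAXONOMIC,
    seed: int = 0,
) -> list[list[GenomeRecord]]:
    """Sort (taxonomic) or shuffle (random), then slice into packs.

    Taxonomic sort groups genomes sharing lineage prefixes into the same
    packs so relatives meet early; unclassified genomes go last, and
    ties break on accession.  Random scheme is a seeded shuffle.  The
    last pack may be smaller than ``pack_size``.
    """
    if not records:
        raise ValueError("cannot partition an empty genome list")
    if pack_size < 2:
        raise ValueError("pack size must be >= 2")
    if sort_scheme == TAXONOMIC:
        ordered = sorted(
            records,
            key=lambda r: (not r.lineage, r.lineage_string(), r.accession),
        )
    elif sort_scheme == RANDOM:
        rng = np.random.default_rng(seed)
        ordered = list(records)
        perm = rng.permutation(len(ordered))
        ordered = [ordered[i] for i in perm]
    else:
        raise ValueError(f"unknown sort scheme {sort_scheme!r}")
    return [ordered[i : i + pack_size] for i in range(0, len(ordered), pack_size)]


def _rank_order(
    pack: Sequence[GenomeRecord],
    order_index: Mapping[str, int],
    priority: set[str],
) -> list[str]:
    accs = [r.accession for r in pack]
    return sorted(accs, key=lambda a: (a not in priority, order_index[a]))


def run_round(
    records: Sequence[GenomeRecord],
    config: EngineConfig,
    distance_fn: Callable[[str, str], float],
    order_index: Mapping[str, int],
    priority: set[str] = frozenset(),
    round_index: int = 1,
) -> tuple[list[GenomeRecord], RoundStats, list[PackResult]]:
    """One divide-and-conquer round: pack, cluster, merge representatives."""
    if not records:
        raise ValueError("cannot run a round on zero genomes")
    packs = partition_into_packs(
        records,
        config.pack_size,
        config.sort_scheme,
        seed=_round_seed(config.random_seed, round_index),
    )
    by_acc = {r.accession: r for r in records}
    reps: list[GenomeRecord] = []
    pack_results: list[PackResult] = []
    for i, pack in enumerate(packs):
        ordered = _rank_order(pack, order_index, priority)
        try:
            result = cluster_pack(ordered, distance_fn, config.threshold, config.mode)
        except Exception as exc:  # pragma: no cover - defensive re-raise
            raise RuntimeError(f"pack {i} of round {round_index} failed: {exc}") from exc
        pack_results.append(result)
        reps.extend(by_acc[a] for a in result.representatives)
    stats = RoundStats(
        round_index=round_index,
        genomes_in=len(records),
        representatives_out=len(reps),
        packs=len(packs),
    )
    return reps, stats, pack_results


def _round_seed(random_seed: int, round_index: int) -> int:
    return (random_seed * 1_000_003 + round_index) % (1 << 31)


def check_stop(
    history: Sequence[RoundStats],
    n_representatives: int,
    stop: StopCriteria,
) -> tuple[bool, str]:
    """Evaluate the stop criteria after a completed round."""
    if not history:
        raise ValueError("check_stop needs at least one completed round")
    last = history[-1]
    if last.clustering_ratio == 0.0:
        return True, "fixed_point"
    if stop.max_rounds is not None and len(history) >= stop.max_rounds:
        return True, "max_rounds"
    if stop.max_representatives is not None and n_representatives <= stop.max_representatives:
        return True, "max_representatives"
    if stop.min_clustering_ratio is not None and last.clustering_ratio < stop.min_clustering_ratio:
        return True, "min_clustering_ratio"
    return False, ""


def run_dereplication(
    records: Sequence[GenomeRecord],
    config: EngineConfig,
    metrics: pd.DataFrame | None = None,
    lists: Sequence[AccessionList] = (),
    distance_fn: Callable[[str, str], float] | None = None,
) -> DereplicationResult:
    """Run the full iterative dereplication.

    ``metrics`` (accession-indexed) powers the metric filters and the
    sum-of-ranks ordering; without it, and without ``config.ranking``,
    genomes are ordered by accession.  ``distance_fn`` overrides the
    built-in k-mer backend (used for testing with synthetic matrices).
    Deterministic given the config, including all seeds.
    """
    eligible, priority, reasons = prefilter(records, config, metrics, lists)
    if not eligible:
        raise ValueError("no genome survives the prefilter")

    ranking: GlobalRanking | None = None
    if config.ranking is not None:
        if metrics is None:
            raise ValueError("a ranking spec requires a metric table")
        ranking = sum_of_ranks(metrics.loc[[r.accession for r in eligible]], config.ranking)
        ranking = apply_priority(ranking, priority)
        ranked_accs = set(ranking.order)
        dropped = [r for r in eligible if r.accession not in ranked_accs]
        for r in dropped:
            reasons[r.accession] = ranking.excluded.get(
                r.accession, "excluded from ranking"
            )
        eligible = [r for r in eligible if r.accession in ranked_accs]
        order_index = {acc: i for i, acc in enumerate(ranking.order)}
    else:
        order_index = {
            r.accession: i for i, r in enumerate(sorted(eligible, key=lambda r: r.accession))
        }

    backend = None
    if distance_fn is None:
        backend = DistanceBackend(eligible, config)
        distance_fn = backend.distance

    survivors = list(eligible)
    membership = {r.accession: r.accession for r in eligible}
    round_joined: dict[str, int] = {}
    history: list[RoundStats] = []
    provenance: list[list[PackResult]] = []
    stop_reason = "max_rounds"
    round_index = 0
    while True:
        round_index += 1
        survivors, stats, pack_results = run_round(
            survivors, config, distance_fn, order_index, priority, round_index
        )
        history.append(stats)
        provenance.append(pack_results)
        round_map: dict[str, str] = {}
        for pr in pack_results:
            round_map.update(pr.membership())
        # compose this round's merges into the transitive membership
        for acc in membership:
            membership[acc] = round_map.get(membership[acc], membership[acc])
        for acc, rep in round_map.items():
            if acc != rep and acc not in round_joined:
                round_joined[acc] = round_index
        logger.info(
            "round %d: %d genomes in, %d representatives out, clustering ratio %.2f%%",
            stats.round_index, stats.genomes_in, stats.representatives_out,
            stats.clustering_ratio,
        )
        if backend is not None:
            backend.drop_except({r.accession for r in survivors})
        stop, stop_reason = check_stop(history, len(survivors), config.stop)
        if stop:
            break

    logger.info("dereplication stopped: %s", stop_reason)
    return DereplicationResult(
        final_representatives=[r.accession for r in survivors],
        membership=membership,
        rounds=history,
        stop_reason=stop_reason,
        provenance=provenance,
        round_joined=round_joined,
        prefilter_reasons=reasons,
        ranking=ranking,
    )


def diversity_report(
    result: DereplicationResult,
    records: Sequence[GenomeRecord],
    rank_index: int = 1,
    rank_name: str = "phylum",
) -> DiversityReport:
    """Diversity / redundancy / mixity of the final representative set.

    Groups are the final clusters over the *original* genomes.  A group
    is mixed when its members span at least two distinct taxa at
    ``rank_index`` (unclassified members are ignored); the redundancy
    index is groups per phylum represented — lower means the selection
    is closer to one representative per phylum.
    """
    taxon = {r.accession: r.taxon_at(rank_index) for r in records}
    if all(t is None for t in taxon.values()):
        raise ValueError(f"no genome has a lineage entry at rank index {rank_index}")
    groups = result.groups()
    rep_phyla = {taxon.get(rep) for rep in groups if taxon.get(rep) is not None}
    n_mixed = 0
    n_singletons = 0
    for rep, members in groups.items():
        taxa = {taxon[m] for m in members if taxon.get(m) is not None}
        if len(taxa) >= 2:
            n_mixed += 1
        if len(members) == 1:
            n_singletons += 1
    n_groups = len(groups)
    return DiversityReport(
        rank_name=rank_name,
        n_phyla_represented=len(rep_phyla),
        n_groups=n_groups,
        n_pure=n_groups - n_mixed,
        n_mixed=n_mixed,
        n_singletons=n_singletons,
    )


# ---------------------------------------------------------------------------
# tabular output


def membership_frame(result: DereplicationResult) -> pd.DataFrame:
    rows = [
        {
            "accession": acc,
            "final_representative": rep,
            "round_joined": result.round_joined.get(acc, 0),
        }
        for acc, rep in sorted(result.membership.items())
    ]
    return pd.DataFrame(rows)


def rounds_frame(result: DereplicationResult) -> pd.DataFrame:
    rows = [
        {
            "round": s.round_index,
            "genomes_in": s.genomes_in,
            "representatives_out": s.representatives_out,
            "packs": s.packs,
            "clustering_ratio": s.clustering_ratio,
        }
        for s in result.rounds
    ]
    return pd.DataFrame(rows)
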