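import numpy as np
import pandas as pd
import pytest

from kderep.clustering import cluster_pack
from kderep.engine import (
    EngineConfig,
    RoundStats,
    StopCriteria,
    check_stop,
    diversity_report,
    membership_frame,
    partition_into_packs,
    prefilter,
    rounds_frame,
    run_dereplication,
    run_round,
)
from kderep.io import AccessionList, GenomeRecord
from conftest import purity


def genome(acc, lineage=(), **metrics):
    return GenomeRecord(
        accession=acc, genome_path=f"{acc}.fna", lineage=list(lineage),
        external_metrics=dict(metrics),
    )


def matrix_fn(accs, d):
    pos = {a: i for i, a in enumerate(accs)}
    return lambda a, b: float(d[pos[a], pos[b]])


def stats(round_index, n_in, n_out):
    return RoundStats(round_index=round_index, genomes_in=n_in,
                      representatives_out=n_out, packs=1)


class TestPrefilter:
    def test_size_filter_drops_small_genome(self):
        recs = [genome("g1"), genome("g2")]
        metrics = pd.DataFrame(
            {"quast.total.len": [50_000, 1_000_000]}, index=["g1", "g2"]
        )
        cfg = EngineConfig(size_filter=True)
        kept, _, reasons = prefilter(recs, cfg, metrics)
        assert [r.accession for r in kept] == ["g2"]
        assert "outside" in reasons["g1"]

    def test_require_ssu(self):
        recs = [genome("g1"), genome("g2")]
        metrics = pd.DataFrame({"ssu.count": [0, 2]}, index=["g1", "g2"])
        cfg = EngineConfig(require_ssu=True)
        kept, _, reasons = prefilter(recs, cfg, metrics)
        assert [r.accession for r in kept] == ["g2"]

    def test_chimera_exclusion(self):
        recs = [genome("g1"), genome("g2")]
        metrics = pd.DataFrame({"ssu.flagged": [1.0, 0.0]}, index=["g1", "g2"])
        cfg = EngineConfig(chimera_exclude=True)
        kept, _, _ = prefilter(recs, cfg, metrics)
        assert [r.accession for r in kept] == ["g2"]

    def test_all_filters_off_keeps_everything(self):
        recs = [genome("g1"), genome("g2")]
        kept, _, reasons = prefilter(recs, EngineConfig())
        assert kept == recs and reasons == {}

    def test_exclude_list(self):
        recs = [genome("g1"), genome("g2")]
        kept, _, reasons = prefilter(
            recs, EngineConfig(), lists=[AccessionList("exclude", frozenset({"g1"}))]
        )
        assert [r.accession for r in kept] == ["g2"]
        assert "list" in reasons["g1"]


class TestPartition:
    def test_pack_sizes(self):
        recs = [genome(f"g{i}") for i in range(5)]
        packs = partition_into_packs(recs, 2)
        assert [len(p) for p in packs] == [2, 2, 1]

    def test_taxonomic_sort_groups_relatives(self):
        recs = [
            genome("g1", ["Bacteria", "Proteobacteria"]),
            genome("g2", ["Bacteria", "Firmicutes"]),
            genome("g3", ["Bacteria", "Firmicutes"]),
        ]
        packs = partition_into_packs(recs, 2, "taxonomic")
        assert [r.accession for r in packs[0]] == ["g2", "g3"]

    def test_unclassified_sort_last(self):
        recs = [genome("g1"), genome("g2", ["Bacteria", "Firmicutes"])]
        packs = partition_into_packs(recs, 10, "taxonomic")
        assert [r.accession for r in packs[0]] == ["g2", "g1"]

    def test_random_scheme_deterministic_per_seed(self):
        recs = [genome(f"g{i}") for i in range(20)]
        p1 = partition_into_packs(recs, 6, "random", seed=3)
        p2 = partition_into_packs(recs, 6, "random", seed=3)
        assert [[r.accession for r in p] for p in p1] == [
            [r.accession for r in p] for p in p2
        ]
        p3 = partition_into_packs(recs, 6, "random", seed=4)
        assert [[r.accession for r in p] for p in p1] != [
            [r.accession for r in p] for p in p3
        ]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            partition_into_packs([], 2)


class TestRunRound:
    def _setup(self, n, fill):
        accs = [f"g{i}" for i in range(n)]
        recs = [genome(a) for a in accs]
        d = np.full((n, n), fill)
        np.fill_diagonal(d, 0.0)
        order = {a: i for i, a in enumerate(accs)}
        return recs, matrix_fn(accs, d), order

    def test_everything_merges(self):
        recs, fn, order = self._setup(10, 0.01)
        cfg = EngineConfig(threshold=0.5, pack_size=20)
        reps, stats, _ = run_round(recs, cfg, fn, order)
        assert len(reps) == 1
        assert stats.clustering_ratio == pytest.approx(100 * 9 / 10)

    def test_threshold_zero_keeps_everything(self):
        recs, fn, order = self._setup(5, 0.5)
        cfg = EngineConfig(threshold=0.0, pack_size=20)
        reps, stats, _ = run_round(recs, cfg, fn, order)
        assert len(reps) == 5
        assert stats.clustering_ratio == 0.0

    def test_two_packs_collapse_independently(self):
        recs, fn, order = self._setup(20, 0.01)
        cfg = EngineConfig(threshold=0.5, pack_size=10)
        reps, stats, _ = run_round(recs, cfg, fn, order)
        assert len(reps) == 2
        assert stats.clustering_ratio == pytest.approx(90.0)
        assert stats.packs == 2


class TestCheckStop:
    def test_max_rounds(self):
        stop = StopCriteria(max_rounds=1, min_clustering_ratio=None)
        assert check_stop([stats(1, 10, 5)], 5, stop) == (True, "max_rounds")

    def test_max_representatives(self):
        stop = StopCriteria(max_rounds=None, max_representatives=50,
                            min_clustering_ratio=None)
        assert check_stop([stats(1, 100, 40)], 40, stop) == (True, "max_representatives")

    def test_fixed_point_always_stops(self):
        stop = StopCriteria(max_rounds=100, min_clustering_ratio=None)
        assert check_stop([stats(1, 10, 10)], 10, stop) == (True, "fixed_point")

    def test_min_clustering_ratio(self):
        stop = StopCriteria(max_rounds=None, min_clustering_ratio=5.0)
        assert check_stop([stats(1, 1000, 999)], 999, stop) == (
            True, "min_clustering_ratio",
        )

    def test_no_criterion_fires(self):
        stop = StopCriteria(max_rounds=10, min_clustering_ratio=0.1)
        assert check_stop([stats(1, 10, 5)], 5, stop) == (False, "")

    def test_all_criteria_unset_rejected(self):
        with pytest.raises(ValueError):
            StopCriteria(max_rounds=None, max_representatives=None,
                         min_clustering_ratio=None)


class TestRunDereplication:
    def test_single_genome(self):
        recs = [genome("g1")]
        cfg = EngineConfig(threshold=0.5, pack_size=2)
        res = run_dereplication(recs, cfg, distance_fn=lambda a, b: 1.0)
        assert res.final_representatives == ["g1"]
        assert res.membership == {"g1": "g1"}

    def test_transitive_membership_composition(self):
        # g2 joins g1 in round 1; in round 2 g1 joins g0: g2 must map to g0
        accs = ["g0", "g1", "g2"]
        recs = [
            genome("g0", ["Bacteria", "Zeta"]),
            genome("g1", ["Bacteria", "Alpha"]),
            genome("g2", ["Bacteria", "Alpha"]),
        ]
        d = np.array([
            [0.0, 0.3, 0.9],
            [0.3, 0.0, 0.1],
            [0.9, 0.1, 0.0],
        ])
        # taxonomic sort puts [g1,g2] in pack 1 (g0's phylum sorts last):
        # round 1 -> g2 joins g1; round 2 pack [g0,g1] -> g1 joins g0 (0.3<0.5)
        cfg = EngineConfig(threshold=0.5, pack_size=2, sort_scheme="taxonomic")
        res = run_dereplication(recs, cfg, distance_fn=matrix_fn(accs, d))
        assert res.membership["g2"] == "g0"
        assert res.final_representatives == ["g0"]

    def test_membership_idempotent_and_reps_self_mapped(self, small_family_set):
        records, truth = small_family_set
        cfg = EngineConfig(k=10, engine="exact_ji", threshold=0.5, pack_size=5)
        res = run_dereplication(records, cfg)
        for acc, rep in res.membership.items():
            assert res.membership[rep] == rep
        for rep in res.final_representatives:
            assert res.membership[rep] == rep

    def test_representative_counts_non_increasing(self, small_family_set):
        records, _ = small_family_set
        cfg = EngineConfig(k=10, engine="exact_ji", threshold=0.5, pack_size=4)
        res = run_dereplication(records, cfg)
        counts = [s.representatives_out for s in res.rounds]
        assert counts == sorted(counts, reverse=True)
        # nested: each round's reps are a subset of the previous round's
        rep_sets = [
            {rep for pr in round_packs for rep in pr.representatives}
            for round_packs in res.provenance
        ]
        for earlier, later in zip(rep_sets, rep_sets[1:]):
            assert later <= earlier

    def test_single_pack_single_round_equals_cluster_pack(self):
        accs = [f"g{i}" for i in range(8)]
        recs = [genome(a) for a in accs]
        rng = np.random.default_rng(10)
        d = rng.random((8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        fn = matrix_fn(accs, d)
        cfg = EngineConfig(
            threshold=0.4, pack_size=100,
            stop=StopCriteria(max_rounds=1, min_clustering_ratio=None),
        )
        res = run_dereplication(recs, cfg, distance_fn=fn)
        direct = cluster_pack(accs, fn, 0.4, "loose")
        assert res.final_representatives == direct.representatives

    def test_family_recovery_taxonomic(self, small_family_set):
        records, truth = small_family_set
        cfg = EngineConfig(k=10, engine="exact_ji", threshold=0.5, pack_size=5,
                           sort_scheme="taxonomic")
        res = run_dereplication(records, cfg)
        assert len(res.final_representatives) == 4
        assert purity(res.groups(), truth) == 1.0

    def test_family_recovery_random_sort_same_purity(self, small_family_set):
        records, truth = small_family_set
        for seed in (0, 1):
            cfg = EngineConfig(k=10, engine="exact_ji", threshold=0.5, pack_size=5,
                               sort_scheme="random", random_seed=seed)
            res = run_dereplication(records, cfg)
            assert purity(res.groups(), truth) == 1.0

    def test_igf_engine_recovers_families_too(self, small_family_set):
        records, truth = small_family_set
        cfg = EngineConfig(k=10, engine="exact_igf", threshold=0.5, pack_size=5)
        res = run_dereplication(records, cfg)
        assert purity(res.groups(), truth) == 1.0

    def test_sketch_engine_recovers_families(self, small_family_set):
        records, truth = small_family_set
        cfg = EngineConfig(k=10, engine="sketch_ji", threshold=0.5, pack_size=5,
                           sketch_size=2000, sketch_seed=1)
        res = run_dereplication(records, cfg)
        assert purity(res.groups(), truth) == 1.0

    def test_priority_genome_becomes_representative(self):
        accs = ["g0", "g1", "g2"]
        recs = [genome(a) for a in accs]
        d = np.full((3, 3), 0.01)
        np.fill_diagonal(d, 0.0)
        cfg = EngineConfig(threshold=0.5, pack_size=10)
        res = run_dereplication(
            recs, cfg, distance_fn=matrix_fn(accs, d),
            lists=[AccessionList("priority", frozenset({"g2"}))],
        )
        assert res.final_representatives == ["g2"]

    def test_ranking_orders_representatives(self):
        accs = ["g0", "g1"]
        recs = [genome(a) for a in accs]
        metrics = pd.DataFrame({"m": [5.0, 1.0]}, index=accs)
        from kderep.ranking import LOWER_BETTER, RankingSpec

        cfg = EngineConfig(
            threshold=0.5, pack_size=10,
            ranking=RankingSpec(metrics=(("m", LOWER_BETTER),)),
        )
        d = np.full((2, 2), 0.01)
        np.fill_diagonal(d, 0.0)
        res = run_dereplication(recs, cfg, metrics=metrics,
                                distance_fn=matrix_fn(accs, d))
        assert res.final_representatives == ["g1"]  # better (lower) metric wins

    def test_no_eligible_genomes_rejected(self):
        recs = [genome("g1")]
        cfg = EngineConfig()
        with pytest.raises(ValueError):
            run_dereplication(
                recs, cfg, distance_fn=lambda a, b: 1.0,
                lists=[AccessionList("exclude", frozenset({"g1"}))],
            )

    def test_deterministic_given_config(self, small_family_set):
        records, _ = small_family_set
        cfg = EngineConfig(k=10, engine="exact_ji", threshold=0.5, pack_size=5,
                           sort_scheme="random", random_seed=9)
        r1 = run_dereplication(records, cfg)
        r2 = run_dereplication(records, cfg)
        assert r1.final_representatives == r2.final_representatives
        assert r1.membership == r2.membership


class TestDiversityReport:
    def _result(self, membership):
        from kderep.engine import DereplicationResult

        return DereplicationResult(
            final_representatives=sorted(set(membership.values())),
            membership=membership,
            rounds=[],
            stop_reason="test",
        )

    def test_pure_groups(self):
        recs = [genome(f"g{i}", ["Bacteria", "P1"]) for i in range(3)]
        res = self._result({"g0": "g0", "g1": "g0", "g2": "g2"})
        rep = diversity_report(res, recs)
        assert rep.n_phyla_represented == 1
        assert rep.n_groups == 2
        assert rep.n_mixed == 0
        assert rep.redundancy_index == 2.0
        assert rep.n_singletons == 1

    def test_mixed_group_detected(self):
        recs = [
            genome("g0", ["Bacteria", "Proteobacteria"]),
            genome("g1", ["Bacteria", "Firmicutes"]),
        ]
        rep = diversity_report(self._result({"g0": "g0", "g1": "g0"}), recs)
        assert rep.n_mixed == 1
        assert rep.n_pure == 0

    def test_unclassified_ignored_for_mixity(self):
        recs = [genome("g0", ["Bacteria", "Proteobacteria"]), genome("g1")]
        rep = diversity_report(self._result({"g0": "g0", "g1": "g0"}), recs)
        assert rep.n_mixed == 0

    def test_no_lineages_rejected(self):
        recs = [genome("g0"), genome("g1")]
        with pytest.raises(ValueError):
            diversity_report(self._result({"g0": "g0", "g1": "g1"}), recs)

    def test_invariants(self):
        recs = [
            genome("g0", ["Bacteria", "P1"]),
            genome("g1", ["Bacteria", "P2"]),
            genome("g2", ["Bacteria", "P2"]),
        ]
        rep = diversity_report(
            self._result({"g0": "g0", "g1": "g0", "g2": "g2"}), recs
        )
        assert rep.n_pure + rep.n_mixed == rep.n_groups
        assert rep.n_singletons <= rep.n_pure


def test_output_frames_round_trip_shapes(small_family_set):
    records, _ = small_family_set
    cfg = EngineConfig(k=10, engine="exact_ji", threshold=0.5, pack_size=5)
    res = run_dereplication(records, cfg)
    mem = membership_frame(res)
    assert set(mem.columns) == {"accession", "final_representative", "round_joined"}
    assert len(mem) == len(records)
    rnd = rounds_frame(res)
    assert list(rnd["round"]) == list(range(1, len(res.rounds) + 1))


def test_engine_config_validation():
    with pytest.raises(ValueError):
        EngineConfig(engine="blast")
    with pytest.raises(ValueError):
        EngineConfig(pack_size=1)
    with pytest.raises(ValueError):
        EngineConfig(threshold=-0.1)


def test_engine_config_from_yaml(tmp_path):
    p = tmp_path / "cfg.yaml"
    p.write_text(
        "k: 7\nengine: exact_igf\nthreshold: 0.06\npack_size: 10\n"
        "stop:\n  max_rounds: 5\nranking:\n  - 'm1:lower_better'\n"
    )
    cfg = EngineConfig.from_yaml(p)
    assert cfg.k == 7
    assert cfg.engine == "exact_igf"
    assert cfg.stop.max_rounds == 5
    assert cfg.ranking.metric_names == ["m1"]
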