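"""Greedy single-linkage clustering of one pack of rank-ordered genomes.

Genomes are processed from best to worst.  The best genome founds the
first cluster; each subsequent genome scans existing clusters in
creation order and joins the first one it is close enough to, else
founds a new cluster.  Because the input is rank-ordered, every cluster
founder is automatically the best-ranked member of its cluster and is
returned as its representative.

Two modes differ in what "close enough to a cluster" means:

* ``loose`` — within the distance threshold of *any* current member
  (pure single linkage; members are scanned in join order);
* ``strict`` — within the threshold of the *founder* only, which is
  cheaper and mitigates single-linkage chaining through bridge genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable, Sequence

LOOSE = "loose"
STRICT = "strict"


@dataclass
class Cluster:
    """One cluster: founder first, then members in join order."""

    members: list

    @property
    def representative(self):
        return self.members[0]


@dataclass
class PackResult:
    """Clusters of one pack, in creation order, plus the distance-call count."""

    clusters: list[Cluster]
    distance_calls: int = 0

    @property
    def representatives(self) -> list:
        return [c.representative for c in self.clusters]

    def membership(self) -> dict:
        return {m: c.representative for c in self.clusters for m in c.members}


def cluster_pack(
    ordered_genomes: Sequence[Hashable],
    distance_fn: Callable[[Hashable, Hashable], float],
    threshold: float,
    mode: str = LOOSE,
) -> PackResult:
    """Greedily cluster a rank-ordered pack under a distance threshold.

    A genome joins a cluster when its distance to a scanned member is
    strictly below ``threshold`` (so threshold 0 yields all singletons).
    ``distance_fn`` must be symmetric; calls are memoized per pack and
    counted, which makes the loose/strict cost difference measurable.
    """
    if not ordered_genomes:
        raise ValueError("cannot cluster an empty pack")
    if mode not in (LOOSE, STRICT):
        raise ValueError(f"unknown clustering mode {mode!r}")
    if threshold < 0:
        raise ValueError("distance threshold must be >= 0")

    cache: dict[tuple, float] = {}
    calls = 0

    def dist(a, b) -> float:
        nonlocal calls
        key = (a, b) if repr(a) <= repr(b) else (b, a)
        if key not in cache:
            calls += 1
            cache[key] = distance_fn(a, b)
        return cache[key]

    clusters: list[Cluster] = []
    for genome in ordered_genomes:
        joined = False
        for cluster in clusters:
            scan = cluster.members if mode == LOOSE else cluster.members[:1]
            if any(dist(genome, member) < threshold for member in scan):
                cluster.members.append(genome)
                joined = True
                break
        if not joined:
            clusters.append(Cluster(members=[genome]))
    return PackResult(clusters=clusters, distance_calls=calls)
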