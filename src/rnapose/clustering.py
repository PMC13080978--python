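"""Quality-Threshold clustering on precomputed distance matrices.

QT clustering is fully deterministic: from every remaining item a candidate
cluster is grown — exactly, as the maximum clique of the threshold graph,
when the item's neighbourhood is small enough to enumerate, and otherwise
greedily by adding the item that minimally increases the cluster diameter
(the maximum pairwise distance) — and the largest candidate is committed,
its members removed, until nothing is left.  The same routine
serves both the eRMSD matrix of conformational frames (cutoff 0.7) and the
symmetry-corrected pose RMSD matrix (cutoff 5 Å).

Cluster "centroids" on a distance matrix are medoids (the member minimising
the summed distance to the rest of its cluster).  Two post-processing rules
from the study design are provided: diverse-centroid retention (keep a
centroid only if it is farther than a cutoff from every centroid already
kept, scanning clusters in descending size) and population-coverage
selection (the shortest prefix of size-ordered clusters covering a given
fraction of items).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class DistanceMatrix:
    values: np.ndarray
    metric_tag: str = "other"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric (tol 1e-9)")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Clustering:
    """QT output: member-index sets ordered by decreasing size, a full label
    vector (cluster id per item), and the threshold used."""

    clusters: list[list[int]]
    labels: np.ndarray
    threshold: float

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


@dataclass
class CentroidSet:
    medoids: list[int]              # one per cluster, same order as clusters
    retained: list[bool]

    def retained_indices(self) -> list[int]:
        return [m for m, r in zip(self.medoids, self.retained) if r]


_EXACT_NEIGHBOURHOOD = 30


def _max_clique_mask(adj: list[int], n: int) -> int:
    """Deterministic branch-and-bound maximum clique on a bitmask graph."""
    best = 0
    best_count = 0

    def expand(current: int, count: int, cand: int) -> None:
        nonlocal best, best_count
        if count + cand.bit_count() <= best_count:
            return
        if cand == 0:
            if count > best_count:
                best, best_count = current, count
            return
        v = (cand & -cand).bit_length() - 1        # lowest-index branch first
        expand(current | (1 << v), count + 1, cand & adj[v])
        expand(current, count, cand & ~(1 << v))

    expand(0, 0, (1 << n) - 1)
    return best


def _grow_candidate(D: np.ndarray, seed: int, pool: np.ndarray,
                    threshold: float) -> list[int]:
    """Largest candidate cluster from one seed within ``pool``.

    A cluster of diameter <= threshold is a clique of the threshold graph,
    so for small seed neighbourhoods the maximum clique containing the seed
    is found exactly by branch and bound; larger neighbourhoods fall back to
    greedy diameter growth (adding the item that minimally increases the
    diameter), which is exact for well-separated cluster structure.
    """
    cand0 = pool[D[seed, pool] <= threshold]
    cand0 = cand0[cand0 != seed]
    if len(cand0) <= _EXACT_NEIGHBOURHOOD:
        sub = D[np.ix_(cand0, cand0)] <= threshold
        adj = [int(sum(1 << j for j in np.flatnonzero(sub[i]) if j != i))
               for i in range(len(cand0))]
        mask = _max_clique_mask(adj, len(cand0))
        members = [int(seed)] + [int(cand0[i]) for i in range(len(cand0))
                                 if mask >> i & 1]
        return members
    return _grow_greedy(D, seed, cand0, threshold)


def _grow_greedy(D: np.ndarray, seed: int, cand: np.ndarray,
                 threshold: float) -> list[int]:
    """Greedy diameter growth from one seed over its neighbour set."""
    members = [seed]
    # maxdist[i] = max distance from candidate i to current members
    maxdist = D[seed, cand].copy()
    alive = np.ones(len(cand), dtype=bool)
    while True:
        idx = np.flatnonzero(alive & (maxdist <= threshold))
        if idx.size == 0:
            break
        # add the item that minimally increases the diameter; break ties by
        # lowest item index for determinism
        best_val = maxdist[idx].min()
        tied = idx[maxdist[idx] == best_val]
        pick = tied[np.argmin(cand[tied])]
        new = cand[pick]
        members.append(int(new))
        alive[pick] = False
        np.maximum(maxdist, D[new, cand], out=maxdist)
    return members


def qt_cluster(D: DistanceMatrix, threshold: float) -> Clustering:
    """Quality-Threshold clustering at the given diameter threshold.

    Iteratively commits the largest grown candidate cluster (ties broken
    by lowest seed index), removes its members, and repeats.  The
    output is a partition; within every cluster the maximum pairwise distance
    is at most ``threshold``.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    M = D.values
    n = D.n
    remaining = np.arange(n)
    clusters: list[list[int]] = []
    while remaining.size:
        # Upper bound for each seed: itself plus its in-threshold neighbours.
        sub = M[np.ix_(remaining, remaining)]
        bound = (sub <= threshold).sum(axis=1)     # includes self
        order = np.argsort(-bound, kind="stable")  # seeds by descending bound
        best: list[int] = []
        for oi in order:
            seed = remaining[oi]
            if bound[oi] <= len(best):
                break                               # cannot strictly beat best
            cand = _grow_candidate(M, int(seed), remaining, threshold)
            if len(cand) > len(best):
                best = cand
        # Tie rule: among equal-size candidates the lowest seed index wins.
        # The scan above visits seeds in descending-bound order, so re-check
        # all seeds tied at the best size for the lowest seed index.
        if len(best) > 1:
            best_size = len(best)
            for oi in order:
                seed = int(remaining[oi])
                if bound[oi] < best_size:
                    break
                if seed >= best[0]:
                    continue
                cand = _grow_candidate(M, seed, remaining, threshold)
                if len(cand) == best_size and cand[0] < best[0]:
                    best = cand
        clusters.append(sorted(best))
        keep = ~np.isin(remaining, best)
        remaining = remaining[keep]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    labels = np.empty(n, dtype=int)
    for cid, members in enumerate(clusters):
        labels[members] = cid
    return Clustering(clusters, labels, float(threshold))


def medoid(cluster: Sequence[int], D: DistanceMatrix) -> int:
    """The cluster member minimising total distance to the other members
    (lowest index on ties)."""
    members = sorted(cluster)
    if not members:
        raise ValueError("empty cluster")
    sub = D.values[np.ix_(members, members)]
    sums = sub.sum(axis=1)
    return int(members[int(np.argmin(sums))])


def extract_centroids(clustering: Clustering, D: DistanceMatrix) -> CentroidSet:
    meds = [medoid(c, D) for c in clustering.clusters]
    return CentroidSet(meds, [True] * len(meds))


def select_diverse_centroids(
    centroids: CentroidSet, D: DistanceMatrix, cutoff: float
) -> CentroidSet:
    """Greedy diverse-centroid retention.

    Scanning centroids in descending parent-cluster size (their stored
    order), a centroid is retained iff its distance to every already-retained
    centroid exceeds ``cutoff``; the first (largest-cluster) centroid is
    always retained.  This maximises the structural variability of the
    curated ensemble.
    """
    retained: list[bool] = []
    kept: list[int] = []
    for m in centroids.medoids:
        if not kept:
            retained.append(True)
            kept.append(m)
            continue
        ok = all(D.values[m, k] > cutoff for k in kept)
        retained.append(ok)
        if ok:
            kept.append(m)
    return CentroidSet(list(centroids.medoids), retained)


def select_top_clusters(clustering: Clustering, coverage: float) -> list[int]:
    """Smallest prefix of the size-ordered clusters whose cumulative member
    fraction reaches ``coverage`` (a fraction in (0, 1])."""
    if not (0 < coverage <= 1):
        raise ValueError("coverage must lie in (0, 1]")
    total = sum(clustering.sizes)
    cum = 0
    out: list[int] = []
    for cid, size in enumerate(clustering.sizes):
        out.append(cid)
        cum += size
        if cum / total >= coverage:
            break
    return out
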