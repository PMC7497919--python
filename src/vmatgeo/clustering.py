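"""Lesion grouping: minimum-isocenter clustering under the BEV distance
criteria.

Two routes share one objective (the sum of squared Euclidean distances,
SSED, from each isocenter to its grouped lesion centroids):

* **exhaustive** — for up to 7 lesions, every set partition into k blocks is
  enumerated for k = 1, 2, 3; the first k with at least one fully feasible
  partition wins and the feasible partition with minimum total SSED is
  returned.
* **k-means** — for more than 7 lesions (or when the exhaustive search finds
  nothing at k ≤ 3), k-means++ clustering of the lesion centroids is run at
  increasing k until every cluster's symmetrized isocenter passes the
  projection-distance check.

Both paths place each cluster's isocenter by centroid initialization +
POB symmetrization before checking feasibility, so a returned clustering is
feasible by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .isocenter import (
    DEFAULT_CHECK_ANGLES,
    DistanceCriteria,
    FeasibilityReport,
    check_projection_distance,
    initial_isocenter,
    symmetrize_isocenter,
)

__all__ = [
    "Cluster",
    "ClusteringResult",
    "InfeasibleLesionError",
    "enumerate_partitions",
    "compute_ssed",
    "exhaustive_search",
    "kmeans_pp",
    "optimize_isocenters",
]

logger = logging.getLogger(__name__)

MAX_EXHAUSTIVE_LESIONS = 7
MAX_EXHAUSTIVE_ISOCENTERS = 3
DEFAULT_KMEANS_SEED = 20160701

#: SSED ties within this relative tolerance are broken lexicographically
_SSED_TIE_REL = 1e-6


class InfeasibleLesionError(ValueError):
    """A single lesion violates the distance criteria on its own; no number
    of isocenters can make the case feasible."""

    def __init__(self, lesion_id):
        self.lesion_id = lesion_id
        super().__init__(
            f"lesion {lesion_id!r} exceeds the distance criteria even with a "
            "dedicated isocenter; adjust the criteria or the contour"
        )


@dataclass
class Cluster:
    lesion_ids: list
    isocenter: np.ndarray
    ssed: float
    feasibility: FeasibilityReport

    def __post_init__(self) -> None:
        if not self.lesion_ids:
            raise ValueError("cluster must contain at least one lesion")
        if len(set(self.lesion_ids)) != len(self.lesion_ids):
            raise ValueError("duplicate lesion ids in cluster")


@dataclass
class ClusteringResult:
    clusters: list[Cluster]
    method: str  # "exhaustive" | "kmeans"
    n_feasible_candidates: int | None = None

    @property
    def n_isocenters(self) -> int:
        return len(self.clusters)

    @property
    def total_ssed(self) -> float:
        return float(sum(c.ssed for c in self.clusters))

    def assignment(self) -> dict:
        """lesion id -> cluster index"""
        return {lid: i for i, c in enumerate(self.clusters) for lid in c.lesion_ids}


def enumerate_partitions(item_ids: Sequence, k: int) -> Iterator[list[list]]:
    """Yield every set partition of ``item_ids`` into exactly ``k`` non-empty
    blocks, each exactly once, in a canonical order.

    Canonical form: within a block, items keep input order; blocks are
    ordered by their smallest (first-seen) member, which the construction
    guarantees (item 0 is always in block 0, the first item outside blocks
    0..j-1 opens block j).  Enumeration is by restricted-growth placement:
    each item joins an existing block or opens a new one, never leaving more
    items than open slots.
    """
    items = list(item_ids)
    n = len(items)
    if not (1 <= k <= n):
        raise ValueError(f"cannot partition {n} items into {k} non-empty blocks")

    blocks: list[list] = []

    def place(i: int) -> Iterator[list[list]]:
        if i == n:
            if len(blocks) == k:
                yield [list(b) for b in blocks]
            return
        remaining = n - i
        for b in blocks:
            # feasible only if the rest can still open the missing blocks
            if remaining - 1 >= k - len(blocks):
                b.append(items[i])
                yield from place(i + 1)
                b.pop()
        if len(blocks) < k:
            blocks.append([items[i]])
            yield from place(i + 1)
            blocks.pop()

    return place(0)


def compute_ssed(member_centroids: np.ndarray, isocenter: np.ndarray) -> float:
    """Sum of squared Euclidean distances (mm²) from the isocenter to each
    member lesion centroid — the clustering objective."""
    cents = np.asarray(member_centroids, dtype=float).reshape(-1, 3)
    if len(cents) == 0:
        raise ValueError("SSED needs at least one centroid")
    iso = np.asarray(isocenter, dtype=float).reshape(3)
    return float(np.sum((cents - iso) ** 2))


def _partition_key(partition: list[list], id_rank: dict) -> tuple:
    """Sort key for the documented lexicographic tie-break."""
    return tuple(tuple(id_rank[lid] for lid in block) for block in partition)


def _evaluate_block(block_lesions, criteria, check_angles, mode):
    iso0 = initial_isocenter(block_lesions)
    iso = symmetrize_isocenter(block_lesions, iso0, mode=mode)
    report = check_projection_distance(
        block_lesions, iso, criteria, check_angles=check_angles, mode=mode
    )
    ssed = compute_ssed([l.centroid for l in block_lesions], iso)
    return iso, ssed, report


def _check_singletons(lesions, criteria, check_angles, mode) -> None:
    for lesion in lesions:
        _, _, report = _evaluate_block([lesion], criteria, check_angles, mode)
        if not report.overall_pass:
            raise InfeasibleLesionError(lesion.id)


def exhaustive_search(
    lesions,
    criteria: DistanceCriteria,
    max_k: int = MAX_EXHAUSTIVE_ISOCENTERS,
    check_angles=DEFAULT_CHECK_ANGLES,
    mode: str = "parallel",
) -> ClusteringResult | None:
    """Minimum-isocenter exhaustive set-partition search.

    For k = 1..max_k every partition of the lesions into k blocks is scored:
    each block's isocenter is placed (centroid + symmetrization) and checked
    against ``criteria``.  At the first k admitting at least one fully
    feasible partition, the feasible partition with minimum total SSED is
    returned (ties broken to the lexicographically smallest canonical
    partition).  Returns None if no k ≤ max_k is feasible.
    """
    lesions = list(lesions)
    _check_singletons(lesions, criteria, check_angles, mode)
    by_id = {l.id: l for l in lesions}
    id_rank = {l.id: i for i, l in enumerate(lesions)}
    ids = [l.id for l in lesions]

    for k in range(1, min(max_k, len(lesions)) + 1):
        best = None  # (ssed, key, clusters)
        n_feasible = 0
        for partition in enumerate_partitions(ids, k):
            clusters = []
            total = 0.0
            feasible = True
            for block in partition:
                block_lesions = [by_id[lid] for lid in block]
                iso, ssed, report = _evaluate_block(
                    block_lesions, criteria, check_angles, mode
                )
                if not report.overall_pass:
                    feasible = False
                    break
                clusters.append(Cluster(list(block), iso, ssed, report))
                total += ssed
            if not feasible:
                continue
            n_feasible += 1
            key = _partition_key(partition, id_rank)
            if best is None:
                best = (total, key, clusters)
            else:
                rel = abs(total - best[0]) / max(abs(best[0]), 1e-30)
                if (rel > _SSED_TIE_REL and total < best[0]) or (
                    rel <= _SSED_TIE_REL and key < best[1]
                ):
                    best = (total, key, clusters)
        if best is not None:
            logger.info(
                "exhaustive search: k=%d feasible (%d candidate partitions)",
                k,
                n_feasible,
            )
            return ClusteringResult(
                clusters=best[2], method="exhaustive", n_feasible_candidates=n_feasible
            )
    return None


def kmeans_pp(
    centroids: np.ndarray,
    k: int,
    repeats: int | None = None,
    seed: int = DEFAULT_KMEANS_SEED,
) -> tuple[np.ndarray, np.ndarray]:
    """k-means++ on lesion centroids: best of ``repeats`` seeded runs by
    within-cluster SSED.  Returns (labels, cluster centers)."""
    cents = np.asarray(centroids, dtype=float).reshape(-1, 3)
    n = len(cents)
    if repeats is None:
        repeats = n
    n_distinct = len(np.unique(cents, axis=0))
    if not (1 <= k <= n_distinct):
        raise ValueError(f"k={k} outside [1, {n_distinct} distinct centroids]")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=max(1, repeats),
        random_state=int(seed) % (2**31),
    ).fit(cents)
    return km.labels_.copy(), km.cluster_centers_.copy()


def _kmeans_escalation(lesions, criteria, check_angles, mode, start_k, repeats, seed):
    cents = np.array([l.centroid for l in lesions])
    for k in range(start_k, len(lesions) + 1):
        labels, _ = kmeans_pp(cents, k, repeats=repeats, seed=seed)
        clusters = []
        feasible = True
        for j in range(k):
            block_lesions = [l for l, lab in zip(lesions, labels) if lab == j]
            if not block_lesions:
                feasible = False
                break
            iso, ssed, report = _evaluate_block(
                block_lesions, criteria, check_angles, mode
            )
            if not report.overall_pass:
                feasible = False
                break
            clusters.append(Cluster([l.id for l in block_lesions], iso, ssed, report))
        if feasible:
            logger.info("k-means escalation: feasible at k=%d", k)
            # deterministic cluster order: by input rank of the first member
            rank = {l.id: i for i, l in enumerate(lesions)}
            clusters.sort(key=lambda c: min(rank[lid] for lid in c.lesion_ids))
            return ClusteringResult(clusters=clusters, method="kmeans")
    raise RuntimeError("k-means escalation exhausted k up to the lesion count")


def optimize_isocenters(
    lesions,
    criteria: DistanceCriteria,
    *,
    max_exhaustive_lesions: int = MAX_EXHAUSTIVE_LESIONS,
    max_exhaustive_isocenters: int = MAX_EXHAUSTIVE_ISOCENTERS,
    kmeans_repeats: int | None = None,
    kmeans_seed: int = DEFAULT_KMEANS_SEED,
    check_angles=DEFAULT_CHECK_ANGLES,
    mode: str = "parallel",
) -> ClusteringResult:
    """Dispatch lesion grouping to the exhaustive or k-means route.

    Up to ``max_exhaustive_lesions`` lesions (default 7) the exhaustive
    search runs for k ≤ ``max_exhaustive_isocenters`` (default 3); larger
    cases, or an exhaustive search that found nothing, fall through to
    k-means escalation (starting past the proven-infeasible k).
    """
    lesions = list(lesions)
    if not lesions:
        raise ValueError("no lesions to cluster")
    logger.info(
        "optimizing isocenters: %d lesions, criteria x<=%g mm y<=%g mm",
        len(lesions),
        criteria.x_max_mm,
        criteria.y_max_mm,
    )
    if len(lesions) <= max_exhaustive_lesions:
        result = exhaustive_search(
            lesions,
            criteria,
            max_k=max_exhaustive_isocenters,
            check_angles=check_angles,
            mode=mode,
        )
        if result is not None:
            return result
        start_k = max_exhaustive_isocenters + 1
    else:
        _check_singletons(lesions, criteria, check_angles, mode)
        start_k = 1
    return _kmeans_escalation(
        lesions, criteria, check_angles, mode, start_k, kmeans_repeats, kmeans_seed
    )
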