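"""Hierarchical average-linkage clustering and the two tree-cut criteria.

Fragments are agglomerated with average linkage (UPGMA-style) on a normalized
distance matrix.  Two cut criteria turn the dendrogram into clusters:

* the structural cut scans every merge height and minimizes
  ``J = mean intra-cluster pairwise RMSD - lambda * (fraction of fragments
  within rmsd_threshold of their cluster medoid)``, trading compactness
  against the number of correctly positioned fragments;
* the sequence cut minimizes ``#singleton clusters + #clusters smaller than
  min_size``, breaking ties toward fewer clusters, then toward the lower cut.

Candidate cuts are horizontal (one height for the whole tree), which keeps
the objective exhaustively enumerable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from tmmotif.fragments import Fragment
from tmmotif.metrics import DistanceMatrix, rmsd_matrix


@dataclass
class Dendrogram:
    """Agglomeration result: scipy linkage matrix plus the leaf ids."""

    leaf_ids: list[str]
    merges: np.ndarray  # scipy (n-1, 4) linkage matrix

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if n > 1 and self.merges.shape != (n - 1, 4):
            raise ValueError("linkage matrix shape mismatch")
        heights = self.merges[:, 2]
        if heights.size and np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    def cut(self, height: float) -> list[list[int]]:
        """Leaf-index clusters after merging everything at or below ``height``."""
        n = len(self.leaf_ids)
        if n == 1:
            return [[0]]
        labels = fcluster(self.merges, t=height, criterion="distance")
        clusters: dict[int, list[int]] = {}
        for leaf, lab in enumerate(labels):
            clusters.setdefault(lab, []).append(leaf)
        return [sorted(c) for c in sorted(clusters.values(), key=lambda c: c[0])]

    def candidate_heights(self) -> list[float]:
        """All distinct partitions: below the first merge, then each merge height."""
        if len(self.leaf_ids) == 1:
            return [0.0]
        hs = [-1e-12]
        hs.extend(float(h) for h in self.merges[:, 2])
        return sorted(set(hs))

    def to_newick(self) -> str:
        n = len(self.leaf_ids)
        if n == 1:
            return f"{self.leaf_ids[0]};"
        reps: dict[int, str] = {i: self.leaf_ids[i] for i in range(n)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = (h - heights[a]) / 2
            lb = (h - heights[b]) / 2
            reps[n + k] = f"({reps.pop(a)}:{la:.6g},{reps.pop(b)}:{lb:.6g})"
            heights[n + k] = float(h)
        return reps[2 * n - 2] + ";"


@dataclass
class ClusterSet:
    """A partition of the leaves at one cut, with per-cluster diagnostics."""

    clusters: list[list[str]]
    cut_height: float
    mean_rmsd: list[float | None] = field(default_factory=list)
    objective: float | None = None

    @property
    def outliers(self) -> list[list[str]]:
        return [c for c in self.clusters if len(c) == 1]

    @property
    def largest(self) -> int:
        return max(len(c) for c in self.clusters)

    def to_tsv(self) -> str:
        rows = ["fragment_id\tcluster_id"]
        for k, cluster in enumerate(self.clusters):
            for fid in cluster:
                rows.append(f"{fid}\t{k}")
        return "\n".join(rows) + "\n"


def average_linkage(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA-style) agglomeration of a distance matrix."""
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("non-finite distances")
    n = len(dm.ids)
    if n == 1:
        return Dendrogram(list(dm.ids), np.empty((0, 4)))
    condensed = squareform(dm.values, checks=False)
    merges = linkage(condensed, method="average")
    return Dendrogram(list(dm.ids), merges)


def structural_objective(
    clusters: list[list[int]],
    rmsd: np.ndarray,
    rmsd_threshold: float,
    lambda_tradeoff: float,
) -> float:
    """J = pooled mean intra-cluster pairwise RMSD - lambda * fraction correctly positioned.

    A fragment is correctly positioned when it sits *inside a sub-cluster*
    (size >= 2), its RMSD to its own cluster medoid (the member minimizing
    total RMSD to the rest) is at most the threshold, and that medoid is the
    nearest of all sub-cluster medoids -- i.e. the fragment is in the right
    cluster.  Singletons never count (otherwise the all-singleton partition,
    with zero RMSD and everything trivially positioned, would always win),
    and the nearest-medoid condition keeps oversplit partitions from scoring
    as well as the true one.
    """
    pair_sum = 0.0
    pair_count = 0
    n_total = sum(len(c) for c in clusters)
    medoids: list[int | None] = []
    for cluster in clusters:
        if len(cluster) == 1:
            medoids.append(None)
            continue
        sub = rmsd[np.ix_(cluster, cluster)]
        iu = np.triu_indices(len(cluster), k=1)
        pair_sum += float(sub[iu].sum())
        pair_count += len(iu[0])
        medoids.append(cluster[int(np.argmin(sub.sum(axis=1)))])
    medoid_ids = [m for m in medoids if m is not None]
    n_correct = 0
    for cluster, medoid in zip(clusters, medoids):
        if medoid is None:
            continue
        for frag in cluster:
            d_own = rmsd[frag, medoid]
            if d_own > rmsd_threshold:
                continue
            if all(rmsd[frag, other] >= d_own for other in medoid_ids):
                n_correct += 1
    mean_rmsd = pair_sum / pair_count if pair_count else 0.0
    return mean_rmsd - lambda_tradeoff * (n_correct / n_total)


def _cluster_mean_rmsds(clusters: list[list[int]], rmsd: np.ndarray) -> list[float | None]:
    out: list[float | None] = []
    for cluster in clusters:
        if len(cluster) == 1:
            out.append(None)
            continue
        sub = rmsd[np.ix_(cluster, cluster)]
        iu = np.triu_indices(len(cluster), k=1)
        out.append(float(sub[iu].mean()))
    return out


def cut_structural_tree(
    dend: Dendrogram,
    frags: list[Fragment],
    rmsd_threshold: float = 1.5,
    lambda_tradeoff: float = 2.0,
    rmsd: np.ndarray | None = None,
) -> ClusterSet:
    """Cut minimizing the compactness/correct-positioning trade-off objective.

    Ties go to the partition with fewer clusters, then to the lower cut.
    """
    id_to_frag = {f.frag_id: f for f in frags}
    ordered = [id_to_frag[i] for i in dend.leaf_ids]
    if rmsd is None:
        rmsd = rmsd_matrix(ordered)
    best: tuple[float, int, float] | None = None
    best_clusters: list[list[int]] | None = None
    best_h = 0.0
    for h in dend.candidate_heights():
        clusters = dend.cut(h)
        j = structural_objective(clusters, rmsd, rmsd_threshold, lambda_tradeoff)
        key = (round(j, 12), len(clusters), h)
        if best is None or key < best:
            best, best_clusters, best_h = key, clusters, h
    assert best_clusters is not None
    return ClusterSet(
        clusters=[[dend.leaf_ids[i] for i in c] for c in best_clusters],
        cut_height=best_h,
        mean_rmsd=_cluster_mean_rmsds(best_clusters, rmsd),
        objective=best[0],
    )


def sequence_objective(clusters: list[list[int]], min_size: int) -> int:
    """#singleton clusters + #clusters with fewer than ``min_size`` members."""
    singletons = sum(1 for c in clusters if len(c) == 1)
    small = sum(1 for c in clusters if len(c) < min_size)
    return singletons + small


def cut_sequence_tree(dend: Dendrogram, min_size: int = 5) -> ClusterSet:
    """Cut minimizing singleton and undersized-cluster counts.

    Ties prefer the finer partition (more clusters -- the cut exists to
    isolate specific sequence families), then the lower height.
    """
    best: tuple[int, int, float] | None = None
    best_clusters: list[list[int]] | None = None
    best_h = 0.0
    for h in dend.candidate_heights():
        clusters = dend.cut(h)
        obj = sequence_objective(clusters, min_size)
        key = (obj, -len(clusters), h)
        if best is None or key < best:
            best, best_clusters, best_h = key, clusters, h
    assert best_clusters is not None
    return ClusterSet(
        clusters=[[dend.leaf_ids[i] for i in c] for c in best_clusters],
        cut_height=best_h,
        objective=float(best[0]),
    )
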