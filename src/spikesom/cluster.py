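"""Hierarchical agglomerative clustering of BMU-trajectory distances.

The agglomerator runs the Lance-Williams recurrence directly on the
supplied dissimilarity matrix.  Average linkage is the applied option;
single, complete, median, centroid and Ward are available for
sensitivity analysis.  Because the trajectory distances are *squared*
map distances, the geometric linkages (median/centroid/ward) operate on
squared-distance semantics, where centroid/median can produce height
inversions; average linkage is monotone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .som import DistanceMatrix

LINKAGES = ("single", "complete", "average", "median", "centroid", "ward")


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: cluster indices follow the scipy convention
    (leaves 0..n-1, the k-th merge creates cluster n+k)."""

    left: int
    right: int
    height: float
    count: int


@dataclass
class Dendrogram:
    """Result of agglomerative clustering: n-1 ordered merges over n leaves."""

    merges: list[Merge]
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])


def _lance_williams(linkage: str, na: int, nb: int, nc: int) -> tuple[float, float, float, float]:
    """(alpha_a, alpha_b, beta, gamma) coefficients for d(C, A+B)."""
    if linkage == "single":
        return 0.5, 0.5, 0.0, -0.5
    if linkage == "complete":
        return 0.5, 0.5, 0.0, 0.5
    if linkage == "average":
        return na / (na + nb), nb / (na + nb), 0.0, 0.0
    if linkage == "median":
        return 0.5, 0.5, -0.25, 0.0
    if linkage == "centroid":
        s = na + nb
        return na / s, nb / s, -na * nb / (s * s), 0.0
    if linkage == "ward":
        s = na + nb + nc
        return (na + nc) / s, (nb + nc) / s, -nc / s, 0.0
    raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")


def agglomerate(D: DistanceMatrix | np.ndarray, linkage: str = "average",
                ids: Sequence[str] | None = None) -> Dendrogram:
    """Agglomerative clustering by the Lance-Williams update.

    At each step the pair of active clusters with the smallest
    dissimilarity is merged (ties broken by the lexicographically
    smallest cluster-index pair), recording the merge height; the
    dissimilarity of the new cluster to every other is given by the
    linkage's Lance-Williams coefficients.
    """
    if isinstance(D, DistanceMatrix):
        mat, leaf_ids = D.values, list(D.ids)
    else:
        mat = np.asarray(D, dtype=float)
        leaf_ids = list(ids) if ids is not None else [f"leaf{i}" for i in range(mat.shape[0])]
    n = mat.shape[0]
    if mat.shape != (n, n) or n < 2:
        raise ValueError("distance matrix must be square with n >= 2")
    if not np.allclose(mat, mat.T, rtol=0, atol=1e-12 * max(1.0, np.abs(mat).max())):
        raise ValueError("distance matrix must be symmetric")
    if (mat < 0).any():
        raise ValueError("distance matrix must be non-negative")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; expected one of {LINKAGES}")

    d = mat.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    active = list(range(n))                  # positions currently alive
    cluster_of = list(range(n))              # position -> cluster index
    sizes = {i: 1 for i in range(n)}
    merges: list[Merge] = []
    for step in range(n - 1):
        # smallest dissimilarity; ties -> lexicographically smallest pair
        best = (np.inf, n * 2, n * 2)
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                pa, pb = active[ai], active[bi]
                ca, cb = cluster_of[pa], cluster_of[pb]
                lo, hi = min(ca, cb), max(ca, cb)
                key = (d[pa, pb], lo, hi)
                if key < best:
                    best = key
                    pair = (pa, pb)
        pa, pb = pair
        ca, cb = cluster_of[pa], cluster_of[pb]
        height = d[pa, pb]
        na, nb = sizes[ca], sizes[cb]
        new_cluster = n + step
        merges.append(Merge(left=min(ca, cb), right=max(ca, cb),
                            height=float(height), count=na + nb))
        # update dissimilarities of the merged cluster (stored at slot pa)
        for pc in active:
            if pc in (pa, pb):
                continue
            nc = sizes[cluster_of[pc]]
            aa, ab, beta, gamma = _lance_williams(linkage, na, nb, nc)
            val = (aa * d[pa, pc] + ab * d[pb, pc] + beta * height
                   + gamma * abs(d[pa, pc] - d[pb, pc]))
            d[pa, pc] = d[pc, pa] = val
        d[pb, :] = d[:, pb] = np.inf
        active.remove(pb)
        cluster_of[pa] = new_cluster
        sizes[new_cluster] = na + nb
    return Dendrogram(merges=merges, leaf_ids=leaf_ids)


def dendrogram_to_newick(dend: Dendrogram) -> str:
    """Serialise an ultrametric dendrogram as a Newick string.

    Each merge node sits at half its merge height, so a two-leaf
    dendrogram at height h becomes ``(A:h/2,B:h/2);``.
    """
    n = dend.n_leaves
    node_height = {i: 0.0 for i in range(n)}
    subtree: dict[int, str] = {i: _escape_newick(dend.leaf_ids[i]) for i in range(n)}
    for k, m in enumerate(dend.merges):
        h = m.height / 2.0
        bl_left = max(h - node_height[m.left], 0.0)
        bl_right = max(h - node_height[m.right], 0.0)
        subtree[n + k] = (f"({subtree[m.left]}:{bl_left:.10g},"
                          f"{subtree[m.right]}:{bl_right:.10g})")
        node_height[n + k] = h
    return subtree[n + len(dend.merges) - 1] + ";"


def _escape_newick(label: str) -> str:
    if any(ch in label for ch in "(),:; \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def pair_merge_fraction(dend: Dendrogram,
                        pairing: Mapping[str, tuple[str, str]]) -> float:
    """Fraction of players whose successful and faulty leaves are each
    other's first merge partner (they merge as singletons, before either
    joins any other cluster)."""
    index = {leaf: i for i, leaf in enumerate(dend.leaf_ids)}
    first_merges = {frozenset((m.left, m.right)) for m in dend.merges
                    if m.left < dend.n_leaves and m.right < dend.n_leaves}
    hits = 0
    for player, (succ_id, fault_id) in pairing.items():
        for leaf in (succ_id, fault_id):
            if leaf not in index:
                raise KeyError(f"pairing for {player!r} references unknown leaf {leaf!r}")
        if frozenset((index[succ_id], index[fault_id])) in first_merges:
            hits += 1
    if not pairing:
        raise ValueError("empty pairing")
    return hits / len(pairing)
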