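"""Mesoscale structure: hierarchical clustering, stability, hub scoring.

Embedding coordinates are clustered with Ward's minimum-variance linkage
on Euclidean distances.  Stability across participant-level bootstrap
iterations is quantified two ways: globally, with the Fowlkes–Mallows
pair-counting index normalized by its chance expectation (0 = chance,
1 = identical), and per cluster, with the maximum Jaccard coefficient
against each bootstrap labeling minus a permutation bias estimate.

Hubs are scored geometrically: a node whose connectivity is strong and
homogeneous sits near the centroid of embedding space, so centroid
distance (optionally normalized to the within-band median) and mean
connectivity are reported side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .embedding import Embedding
from .types import ConnectivityMatrix

__all__ = [
    "ClusterTree",
    "hierarchical_clusters",
    "fowlkes_mallows_normalized",
    "jaccard_stability",
    "hub_scores",
]


@dataclass
class ClusterTree:
    """Ward linkage with optimized leaf order and labelings at cut levels."""

    linkage: np.ndarray
    leaf_order: np.ndarray
    labels: dict = field(default_factory=dict)   # n_clusters -> labels array
    node_labels: list = field(default_factory=list)

    def cut(self, n_clusters: int) -> np.ndarray:
        if n_clusters not in self.labels:
            self.labels[n_clusters] = hierarchy.fcluster(
                self.linkage, t=n_clusters, criterion="maxclust")
        return self.labels[n_clusters]


def hierarchical_clusters(emb: Embedding, n_clusters: int) -> ClusterTree:
    """Ward-linkage agglomerative clustering of embedding coordinates.

    Leaf order is optimized for group cohesion (distance-minimizing
    ordering over the fixed tree topology); merge heights are unaffected.
    """
    n = emb.n_nodes
    if not (2 <= n_clusters < n):
        raise ValueError(f"need 2 <= n_clusters < {n}")
    z = hierarchy.linkage(emb.coords, method="ward")
    from scipy.spatial.distance import pdist
    zo = hierarchy.optimal_leaf_ordering(z, pdist(emb.coords))
    order = hierarchy.leaves_list(zo)
    tree = ClusterTree(linkage=z, leaf_order=order,
                       node_labels=list(emb.node_labels))
    tree.cut(n_clusters)
    return tree


def _pair_counts(labels_a: np.ndarray, labels_b: np.ndarray):
    """Contingency-based pair counts for two labelings of the same items."""
    la = np.asarray(labels_a)
    lb = np.asarray(labels_b)
    if la.shape != lb.shape:
        raise ValueError("labelings cover different item sets")
    _, ia = np.unique(la, return_inverse=True)
    _, ib = np.unique(lb, return_inverse=True)
    ka, kb = ia.max() + 1, ib.max() + 1
    ct = np.bincount(ia * kb + ib, minlength=ka * kb).reshape(ka, kb)
    n = la.size
    tk = (ct ** 2).sum() - n                    # 2 * co-paired in both
    pk = (ct.sum(axis=1) ** 2).sum() - n        # 2 * pairs in A
    qk = (ct.sum(axis=0) ** 2).sum() - n        # 2 * pairs in B
    return tk / 2.0, pk / 2.0, qk / 2.0, n


def fowlkes_mallows_normalized(labels_a, labels_b, k: int | None = None
                               ) -> float:
    """Chance-normalized Fowlkes–Mallows index ``B_k``.

    Raw ``B_k = T_k / sqrt(P_k Q_k)`` (pair counting).  Under random
    permutation of labels with fixed marginal cluster sizes the expected
    number of shared pairs is hypergeometric, ``E(T_k) = P_k Q_k / M`` with
    ``M = n(n-1)/2``, giving ``E(B_k) = sqrt(P_k Q_k) / M``.  Returned is
    ``(B_k - E(B_k)) / (1 - E(B_k))``: 0 at chance, 1 when identical.
    """
    la, lb = np.asarray(labels_a), np.asarray(labels_b)
    if k is None:
        k = len(np.unique(la))
    if k < 2:
        raise ValueError("normalized Fowlkes-Mallows undefined for k = 1")
    tk, pk, qk, n = _pair_counts(la, lb)
    if pk == 0 or qk == 0:
        raise ValueError("a labeling has no co-clustered pair (all "
                         "singletons)")
    bk = tk / np.sqrt(pk * qk)
    m = n * (n - 1) / 2.0
    e_bk = np.sqrt(pk * qk) / m
    return float((bk - e_bk) / (1.0 - e_bk))


def _max_jaccard(ref_cluster: set, labels: np.ndarray) -> float:
    best = 0.0
    for c in np.unique(labels):
        other = set(np.flatnonzero(labels == c))
        inter = len(ref_cluster & other)
        union = len(ref_cluster | other)
        if union and inter / union > best:
            best = inter / union
    return best


def jaccard_stability(reference_labels, bootstrap_labelings,
                      n_perm_bias: int = 1, seed: int = 0) -> pd.DataFrame:
    """Per-cluster bias-corrected Jaccard stability across bootstraps.

    For each reference cluster, the maximum Jaccard coefficient against the
    clusters of each bootstrap labeling is summarized by its median across
    iterations.  A bias estimate — the same statistic with the bootstrap
    cluster assignments randomly permuted — is subtracted, so labelings
    that match the reference only by chance score near 0.
    """
    ref = np.asarray(reference_labels)
    clusters = np.unique(ref)
    if any((ref == c).sum() == 0 for c in clusters):
        raise ValueError("empty reference cluster")
    rng = np.random.default_rng(seed)
    raw = {c: [] for c in clusters}
    bias = {c: [] for c in clusters}
    for lb in bootstrap_labelings:
        lb = np.asarray(lb)
        for _ in range(max(1, n_perm_bias)):
            perm = rng.permutation(lb)
            for c in clusters:
                members = set(np.flatnonzero(ref == c))
                bias[c].append(_max_jaccard(members, perm))
        for c in clusters:
            members = set(np.flatnonzero(ref == c))
            raw[c].append(_max_jaccard(members, lb))
    rows = []
    for c in clusters:
        med = float(np.median(raw[c]))
        b = float(np.median(bias[c]))
        rows.append({"cluster": c, "jaccard_median": med,
                     "bias_estimate": b, "jaccard_corrected": med - b})
    return pd.DataFrame(rows).set_index("cluster")


def hub_scores(emb: Embedding, conn: ConnectivityMatrix) -> pd.DataFrame:
    """Centroid distance and mean connectivity per node.

    Global hubs — strongly and homogeneously connected nodes — sit near
    the center of embedding space, so centroid distance and mean
    connectivity are strongly inversely related.  ``distance_normalized``
    divides by the median centroid distance (median = 1 within a band).
    """
    if list(emb.node_labels) != list(conn.node_labels):
        raise ValueError("embedding and connectivity node sets differ")
    centroid = emb.coords.mean(axis=0)
    dist = np.linalg.norm(emb.coords - centroid, axis=1)
    v = conn.values.copy().astype(float)
    np.fill_diagonal(v, np.nan)
    mean_conn = np.nanmean(v, axis=1)
    med = np.median(dist)
    norm = dist / med if med > 0 else np.ones_like(dist)
    return pd.DataFrame({
        "node": list(emb.node_labels),
        "centroid_distance": dist,
        "mean_connectivity": mean_conn,
        "distance_normalized": norm,
    }).set_index("node")
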