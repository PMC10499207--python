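"""Diffusion map embedding (DME) of thresholded connectivity graphs.

Pipeline: a symmetric connectivity matrix is sparsified (top third of each
row, symmetrized, plus the minimum spanning tree of the elementwise
reciprocal so the graph stays connected), transformed to a cosine
similarity kernel ``K``, and normalized into the random-walk operator
``P = D^-1 K`` and its symmetric form ``Psymm = D^-0.5 K D^-0.5``.  Nodes
are mapped to ``Psi(t) = [lambda_j^t psi_j]`` over the non-trivial
eigenvectors; Euclidean distance in the full embedding equals the t-step
diffusion distance of the random walk, which a brute-force oracle
(:func:`diffusion_distance_direct`) verifies by explicit matrix powers.

The retained dimensionality comes from the eigenvalue spectrum: the
spectral norm error of the best rank-k approximation to ``P`` is
``sigma_{k+1}``, so the elbow ``k_infl`` of the sorted magnitude spectrum
marks where extra dimensions stop paying for themselves; ``k_infl - 1``
dimensions are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .types import ConnectivityMatrix

__all__ = [
    "threshold_connectivity",
    "cosine_similarity_matrix",
    "build_diffusion_operator",
    "DiffusionOperator",
    "Embedding",
    "diffusion_map",
    "multiscale_diffusion_map",
    "select_dimensions",
    "change_of_basis",
    "embedding_distances",
    "diffusion_distance_direct",
    "compare_embeddings",
    "embed_connectivity",
]


def threshold_connectivity(conn: ConnectivityMatrix,
                           fraction: float = 1.0 / 3.0) -> ConnectivityMatrix:
    """Sparsify while guaranteeing a single connected component.

    Keeps, for every row, the top ``ceil(fraction * (n - 1))`` off-diagonal
    entries (ties broken by value descending then column index ascending),
    the transpose of that mask (symmetry), and every edge of the minimum
    spanning tree of the elementwise-reciprocal weight graph.  All other
    entries are zeroed.
    """
    v = conn.values.copy()
    n = v.shape[0]
    if n < 3:
        raise ValueError("thresholding needs >= 3 nodes")
    np.fill_diagonal(v, 0.0)
    off = ~np.eye(n, dtype=bool)
    if not np.isfinite(v[off]).all():
        raise ValueError("non-finite connectivity entries")
    m = int(np.ceil(fraction * (n - 1)))
    keep = np.zeros((n, n), dtype=bool)
    cols = np.arange(n)
    for i in range(n):
        vals = v[i].copy()
        vals[i] = -np.inf
        # stable order: value descending, then column index ascending
        order = np.lexsort((cols, -vals))
        keep[i, order[:m]] = True
    keep |= keep.T
    # MST of the reciprocal graph (strong connections = short edges)
    w = 1.0 / np.clip(v, 1e-12, None)
    np.fill_diagonal(w, 0.0)
    mst = minimum_spanning_tree(np.triu(w)).toarray()
    keep |= (mst > 0) | (mst > 0).T
    out = np.where(keep, v, 0.0)
    np.fill_diagonal(out, 0.0)
    n_comp, _ = connected_components((out != 0).astype(int), directed=False)
    if n_comp != 1:
        # only possible when the input graph itself (positive edges) is
        # disconnected — the MST would otherwise have bridged it
        raise ValueError("connectivity graph is disconnected; "
                         "thresholding cannot keep it connected")
    return ConnectivityMatrix(values=out, node_labels=conn.node_labels,
                              level=conn.level, band=conn.band,
                              measure=conn.measure,
                              n_segments_used=conn.n_segments_used)


def cosine_similarity_matrix(conn: ConnectivityMatrix,
                             include_self: bool = False) -> np.ndarray:
    """Cosine similarity between rows of the thresholded connectivity.

    By default the two self-connectivity positions (columns ``i`` and
    ``j``) are excluded when comparing rows ``i`` and ``j``.  Negative
    cosines are floored at 0 so ``K`` remains a valid random-walk kernel;
    the diagonal is 1.
    """
    c = conn.values.copy()
    n = c.shape[0]
    np.fill_diagonal(c, 0.0)
    if not (c.any(axis=1)).all():
        raise ValueError("zero row in thresholded connectivity")
    g = c @ c.T
    norm2 = (c ** 2).sum(axis=1)
    if include_self:
        denom2 = np.outer(norm2, norm2)
    else:
        # with a zero diagonal, excluding columns {i, j} removes c[i, j]
        # from row i's norm and c[j, i] from row j's; the dot product is
        # unchanged
        ni = norm2[:, None] - c ** 2
        nj = norm2[None, :] - c.T ** 2
        denom2 = ni * nj
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(denom2 > 0, g / np.sqrt(np.where(denom2 > 0, denom2, 1.0)),
                     0.0)
    k = np.clip(k, 0.0, None)
    k = (k + k.T) / 2.0
    np.fill_diagonal(k, 1.0)
    return k


@dataclass
class DiffusionOperator:
    """Similarity kernel with its random-walk normalizations and spectrum.

    ``eigvals`` are sorted by decreasing magnitude (``eigvals[0] = 1`` for
    a connected graph); ``eigvecs`` are the orthonormal eigenvectors of
    ``Psymm`` with the sign convention that each vector's largest-magnitude
    component is positive.  ``psi`` are the corresponding right
    eigenvectors of ``P`` scaled by ``sqrt(sum(d))`` so that Euclidean
    distances in the full embedding equal diffusion distances exactly.
    """

    K: np.ndarray
    d: np.ndarray
    P: np.ndarray
    Psymm: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray
    psi: np.ndarray
    node_labels: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.K.shape[0]

    @property
    def stationary(self) -> np.ndarray:
        return self.d / self.d.sum()


def build_diffusion_operator(K: np.ndarray,
                             node_labels=None) -> DiffusionOperator:
    """Normalize a similarity kernel into diffusion operators + spectrum."""
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("K must be symmetric")
    if (K < 0).any():
        raise ValueError("K must be nonnegative")
    n_comp, _ = connected_components((K > 0).astype(int), directed=False)
    if n_comp != 1:
        raise ValueError("similarity graph is disconnected; DME requires "
                         "no isolated nodes")
    d = K.sum(axis=1)
    P = K / d[:, None]
    sq = np.sqrt(d)
    Psymm = K / np.outer(sq, sq)
    eigvals, V = np.linalg.eigh((Psymm + Psymm.T) / 2.0)
    order = np.argsort(-np.abs(eigvals), kind="stable")
    eigvals, V = eigvals[order], V[:, order]
    # sign convention: largest-magnitude component positive
    flip = V[np.abs(V).argmax(axis=0), np.arange(n)] < 0
    V[:, flip] *= -1.0
    psi = np.sqrt(d.sum()) * (V / sq[:, None])
    if node_labels is None:
        node_labels = list(range(n))
    return DiffusionOperator(K=K, d=d, P=P, Psymm=Psymm, eigvals=eigvals,
                             eigvecs=V, psi=psi,
                             node_labels=list(node_labels))


@dataclass
class Embedding:
    """Node coordinates ``Psi(t)`` over retained non-trivial dimensions."""

    coords: np.ndarray
    t: object                     # int diffusion time or "multiscale"
    k_infl: int
    spectrum: np.ndarray          # all eigenvalues, |.| descending
    basis: np.ndarray             # Psymm eigenvectors of retained dims
    node_labels: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]


def select_dimensions(spectrum) -> tuple[int, int]:
    """Elbow of the sorted eigenvalue-magnitude curve (kneedle-style).

    The curve is normalized to the unit square and the knee is the index
    of maximum vertical distance below the chord joining its endpoints.
    Returns ``(k_infl, k)`` with ``k = max(k_infl - 1, 1)`` retained
    dimensions.  A flat spectrum has no knee; falls back to ``k = 2`` with
    a warning.
    """
    s = np.abs(np.asarray(spectrum, dtype=float))
    m = len(s)
    if m < 4:
        raise ValueError("need >= 4 eigenvalues to locate an elbow")
    if s[0] - s[-1] <= 1e-12:
        warnings.warn("flat eigenvalue spectrum; falling back to k = 2")
        return 3, 2
    x = np.linspace(0.0, 1.0, m)
    y = (s - s[-1]) / (s[0] - s[-1])
    chord = 1.0 - x
    gap = chord - y
    k_infl = int(np.argmax(gap)) + 1          # 1-based index
    return k_infl, max(k_infl - 1, 1)


def _resolve_k(op: DiffusionOperator, k) -> tuple[int, int]:
    if k == "auto" or k is None:
        k_infl, kk = select_dimensions(op.eigvals)
        kk = min(kk, op.n_nodes - 1)
        return k_infl, kk
    kk = int(k)
    if kk >= op.n_nodes:
        raise ValueError(f"k={kk} must be < n={op.n_nodes}")
    return kk + 1, kk


def diffusion_map(op: DiffusionOperator, t: int = 1, k="auto") -> Embedding:
    """Embedding with coordinate ``j`` equal to ``lambda_j^t psi_j``.

    The trivial constant eigenvector (``lambda = 1``) is dropped before
    dimensions are indexed; with ``k = n - 1`` (all non-trivial
    dimensions), pairwise Euclidean distances equal t-step diffusion
    distances.
    """
    if t < 0 or int(t) != t:
        raise ValueError("t must be a nonnegative integer")
    k_infl, kk = _resolve_k(op, k)
    lam = op.eigvals[1:kk + 1]
    coords = (lam ** int(t))[None, :] * op.psi[:, 1:kk + 1]
    return Embedding(coords=coords, t=int(t), k_infl=k_infl,
                     spectrum=op.eigvals.copy(),
                     basis=op.eigvecs[:, 1:kk + 1].copy(),
                     node_labels=list(op.node_labels))


def multiscale_diffusion_map(op: DiffusionOperator, k="auto") -> Embedding:
    """Embedding aggregating all diffusion times: coordinate scaling
    ``lambda_j / (1 - lambda_j)`` (the geometric sum of ``lambda^t`` over
    ``t = 1..inf``), removing the dependence on a single ``t``."""
    k_infl, kk = _resolve_k(op, k)
    lam = op.eigvals[1:kk + 1]
    if np.any(np.abs(lam) >= 1.0 - 1e-12):
        raise ValueError("|lambda| = 1 in a retained dimension "
                         "(disconnected graph?)")
    scale = lam / (1.0 - lam)
    coords = scale[None, :] * op.psi[:, 1:kk + 1]
    return Embedding(coords=coords, t="multiscale", k_infl=k_infl,
                     spectrum=op.eigvals.copy(),
                     basis=op.eigvecs[:, 1:kk + 1].copy(),
                     node_labels=list(op.node_labels))


def change_of_basis(target: Embedding,
                    reference: DiffusionOperator) -> Embedding:
    """Express a target embedding in a reference operator's eigenbasis.

    The overlap of the target's retained eigenvectors with the reference's
    is orthogonalized to its nearest rotation (polar factor), which is then
    applied in coordinate space.  This aligns eigenvector sign flips and
    rotations within near-degenerate eigenspaces across embeddings of the
    same node set, is an exact isometry (pairwise distances are preserved),
    and is the identity when the target equals the reference.
    """
    if target.n_nodes != reference.n_nodes:
        raise ValueError("target and reference node sets differ")
    if list(target.node_labels) != list(reference.node_labels):
        raise ValueError("node labels/ordering differ between target "
                         "and reference")
    kk = target.k
    v_ref = reference.eigvecs[:, 1:kk + 1]
    overlap = v_ref.T @ target.basis
    u, _, wt = np.linalg.svd(overlap)
    rot = u @ wt
    coords = target.coords @ rot.T
    return Embedding(coords=coords, t=target.t, k_infl=target.k_infl,
                     spectrum=target.spectrum.copy(), basis=v_ref.copy(),
                     node_labels=list(target.node_labels))


def embedding_distances(emb: Embedding) -> np.ndarray:
    """Pairwise Euclidean distances over retained dimensions."""
    return squareform(pdist(emb.coords))


def diffusion_distance_direct(op: DiffusionOperator, t: int) -> np.ndarray:
    """Brute-force diffusion distances via explicit matrix powers.

    ``D_t^2(i, k) = sum_j (P^t[i, j] - P^t[k, j])^2 / pi_j`` with ``pi``
    the degree-normalized stationary distribution.  Intended as an oracle
    for small graphs.
    """
    pt = np.linalg.matrix_power(op.P, int(t))
    pi = op.stationary
    x = pt / np.sqrt(pi)[None, :]
    return squareform(pdist(x))


def compare_embeddings(dist_a: np.ndarray, dist_b: np.ndarray) -> float:
    """Pearson r between the upper triangles of two distance matrices."""
    dist_a = np.asarray(dist_a, dtype=float)
    dist_b = np.asarray(dist_b, dtype=float)
    if dist_a.shape != dist_b.shape:
        raise ValueError("distance matrices differ in shape")
    n = dist_a.shape[0]
    if n < 4:
        raise ValueError("need >= 4 nodes (>= 6 pairs) to correlate")
    iu = np.triu_indices(n, k=1)
    return float(np.corrcoef(dist_a[iu], dist_b[iu])[0, 1])


def embed_connectivity(conn: ConnectivityMatrix, fraction: float = 1.0 / 3.0,
                       t: int = 1, k="auto", multiscale: bool = False,
                       include_self: bool = False
                       ) -> tuple[DiffusionOperator, Embedding]:
    """Threshold -> cosine kernel -> diffusion operator -> embedding."""
    thr = threshold_connectivity(conn, fraction=fraction)
    kern = cosine_similarity_matrix(thr, include_self=include_self)
    op = build_diffusion_operator(kern, node_labels=conn.node_labels)
    emb = (multiscale_diffusion_map(op, k=k) if multiscale
           else diffusion_map(op, t=t, k=k))
    return op, emb
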