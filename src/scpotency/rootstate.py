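"""Root-state and root-cell identification for lineage-trajectory inference.

Trajectory and pseudotime methods need an anchor: the most potent cell state.
CCAT provides it without prior marker knowledge. The procedure: select the
top 5% of cells by CCAT; embed cells with a diffusion map; cluster the
selected cells along ALL diffusion components with the walktrap
community-detection algorithm (random-walk length ~25% of the selected cell
count); the root state is the largest cluster and the root cell its median
(medoid) member. Diffusion pseudotime (DPT) from the root cell then orders
cells along the differentiation trajectory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class DiffusionEmbedding:
    """Cells embedded along diffusion components (DCs).

    ``components`` holds the non-trivial eigenvectors of the diffusion
    operator scaled by their eigenvalues (N x m, one DC per column);
    ``eigenvalues`` are the matching eigenvalues, sorted descending, each in
    (-1, 1]; the trivial constant eigenvector is excluded.
    """

    cell_ids: list[str]
    components: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        n, m = self.components.shape
        if len(self.cell_ids) != n or self.eigenvalues.size != m:
            raise ValueError("components, cell_ids and eigenvalues are inconsistent")
        if (np.diff(self.eigenvalues) > 1e-12).any():
            raise ValueError("eigenvalues must be sorted in non-increasing order")

    def coords(self, cell_ids) -> np.ndarray:
        idx = pd.Index(self.cell_ids)
        pos = idx.get_indexer(list(cell_ids))
        if (pos < 0).any():
            raise KeyError("some requested cells are absent from the embedding")
        return self.components[pos]


@dataclass
class RootStateResult:
    """Outcome of root-state identification.

    ``selected_cells`` is the high-CCAT subset (top q fraction),
    ``cluster_assignment`` its walktrap partition, ``root_state`` the largest
    cluster's cell ids and ``root_cell`` the medoid of that cluster in DC
    space. ``walk_length`` records the walktrap random-walk length used.
    """

    selected_cells: list[str]
    cluster_assignment: pd.Series
    root_state: list[str]
    root_cell: str
    walk_length: int


def select_top_cells(ccat_scores: pd.Series, q: float = 0.05) -> list[str]:
    """The floor(q*N) cells with highest CCAT (clamped to at least one).

    Ties at the selection boundary are broken by cell-id order. With fewer
    than 20 cells at the default q the floor would be zero; it is clamped to
    1 with a warning.
    """
    if len(ccat_scores) == 0:
        raise ValueError("empty score vector")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    scores = ccat_scores.dropna()
    n_sel = int(np.floor(q * len(ccat_scores)))
    if n_sel < 1:
        warnings.warn(
            f"floor({q} * {len(ccat_scores)}) = 0 selected cells; clamping to 1",
            stacklevel=2,
        )
        n_sel = 1
    if scores.nunique() == 1:
        warnings.warn("all CCAT values equal; selection falls back to cell-id order", stacklevel=2)
    # sort by (-score, cell id): deterministic under ties
    order = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [cid for cid, _ in order[:n_sel]]


def diffusion_map(
    expr,
    n_components: int = 15,
    kappa: int = 30,
) -> DiffusionEmbedding:
    """Diffusion-map embedding of cells from a log-normalized matrix.

    A Gaussian kernel with per-cell adaptive bandwidth (the distance to the
    kappa-th nearest neighbor; kappa defaults to 30 or N/3 if smaller) is
    symmetrically normalized and eigendecomposed. The returned DCs are the
    non-trivial eigenvectors of the diffusion operator scaled by their
    eigenvalues; eigenvector signs are fixed by making the largest-magnitude
    loading positive, so the embedding is deterministic.
    """
    if expr.n_cells < 3:
        raise ValueError("diffusion map needs at least 3 cells")
    X = expr.values.T  # cells x genes
    n = X.shape[0]
    D = squareform(pdist(X))
    if not D.any():
        raise ValueError("all cells are identical; no geometry to embed")
    kap = min(kappa, max(1, n // 3))
    # distance to the kap-th neighbor (excluding self at distance 0)
    sigma = np.sort(D, axis=1)[:, min(kap, n - 1)]
    sigma = np.maximum(sigma, 1e-12 * D.max())
    K = np.exp(-(D**2) / (sigma[:, None] * sigma[None, :]))
    q = K.sum(axis=1)
    M = K / np.sqrt(q[:, None] * q[None, :])
    m = min(n_components, n - 1)
    w, phi = eigh(M, subset_by_index=(n - 1 - m, n - 1))
    w, phi = w[::-1], phi[:, ::-1]  # descending
    psi = phi / np.sqrt(q)[:, None]  # right eigenvectors of the random walk
    # drop the trivial lambda=1 constant eigenvector
    w, psi = w[1:], psi[:, 1:]
    # fix signs: largest-|loading| entry positive
    for j in range(psi.shape[1]):
        i = np.argmax(np.abs(psi[:, j]))
        if psi[i, j] < 0:
            psi[:, j] = -psi[:, j]
    comps = psi * w[np.newaxis, :]
    return DiffusionEmbedding(
        cell_ids=list(expr.cell_ids), components=comps, eigenvalues=w
    )


def walk_length_rule(n_selected: int) -> int:
    """Walktrap random-walk length: floor(25% of the selected cells), >= 1."""
    if n_selected < 1:
        raise ValueError("n_selected must be >= 1")
    return max(1, int(np.floor(0.25 * n_selected)))


def walktrap_cluster(
    points: np.ndarray, walk_length: int, knn: int | None = None
) -> np.ndarray:
    """Walktrap community detection on a symmetric kNN graph of the points.

    The graph uses Euclidean distances; communities come from the
    Pons-Latapy short-random-walk agglomeration with the dendrogram cut at
    maximum modularity. Disconnected kNN graphs are clustered per component
    (with a warning); the result is deterministic given identical inputs.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    n = P.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points to cluster")
    if walk_length < 1:
        raise ValueError("walk_length must be >= 1")
    if knn is None:
        knn = min(10, n - 1)
    knn = min(knn, n - 1)
    nn = NearestNeighbors(n_neighbors=knn + 1).fit(P)
    _, idx = nn.kneighbors(P)
    edges = {tuple(sorted((i, int(j)))) for i in range(n) for j in idx[i, 1:]}
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    labels = np.full(n, -1, dtype=int)
    comps = g.connected_components()
    if len(comps) > 1:
        logger.warning(
            "kNN graph has %d components; clustering each separately", len(comps)
        )
    offset = 0
    for comp in comps:
        if len(comp) == 1:
            labels[comp[0]] = offset
            offset += 1
            continue
        sub = g.induced_subgraph(comp)
        dendro = sub.community_walktrap(steps=walk_length)
        membership = dendro.as_clustering().membership
        for node, m in zip(comp, membership):
            labels[node] = offset + m
        offset += max(membership) + 1
    return labels


def identify_root(
    ccat_scores: pd.Series,
    embedding: DiffusionEmbedding,
    q: float = 0.05,
    knn: int | None = None,
) -> RootStateResult:
    """Select the top-q CCAT cells, cluster them in DC space, return the root.

    The root state is the largest walktrap cluster (ties broken by higher
    mean CCAT, then cell-id order); the root cell is the medoid of the root
    state in diffusion-component space — the member minimizing the summed
    Euclidean distance to the other members (ties by cell-id order).
    """
    selected = select_top_cells(ccat_scores, q=q)
    if len(selected) == 1:
        only = selected[0]
        return RootStateResult(
            selected_cells=selected,
            cluster_assignment=pd.Series([0], index=selected, name="cluster"),
            root_state=selected,
            root_cell=only,
            walk_length=walk_length_rule(1),
        )
    coords = embedding.coords(selected)  # ALL diffusion components
    wl = walk_length_rule(len(selected))
    labels = walktrap_cluster(coords, walk_length=wl, knn=knn)
    assignment = pd.Series(labels, index=selected, name="cluster")
    sizes = assignment.value_counts()
    top_size = sizes.max()
    candidates = sorted(sizes[sizes == top_size].index)
    if len(candidates) > 1:
        mean_ccat = {
            c: ccat_scores[assignment.index[assignment == c]].mean() for c in candidates
        }
        best = max(candidates, key=lambda c: (mean_ccat[c], -candidates.index(c)))
    else:
        best = candidates[0]
    root_state = sorted(assignment.index[assignment == best])
    pts = embedding.coords(root_state)
    if len(root_state) == 1:
        root_cell = root_state[0]
    else:
        dist = squareform(pdist(pts))
        total = dist.sum(axis=1)
        root_cell = root_state[int(np.lexsort((np.array(root_state), total))[0])]
    return RootStateResult(
        selected_cells=selected,
        cluster_assignment=assignment,
        root_state=root_state,
        root_cell=root_cell,
        walk_length=wl,
    )


def diffusion_pseudotime(embedding: DiffusionEmbedding, root_cell: str) -> pd.Series:
    """Diffusion distance of every cell to the root cell (DPT).

    Computed from the spectral representation of the diffusion operator:
    dpt(c)^2 = sum_l (lambda_l / (1 - lambda_l))^2 (psi_lc - psi_l,root)^2,
    over the non-trivial components. Zero at the root, non-negative
    everywhere.
    """
    lam = embedding.eigenvalues
    if (lam >= 1 - 1e-10).any():
        raise ValueError(
            "a non-trivial eigenvalue equals 1: the kernel graph is disconnected"
        )
    psi = embedding.components / lam[np.newaxis, :]
    root = embedding.coords([root_cell]) / lam[np.newaxis, :]
    scale = lam / (1 - lam)
    diff = (psi - root) * scale[np.newaxis, :]
    dpt = np.sqrt((diff**2).sum(axis=1))
    return pd.Series(dpt, index=embedding.cell_ids, name="dpt")
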