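"""Protein-protein interaction (PPI) connectome construction and filtering.

The potency measures in :mod:`scpotency.potency` need a connected, undirected,
unweighted PPI graph over named genes: the adjacency matrix ``A`` supplies the
diffusion topology and its row sums give the degree (connectivity) vector ``k``
— the "connectome" that CCAT correlates with each cell's transcriptome.

Construction follows the standard pipeline for PPI resources such as Pathway
Commons or STRING: load a raw edge list, optionally drop biologically
implausible extracellular-intracellular interactions using per-protein
cellular-localization annotations, and keep the maximally connected component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

#: Allowed cellular-localization labels for the edge filter.
LOCALIZATION_DOMAINS = ("extracellular", "membrane", "intracellular")


@dataclass
class EdgeList:
    """A deduplicated, self-loop-free set of undirected gene-gene interactions.

    Parameters
    ----------
    edges
        Unordered gene pairs stored as sorted 2-tuples, one per interaction.
    node_ids
        Every gene identifier appearing in ``edges`` (sorted, unique).
    """

    edges: list[tuple[str, str]]
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        canon = {tuple(sorted(e)) for e in self.edges if e[0] != e[1]}
        self.edges = sorted(canon)
        in_edges = sorted({g for e in self.edges for g in e})
        if not self.node_ids:
            self.node_ids = in_edges
        else:
            missing = set(in_edges) - set(self.node_ids)
            if missing:
                raise ValueError(f"edges reference genes absent from node_ids: {sorted(missing)[:5]}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class PPINetwork:
    """A connected, undirected, binary PPI graph.

    ``adjacency`` is a symmetric sparse CSR matrix with zero diagonal;
    ``node_ids`` fixes the row/column order. The graph is guaranteed connected
    with at least two nodes, so every degree is >= 1.
    """

    node_ids: list[str]
    adjacency: sp.csr_matrix

    def __post_init__(self) -> None:
        A = sp.csr_matrix(self.adjacency)
        G = len(self.node_ids)
        if A.shape != (G, G):
            raise ValueError(f"adjacency shape {A.shape} does not match {G} node ids")
        if G < 2:
            raise ValueError("a PPI network needs at least 2 genes")
        if A.diagonal().any():
            raise ValueError("adjacency has non-zero diagonal (self-interactions)")
        if (A != A.T).nnz:
            raise ValueError("adjacency is not symmetric")
        ncomp, _ = connected_components(A, directed=False)
        if ncomp != 1:
            raise ValueError(f"adjacency is not connected ({ncomp} components)")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def degrees(self) -> np.ndarray:
        """Integer degree vector k, aligned with ``node_ids``."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)


def load_edge_list(path, fmt: str = "tsv") -> EdgeList:
    """Read an undirected edge list from a 2-column TSV or a SIF file.

    Duplicate unordered pairs and self-loops are dropped (and counted in the
    log). SIF lines are ``geneA<sep>interaction-type<sep>geneB`` with tab or
    whitespace separation; TSV lines are ``geneA\\tgeneB``.
    """
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format {fmt!r}; use 'tsv' or 'sif'")
    raw_pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fmt == "tsv":
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
                a, b = fields
            else:
                if len(fields) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 SIF columns, got {len(fields)}")
                a, _, b = fields
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty gene identifier")
            raw_pairs.append((a, b))
    if not raw_pairs:
        raise ValueError(f"{path}: no edges found")
    n_self = sum(a == b for a, b in raw_pairs)
    canon = {tuple(sorted(p)) for p in raw_pairs if p[0] != p[1]}
    n_dup = len(raw_pairs) - n_self - len(canon)
    if n_self or n_dup:
        logger.info("load_edge_list: dropped %d self-loops and %d duplicate pairs", n_self, n_dup)
    if not canon:
        raise ValueError(f"{path}: no edges left after removing self-loops")
    return EdgeList(edges=sorted(canon))


def load_localization(path) -> dict[str, str]:
    """Read a 2-column TSV mapping gene id -> cellular domain.

    Domain labels must come from ``extracellular``, ``membrane``,
    ``intracellular`` (case-insensitive in the file, normalized to lowercase).
    """
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns (gene, domain)")
            gene, dom = fields[0], fields[1].strip().lower()
            if dom not in LOCALIZATION_DOMAINS:
                raise ValueError(
                    f"{path}:{lineno}: domain {dom!r} not in {LOCALIZATION_DOMAINS}"
                )
            table[gene] = dom
    return table


def filter_by_localization(el: EdgeList, loc: dict[str, str]) -> EdgeList:
    """Drop extracellular-intracellular interactions.

    Only the extracellular x intracellular pairing is removed; membrane
    proteins and genes absent from the annotation table keep all their edges.
    Idempotent, never adds edges.
    """
    bad = {"extracellular", "intracellular"}
    kept = [
        (a, b)
        for a, b in el.edges
        if {loc.get(a), loc.get(b)} != bad
    ]
    n_drop = el.n_edges - len(kept)
    if n_drop:
        logger.info("filter_by_localization: removed %d extracellular-intracellular edges", n_drop)
    return EdgeList(edges=kept)


def _components(el: EdgeList) -> list[list[str]]:
    nodes = el.node_ids
    idx = {g: i for i, g in enumerate(nodes)}
    rows = [idx[a] for a, b in el.edges]
    cols = [idx[b] for a, b in el.edges]
    n = len(nodes)
    A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    ncomp, labels = connected_components(A, directed=False)
    comps: list[list[str]] = [[] for _ in range(ncomp)]
    for g, lab in zip(nodes, labels):
        comps[lab].append(g)
    return [sorted(c) for c in comps]


def max_connected_component(el: EdgeList) -> PPINetwork:
    """Extract the maximally connected component as a :class:`PPINetwork`.

    Size ties are broken by the lexicographically smallest sorted node list,
    so the result is deterministic.
    """
    if not el.edges:
        raise ValueError("cannot extract a component from an empty edge list")
    comps = sorted(_components(el), key=lambda c: (-len(c), c))
    keep = set(comps[0])
    node_ids = comps[0]
    idx = {g: i for i, g in enumerate(node_ids)}
    pairs = [(idx[a], idx[b]) for a, b in el.edges if a in keep and b in keep]
    rows = [i for i, j in pairs] + [j for i, j in pairs]
    cols = [j for i, j in pairs] + [i for i, j in pairs]
    n = len(node_ids)
    A = sp.coo_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)).tocsr()
    return PPINetwork(node_ids=node_ids, adjacency=A)


def intersect_with_genes(net: PPINetwork, genes) -> PPINetwork:
    """Induce the subgraph on ``genes`` and re-extract the largest component.

    Used to integrate the connectome with the gene universe of an expression
    matrix: degrees are recomputed on the surviving subnetwork. Matching is
    exact and case-sensitive.
    """
    keep = set(genes) & set(net.node_ids)
    if not keep:
        raise ValueError(
            "no overlap between network genes "
            f"(e.g. {net.node_ids[:3]}) and expression genes (e.g. {list(genes)[:3]})"
        )
    mask = np.array([g in keep for g in net.node_ids])
    sub = net.adjacency[mask][:, mask].tocoo()
    sub_ids = [g for g, m in zip(net.node_ids, mask) if m]
    edges = [
        (sub_ids[i], sub_ids[j]) for i, j in zip(sub.row, sub.col) if i < j
    ]
    if not edges:
        raise ValueError("gene overlap leaves no interactions (isolated genes only)")
    return max_connected_component(EdgeList(edges=edges))


def degree_vector(net: PPINetwork) -> np.ndarray:
    """Degree vector k (row sums of the adjacency); every entry >= 1."""
    return net.degrees


def network_density(net: PPINetwork) -> float:
    """Edge density E / (G(G-1)/2), in (0, 1]."""
    return density_from_counts(net.n_nodes, net.n_edges)


def density_from_counts(n_nodes: int, n_edges: int) -> float:
    """Density of an undirected simple graph with the given node/edge counts."""
    if n_nodes < 2:
        raise ValueError("density needs at least 2 nodes")
    return n_edges / (n_nodes * (n_nodes - 1) / 2)


def load_toy_network() -> PPINetwork:
    """The packaged 200-node scale-free toy connectome (synthetic).

    Generated once by the synthetic module (preferential attachment,
    200 nodes, 3 edges per node) and shipped as a TSV edge list for examples
    and quick starts.
    """
    from importlib.resources import as_file, files

    path = files("scpotency.data").joinpath("toy_network.tsv")
    with as_file(path) as p:
        return max_connected_component(load_edge_list(p, fmt="tsv"))
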