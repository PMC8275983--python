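"""Single-cell differentiation-potency measures.

The central quantity is the entropy rate SR of an expression-modulated random
walk on a PPI graph. For one cell with strictly positive expression vector
x over the G network genes, the walk's transition matrix is

    P_ij = A_ij x_j / sum_k A_ik x_k,

i.e. signaling flux from gene i is distributed to its neighbors j in
proportion to their expression. The chain is reversible with closed-form
invariant measure

    pi_i = x_i (A x)_i / (x^T A x),

and the entropy rate is SR = sum_i pi_i S_i with local node entropies
S_i = -sum_j P_ij log P_ij. High-potency cells overexpress network hubs,
which lets the walk spread efficiently and raises SR.

CCAT short-circuits all of this: under a mean-field approximation
(A x)_i ~ k_i and a narrow dynamic range of the S_i, SR reduces (up to
scaling) to the alignment of transcriptome and connectome, measured as

    CCAT = PearsonCorrelation(x, k)  in [-1, 1].

A single correlation per cell, hence orders of magnitude faster than SR while
remaining a positively correlated proxy on hub-dominated PPI-like networks.

Also provided are the standard comparator measures: detected-gene count, the
gene-count signature (GCS), whole-transcriptome Shannon entropy (the StemID
statistic) and top-1000-gene Shannon entropy (cmEntropy). All entropies are
in nats.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import PPINetwork
from .preprocess import ExpressionMatrix, normalize_log

logger = logging.getLogger(__name__)

#: All per-cell measures score_all understands.
ALL_MEASURES = (
    "ccat",
    "sr",
    "sr_approx",
    "gene_count",
    "gcs",
    "stemid_entropy",
    "cm_entropy",
)


@dataclass
class DiffusionChain:
    """The expression-modulated random walk of one cell on the PPI graph.

    Attributes
    ----------
    P
        Row-stochastic transition matrix (sparse, support = adjacency).
    pi
        Invariant measure; satisfies ``pi @ P == pi`` and detailed balance
        ``pi_i P_ij == pi_j P_ji``.
    S
        Local node entropies S_i = -sum_j P_ij log P_ij, in nats.
    """

    P: sp.csr_matrix
    pi: np.ndarray
    S: np.ndarray


def _check_x(x: np.ndarray, net: PPINetwork) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size != net.n_nodes:
        raise ValueError(f"x has {x.size} entries for a {net.n_nodes}-gene network")
    if (x <= 0).any():
        raise ValueError(
            "expression vector must be strictly positive; normalize counts with "
            "the 1.1 pseudocount (normalize_log) before computing the diffusion chain"
        )
    return x


def diffusion_chain(x: np.ndarray, net: PPINetwork) -> DiffusionChain:
    """Build P, pi and the local entropies S for one cell."""
    x = _check_x(x, net)
    A = net.adjacency
    W = A.multiply(x[np.newaxis, :]).tocsr()  # w_ij = A_ij x_j
    Ax = np.asarray(W.sum(axis=1)).ravel()  # (A x)_i, > 0 since connected
    P = W.multiply(1.0 / Ax[:, np.newaxis]).tocsr()
    plogp = P.copy()
    plogp.data = P.data * np.log(P.data)
    S = -np.asarray(plogp.sum(axis=1)).ravel()
    S = np.maximum(S, 0.0)  # clip -0.0 from degree-1 nodes
    pi = x * Ax / float(x @ Ax)
    return DiffusionChain(P=P, pi=pi, S=S)


def transition_matrix(x: np.ndarray, net: PPINetwork) -> sp.csr_matrix:
    """Row-stochastic P with P_ij = A_ij x_j / sum_k A_ik x_k."""
    return diffusion_chain(x, net).P


def invariant_measure(x: np.ndarray, net: PPINetwork) -> np.ndarray:
    """Stationary distribution pi_i = x_i (A x)_i / x^T A x."""
    return diffusion_chain(x, net).pi


def entropy_rate(x: np.ndarray, net: PPINetwork) -> float:
    """Entropy rate SR = -sum_ij pi_i P_ij log P_ij, in nats.

    Invariant to positive rescaling of x; bounded by log of the largest
    adjacency eigenvalue (the topological entropy of the graph).
    """
    chain = diffusion_chain(x, net)
    return float(chain.pi @ chain.S)


def sr_approximation(x: np.ndarray, net: PPINetwork) -> float:
    """Mean-field 3-way proxy sum_i x_i k_i S_i for the entropy rate.

    Replaces (A x)_i by the degree k_i in the invariant measure; returned
    without any normalizing constant, so only its ordering across cells is
    meaningful. Diagnostic only — CCAT is the measure used downstream.
    """
    chain = diffusion_chain(x, net)
    k = net.degrees.astype(float)
    x = np.asarray(x, dtype=float).ravel()
    return float(np.sum(x * k * chain.S))


def ccat(x: np.ndarray, k: np.ndarray) -> float:
    """Correlation of Connectome And Transcriptome: Pearson corr of x with k.

    Returns NaN (with a warning) when x has zero variance — a constant
    profile carries no potency signal and must not masquerade as CCAT = 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    k = np.asarray(k, dtype=float).ravel()
    if x.size != k.size:
        raise ValueError("x and k must have equal length")
    if x.size < 3:
        raise ValueError("CCAT needs at least 3 genes")
    xs = x.std()
    ks = k.std()
    if ks == 0:
        raise ValueError("degree vector is constant; connectome carries no signal")
    if xs == 0:
        warnings.warn("constant expression profile: CCAT undefined, returning NaN", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, k)[0, 1])


def ccat_matrix(values: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Vectorized CCAT for a genes x cells matrix: one Pearson corr per column."""
    X = np.asarray(values, dtype=float)
    k = np.asarray(k, dtype=float).ravel()
    if X.shape[0] != k.size:
        raise ValueError("matrix rows and degree vector must align")
    G = k.size
    kc = k - k.mean()
    knorm = np.linalg.norm(kc)
    if knorm == 0:
        raise ValueError("degree vector is constant")
    num = kc @ X  # column means of X drop out since kc sums to 0
    xnorm = np.sqrt(np.maximum((X * X).sum(axis=0) - G * X.mean(axis=0) ** 2, 0.0))
    out = np.full(X.shape[1], np.nan)
    ok = xnorm > 0
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} constant cell profiles: CCAT set to NaN", stacklevel=2
        )
    out[ok] = num[ok] / (xnorm[ok] * knorm)
    return np.clip(out, -1.0, 1.0, out=out)


def gene_count(raw_counts: np.ndarray) -> int:
    """Number of detected genes: entries > 0 in one cell's raw count vector."""
    c = np.asarray(raw_counts)
    if (c < 0).any():
        raise ValueError("gene_count expects raw (non-negative) counts")
    return int(np.count_nonzero(c))


def _gene_counts_per_cell(counts: ExpressionMatrix) -> np.ndarray:
    if counts.layer != "counts":
        raise ValueError("detected-gene counting needs the counts layer (pre-pseudocount)")
    return np.count_nonzero(counts.values > 0, axis=0)


def gcs(
    counts: ExpressionMatrix,
    n_top: int = 200,
    use_lognorm: bool = True,
    base: float = 2,
) -> np.ndarray:
    """Gene-count signature: per-cell geometric mean of the genes most
    correlated with the number of detected genes.

    Per gene, the Pearson correlation across cells between its expression
    (log-normalized by default) and the per-cell detected-gene count is
    computed for this dataset; the ``n_top`` most correlated genes are
    selected (ties by gene input order, constant genes scored 0) and the cell
    score is the geometric mean of their log-normalized expression.
    """
    if counts.n_cells < 3:
        raise ValueError("GCS needs at least 3 cells to correlate against gene counts")
    gc = _gene_counts_per_cell(counts).astype(float)
    expr = normalize_log(counts, base=base) if use_lognorm else counts
    X = expr.values
    if n_top > X.shape[0]:
        warnings.warn(
            f"n_top={n_top} exceeds {X.shape[0]} genes; using all genes", stacklevel=2
        )
        n_top = X.shape[0]
    gcc = gc - gc.mean()
    gnorm = np.linalg.norm(gcc)
    Xc = X - X.mean(axis=1, keepdims=True)
    xnorm = np.linalg.norm(Xc, axis=1)
    corr = np.zeros(X.shape[0])
    ok = (xnorm > 0) & (gnorm > 0)
    corr[ok] = (Xc[ok] @ gcc) / (xnorm[ok] * gnorm)
    top = np.argsort(-corr, kind="stable")[:n_top]  # stable: ties by gene order
    sel = expr.values[top, :]
    if (sel <= 0).any():
        raise ValueError("GCS geometric mean needs strictly positive expression values")
    return np.exp(np.mean(np.log(sel), axis=0))


def stemid_entropy(raw_counts: np.ndarray) -> float:
    """Shannon entropy (nats) of one cell's read-count distribution over genes.

    Measures how uniformly reads are spread: log(G) for perfectly uniform,
    0 when a single gene absorbs all reads, NaN for an empty cell.
    """
    c = np.asarray(raw_counts, dtype=float).ravel()
    if (c < 0).any():
        raise ValueError("stemid_entropy expects raw (non-negative) counts")
    total = c.sum()
    if total == 0:
        warnings.warn("all-zero cell: transcriptome entropy undefined", stacklevel=2)
        return float("nan")
    q = c[c > 0] / total
    return float(-(q * np.log(q)).sum())


def cm_entropy(raw_counts: np.ndarray, n_top: int = 1000) -> float:
    """Shannon entropy (nats) restricted to the cell's top-n most expressed genes.

    The count vector is cut to its ``n_top`` largest entries (ties by gene
    order), renormalized, and passed to the Shannon entropy. Cells expressing
    fewer than ``n_top`` genes reduce to the whole-transcriptome entropy.
    """
    c = np.asarray(raw_counts, dtype=float).ravel()
    if (c < 0).any():
        raise ValueError("cm_entropy expects raw (non-negative) counts")
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    top = np.argsort(-c, kind="stable")[:n_top]
    return stemid_entropy(c[top])


def score_all(
    expr: ExpressionMatrix,
    net: PPINetwork | None = None,
    measures=("ccat",),
    base: float = 2,
    gcs_n_top: int = 200,
    cm_n_top: int = 1000,
) -> pd.DataFrame:
    """Score every cell with the requested potency measures.

    ``expr`` is a counts-layer matrix over the full gene space. Count-based
    measures (gene_count, gcs, stemid_entropy, cm_entropy) use that full
    space; network-based measures (ccat, sr, sr_approx) log-normalize and
    match the matrix to the connectome first. Per-cell failures propagate as
    NaN without aborting the batch.

    Returns a cells x measures DataFrame indexed by cell id.
    """
    from .preprocess import match_genes  # local import to avoid cycle at module load

    measures = list(measures)
    unknown = set(measures) - set(ALL_MEASURES)
    if unknown:
        raise ValueError(f"unknown measures {sorted(unknown)}; choose from {ALL_MEASURES}")
    if expr.layer != "counts":
        raise ValueError("score_all expects the counts layer (it normalizes internally)")
    network_measures = [m for m in measures if m in ("ccat", "sr", "sr_approx")]
    if network_measures and net is None:
        raise ValueError(f"measures {network_measures} need a PPI network")

    out = pd.DataFrame(index=pd.Index(expr.cell_ids, name="cell_id"))
    if network_measures:
        lognorm = normalize_log(expr, base=base)
        matched, subnet = match_genes(lognorm, net)
        X = matched.values
        k = subnet.degrees
        if "ccat" in measures:
            out["ccat"] = ccat_matrix(X, k)
        if "sr" in measures or "sr_approx" in measures:
            sr_vals = np.empty(X.shape[1])
            approx_vals = np.empty(X.shape[1])
            for j in range(X.shape[1]):
                chain = diffusion_chain(X[:, j], subnet)
                sr_vals[j] = chain.pi @ chain.S
                approx_vals[j] = np.sum(X[:, j] * k * chain.S)
            if "sr" in measures:
                out["sr"] = sr_vals
            if "sr_approx" in measures:
                out["sr_approx"] = approx_vals
    if "gene_count" in measures:
        out["gene_count"] = _gene_counts_per_cell(expr)
    if "gcs" in measures:
        out["gcs"] = gcs(expr, n_top=gcs_n_top, base=base)
    if "stemid_entropy" in measures or "cm_entropy" in measures:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty cells yield NaN sentinels
            if "stemid_entropy" in measures:
                out["stemid_entropy"] = [
                    stemid_entropy(expr.values[:, j]) for j in range(expr.n_cells)
                ]
            if "cm_entropy" in measures:
                out["cm_entropy"] = [
                    cm_entropy(expr.values[:, j], n_top=cm_n_top)
                    for j in range(expr.n_cells)
                ]
        n_bad = int(out.filter(["stemid_entropy", "cm_entropy"]).isna().any(axis=1).sum())
        if n_bad:
            warnings.warn(f"{n_bad} all-zero cells scored NaN on entropy measures", stacklevel=2)
    return out[measures]
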