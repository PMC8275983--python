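"""Normalization of scRNA-Seq count matrices and alignment to the connectome.

The diffusion process behind the entropy rate divides by sums of expression
values, so the normalized matrix must be strictly positive everywhere. The
``log(counts + 1.1)`` transform guarantees this: its minimum, log(1.1), is
above zero, unlike the common ``log1p`` whose minimum is exactly zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import PPINetwork, intersect_with_genes

logger = logging.getLogger(__name__)

#: Pseudocount keeping the log-transformed matrix strictly positive.
DEFAULT_PSEUDOCOUNT = 1.1


@dataclass
class ExpressionMatrix:
    """A gene x cell expression matrix with named axes.

    ``layer`` records what the values are: ``"counts"`` for non-negative raw
    (or pre-scaled) counts, ``"lognorm"`` for the strictly positive
    log-transformed matrix that the network-based potency measures consume.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.layer not in ("counts", "lognorm"):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.layer == "counts" and (self.values < 0).any():
            raise ValueError("counts layer contains negative values")
        if self.layer == "lognorm" and (self.values <= 0).any():
            raise ValueError(
                "lognorm layer must be strictly positive; normalize counts with "
                "normalize_log (pseudocount 1.1) rather than log1p"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


def aggregate_duplicate_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Sum rows sharing a gene identifier (counts layer only).

    Summation is linear on counts; on log-transformed data it would silently
    change the meaning of the values, so lognorm input is refused.
    """
    if len(set(expr.gene_ids)) == expr.n_genes:
        return expr
    if expr.layer != "counts":
        raise ValueError("duplicate genes can only be aggregated on the counts layer")
    df = expr.to_frame()
    agg = df.groupby(level=0, sort=False).sum()
    logger.warning(
        "aggregated %d duplicate gene rows by sum", expr.n_genes - agg.shape[0]
    )
    return ExpressionMatrix(
        gene_ids=list(agg.index), cell_ids=expr.cell_ids, values=agg.to_numpy(), layer="counts"
    )


def normalize_log(
    counts: ExpressionMatrix,
    base: float = 2,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    scale_per_cell: bool = False,
    target_sum: float = 1e4,
) -> ExpressionMatrix:
    """log(counts + 1.1) normalization, strictly positive by construction.

    Parameters
    ----------
    base
        Log base, 2 (default) or ``numpy.e``. The entropy rate and CCAT are
        invariant to positive rescaling of the expression vector, so the base
        cannot change any cross-cell ranking.
    pseudocount
        Expert override; values <= 1 lose the strict-positivity guarantee and
        trigger a warning (downstream diffusion operators then reject the
        matrix if zeros remain).
    scale_per_cell
        Optional counts-per-``target_sum`` library-size scaling *before* the
        log transform. Off by default: raw log-counts.
    """
    if counts.layer != "counts":
        raise ValueError("normalize_log expects the counts layer")
    if base not in (2,) and not np.isclose(base, np.e):
        raise ValueError("log base must be 2 or e")
    if pseudocount <= 1.0:
        warnings.warn(
            f"pseudocount {pseudocount} <= 1 does not guarantee a strictly positive "
            "matrix; network-based measures may fail on cells with zeros",
            stacklevel=2,
        )
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
    vals = counts.values
    if scale_per_cell:
        libsize = vals.sum(axis=0)
        if (libsize == 0).any():
            raise ValueError("cells with zero total counts cannot be library-size scaled")
        vals = vals / libsize * target_sum
    out = np.log(vals + pseudocount) / np.log(base)
    layer = "lognorm" if pseudocount > 1.0 else "counts"
    if pseudocount <= 1.0:
        # cannot certify strict positivity; keep permissive layer semantics
        out = np.maximum(out, 0.0)
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        cell_ids=list(counts.cell_ids),
        values=out,
        layer=layer,
    )


def match_genes(
    expr: ExpressionMatrix, net: PPINetwork
) -> tuple[ExpressionMatrix, PPINetwork]:
    """Restrict expression and network to a common, identically ordered gene set.

    The network is intersected with the expression genes and reduced to its
    maximally connected component; the expression matrix is then subset and
    reordered to the surviving network's node order, so that row i of the
    matrix and node i of the graph are the same gene.
    """
    expr = aggregate_duplicate_genes(expr)
    sub = intersect_with_genes(net, expr.gene_ids)
    order = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = [order[g] for g in sub.node_ids]
    matched = ExpressionMatrix(
        gene_ids=list(sub.node_ids),
        cell_ids=list(expr.cell_ids),
        values=expr.values[rows, :],
        layer=expr.layer,
    )
    dropped = expr.n_genes - matched.n_genes
    if dropped:
        logger.info("match_genes: %d expression genes outside the connected subnetwork", dropped)
    return matched, sub
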