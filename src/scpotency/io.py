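"""Readers and writers for the tabular formats the pipeline consumes.

Expression matrices: 10x-style MTX triplets (matrix.mtx with genes/features
and barcodes sidecars, plain or gzipped) and dense CSV/TSV with genes in
rows (a flag flips the orientation). Networks: 2-column TSV or SIF edge
lists. Labels, localization tables and ground truth: 2-column / small TSVs.
All writers emit plain TSV with headers so runs round-trip through files.
"""

from __future__ import annotations

import gzip
import json
import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .network import PPINetwork
from .preprocess import ExpressionMatrix


def _open_maybe_gzip(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _read_sidecar(path) -> list[str]:
    with _open_maybe_gzip(path) as fh:
        out = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            out.append(line.split("\t")[0])
    return out


def read_mtx(matrix_path, genes_path, barcodes_path) -> ExpressionMatrix:
    """Read a 10x-style MTX triplet (genes x cells) as a counts matrix."""
    with _open_maybe_gzip(matrix_path, "rb" if str(matrix_path).endswith(".gz") else "r") as fh:
        m = scipy.io.mmread(fh)
    genes = _read_sidecar(genes_path)
    cells = _read_sidecar(barcodes_path)
    vals = np.asarray(m.todense() if sp.issparse(m) else m, dtype=float)
    if vals.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {vals.shape} does not match {len(genes)} genes x {len(cells)} barcodes"
        )
    return ExpressionMatrix(gene_ids=genes, cell_ids=cells, values=vals, layer="counts")


def read_dense(path, sep: str = "\t", cells_in_rows: bool = False, layer: str = "counts") -> ExpressionMatrix:
    """Read a dense delimited matrix with a header row and id column."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if cells_in_rows:
        df = df.T
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        cell_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        layer=layer,
    )


def write_dense(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    expr.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def write_mtx(expr: ExpressionMatrix, out_dir) -> None:
    """Write a plain (uncompressed) MTX triplet into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    scipy.io.mmwrite(
        os.path.join(out_dir, "matrix.mtx"), sp.coo_matrix(expr.values)
    )
    with open(os.path.join(out_dir, "genes.tsv"), "w") as fh:
        fh.writelines(f"{g}\n" for g in expr.gene_ids)
    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
        fh.writelines(f"{c}\n" for c in expr.cell_ids)


def write_network(net: PPINetwork, path) -> None:
    """Write the network as a 2-column TSV edge list (each edge once)."""
    A = sp.triu(net.adjacency).tocoo()
    with open(path, "w") as fh:
        for i, j in zip(A.row, A.col):
            fh.write(f"{net.node_ids[i]}\t{net.node_ids[j]}\n")


def read_labels(path) -> pd.Series:
    """Read a (cell_id, group) TSV; groups: high/low/intermediate/unlabeled."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns cell_id and group")
    df.columns = ["cell_id", "group", *df.columns[2:]]
    allowed = {"high", "low", "intermediate", "unlabeled"}
    bad = set(df["group"]) - allowed
    if bad:
        raise ValueError(f"{path}: unknown group labels {sorted(bad)}")
    return df.set_index("cell_id")["group"]


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index_label="cell_id", float_format="%.10g")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="cell_id", float_format="%.10g")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
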