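"""Discrimination accuracy, dropout robustness and permutation significance.

Potency measures are evaluated by how well they separate cells of known high
potency from cells of lower potency: the AUC derived from the Wilcoxon
rank-sum (Mann-Whitney) statistic is the probability that a randomly chosen
high-potency cell scores above a randomly chosen low-potency cell.

Robustness analyses: (i) excess-zero dropout injection, which raises the
matrix's zero fraction by a fixed number of percentage points and measures
how strongly per-cell scores before/after correlate; (ii) a Monte-Carlo
degree-permutation test that destroys any transcriptome-connectome
association while exactly preserving the correlation between two connectomes,
isolating the contribution of the expression-degree coupling to the agreement
of CCAT values across PPI networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network import PPINetwork
from .preprocess import ExpressionMatrix
from .potency import ccat_matrix, score_all

#: Above this product of group sizes the Wilcoxon p switches to the
#: tie-corrected normal approximation.
EXACT_WILCOXON_LIMIT = 400


@dataclass
class PermutationNull:
    """Result of a Monte-Carlo permutation test.

    ``p_value`` uses the add-one convention (1 + #{null >= observed}) / (B + 1),
    which can never be zero.
    """

    observed_stat: float
    null_stats: np.ndarray
    p_value: float


def _check_groups(scores_high, scores_low):
    h = np.asarray(scores_high, dtype=float).ravel()
    l = np.asarray(scores_low, dtype=float).ravel()
    if h.size == 0 or l.size == 0:
        raise ValueError("both score groups must be non-empty")
    if np.isnan(h).any() or np.isnan(l).any():
        raise ValueError("scores contain NaN; drop sentinel cells before computing AUC")
    return h, l


def _mann_whitney_u(h: np.ndarray, l: np.ndarray) -> float:
    """U statistic for 'high > low' with ties counting one half."""
    pooled = np.concatenate([h, l])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: h.size].sum()
    return float(r1 - h.size * (h.size + 1) / 2)


def auc_wilcoxon(scores_high, scores_low) -> float:
    """AUC = U / (n1 n2): fraction of (high, low) pairs with high > low, ties = 1/2.

    Invariant under any strictly monotone transform of all scores, and
    complementary: auc(h, l) + auc(l, h) = 1 exactly.
    """
    h, l = _check_groups(scores_high, scores_low)
    return _mann_whitney_u(h, l) / (h.size * l.size)


def wilcoxon_onesided_p(scores_high, scores_low) -> float:
    """One-sided Wilcoxon rank-sum p-value for the alternative 'high > low'.

    Exact Mann-Whitney distribution when there are no ties and
    n1*n2 <= 400; otherwise the normal approximation with tie correction.
    A pooled sample with zero rank variance (all values tied) returns 0.5,
    the symmetric-null convention.
    """
    h, l = _check_groups(scores_high, scores_low)
    n1, n2 = h.size, l.size
    u = _mann_whitney_u(h, l)
    pooled = np.concatenate([h, l])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and n1 * n2 <= EXACT_WILCOXON_LIMIT:
        res = stats.mannwhitneyu(h, l, alternative="greater", method="exact")
        return float(res.pvalue)
    mu = n1 * n2 / 2
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.5
    z = (u - mu) / np.sqrt(var)
    return float(stats.norm.sf(z))


def dropout_inject(
    counts: ExpressionMatrix,
    delta: float,
    seed: int,
    weighted: bool = False,
) -> ExpressionMatrix:
    """Raise the matrix zero fraction by ``delta`` (in absolute fraction units).

    Exactly enough non-zero entries are zeroed, chosen uniformly at random
    under ``seed`` (or, with ``weighted=True``, with probability inversely
    proportional to the count, so lowly expressed transcripts drop first —
    a sensitivity-analysis alternative). Existing zeros are never touched;
    gene and cell identifiers are unchanged.
    """
    if counts.layer != "counts":
        raise ValueError("dropout injection operates on the counts layer")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    vals = counts.values
    size = vals.size
    n_zero = size - np.count_nonzero(vals)
    z0 = n_zero / size
    if z0 + delta > 1 + 1e-12:
        raise ValueError(f"target zero fraction {z0 + delta:.3f} exceeds 1")
    target_zeros = int(round((z0 + delta) * size))
    n_new = max(target_zeros - n_zero, 0)
    out = vals.copy()
    if n_new:
        flat_nonzero = np.flatnonzero(vals)
        rng = np.random.default_rng(seed)
        if weighted:
            w = 1.0 / vals.ravel()[flat_nonzero]
            chosen = rng.choice(flat_nonzero, size=n_new, replace=False, p=w / w.sum())
        else:
            chosen = rng.choice(flat_nonzero, size=n_new, replace=False)
        out.ravel()[chosen] = 0.0
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        cell_ids=list(counts.cell_ids),
        values=out,
        layer="counts",
    )


def dropout_robustness(
    expr: ExpressionMatrix,
    net: PPINetwork | None,
    measure: str,
    delta: float,
    seed: int,
    weighted: bool = False,
) -> float:
    """Pearson correlation of per-cell scores before vs after dropout injection.

    The measure is recomputed from counts on the injected matrix (including
    re-normalization), so the correlation reflects the full pipeline's
    sensitivity to excess zeros.
    """
    before = score_all(expr, net, measures=(measure,))[measure].to_numpy()
    injected = dropout_inject(expr, delta, seed, weighted=weighted)
    after = score_all(injected, net, measures=(measure,))[measure].to_numpy()
    ok = ~(np.isnan(before) | np.isnan(after))
    n_bad = int((~ok).sum())
    if n_bad > 0.1 * before.size:
        warnings.warn(
            f"{n_bad}/{before.size} cells have undefined {measure} scores", stacklevel=2
        )
    if ok.sum() < 3:
        raise ValueError("fewer than 3 cells with defined scores on both matrices")
    return float(np.corrcoef(before[ok], after[ok])[0, 1])


def degree_permutation_test(
    expr: ExpressionMatrix,
    k1: np.ndarray,
    k2: np.ndarray,
    B: int = 1000,
    seed: int = 0,
) -> PermutationNull:
    """Monte-Carlo significance of the cross-network agreement of CCAT.

    Observed statistic: the Pearson correlation over cells between CCAT
    computed with connectome ``k1`` and with ``k2`` (both indexed over
    ``expr``'s genes). Each of the ``B`` null draws applies ONE shared random
    permutation sigma to both degree vectors — this leaves the correlation
    between the two connectomes exactly invariant (the pairing (k1_i, k2_i)
    is only relabeled) while destroying any association between connectome
    and transcriptome — and recomputes the CCAT-agreement statistic.
    """
    if expr.layer != "lognorm":
        raise ValueError("degree_permutation_test expects a log-normalized matrix")
    k1 = np.asarray(k1, dtype=float).ravel()
    k2 = np.asarray(k2, dtype=float).ravel()
    if k1.size != k2.size or k1.size != expr.n_genes:
        raise ValueError(
            "k1, k2 and the expression matrix must share one common gene universe"
        )
    if B < 1:
        raise ValueError("B must be >= 1")
    X = expr.values

    def agreement(ka: np.ndarray, kb: np.ndarray) -> float:
        return float(np.corrcoef(ccat_matrix(X, ka), ccat_matrix(X, kb))[0, 1])

    observed = agreement(k1, k2)
    kk_corr = np.corrcoef(k1, k2)[0, 1]
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        sigma = rng.permutation(k1.size)
        p1, p2 = k1[sigma], k2[sigma]
        assert np.isclose(np.corrcoef(p1, p2)[0, 1], kk_corr), (
            "shared permutation must leave the connectome correlation invariant"
        )
        null[b] = agreement(p1, p2)
    p = (1 + int((null >= observed).sum())) / (B + 1)
    return PermutationNull(observed_stat=observed, null_stats=null, p_value=p)
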