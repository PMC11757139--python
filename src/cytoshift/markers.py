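"""Rank-based marker detection and pseudobulk differential expression.

Marker genes are found per cluster by a one-vs-rest Wilcoxon rank-sum test
on log-normalized expression, with Benjamini-Hochberg control within each
cluster at a 1% FDR.  Group-level differential expression runs the same test
across per-sample pseudobulk profiles at a 5% FDR.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError
from .preprocess import NormMatrix

logger = logging.getLogger(__name__)

#: total sample size at or below which the exact null distribution is used
EXACT_MAX_N = 12


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the original order."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns ``(rank_sum_of_x, p)``.

    Uses exact enumeration when the pooled sample has at most 12
    observations and no ties, and the normal approximation with tie and
    continuity corrections otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("wilcoxon_rank_sum: empty input")
    pooled = np.concatenate([x, y])
    W = float(scipy.stats.rankdata(pooled)[: x.size].sum())
    if np.all(pooled == pooled[0]):
        return W, 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and no_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return W, float(res.pvalue)


def _vectorized_ranksum(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Asymptotic two-sided rank-sum p per row of genes x cells blocks."""
    pvals = np.ones(A.shape[0])
    const = np.ptp(np.hstack([A, B]), axis=1) == 0
    var_rows = np.flatnonzero(~const)
    if var_rows.size:
        res = scipy.stats.mannwhitneyu(
            A[var_rows], B[var_rows], alternative="two-sided",
            method="asymptotic", use_continuity=True, axis=1,
        )
        pvals[var_rows] = res.pvalue
    return pvals


def find_markers(
    norm: NormMatrix,
    ann: pd.DataFrame,
    fdr: float = 0.01,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker test per (cluster, gene).

    BH is applied across genes within each cluster; ``significant`` means
    q < *fdr*.  Clusters with fewer than *min_cells* cells are skipped with
    a warning.  log2fc is the difference of mean log-normalized expression
    rescaled to log2 (a reporting convention; significance is rank-based).
    """
    ann = ann.set_index("cell").loc[norm.cells]
    clusters = ann["cluster"].to_numpy()
    labels = sorted(pd.unique(clusters))
    if len(labels) < 2:
        raise ValidationError("find_markers needs at least two clusters")
    X = np.asarray(norm.values.todense())
    ranks = scipy.stats.rankdata(X, axis=1)
    rows = []
    for lab in labels:
        mask = clusters == lab
        if mask.sum() < min_cells:
            logger.warning("cluster %s has <%d cells; skipped", lab, min_cells)
            continue
        A, B = X[:, mask], X[:, ~mask]
        p = _vectorized_ranksum(A, B)
        q = bh_adjust(p)
        stat = ranks[:, mask].sum(axis=1)
        log2fc = (A.mean(axis=1) - B.mean(axis=1)) / np.log(2)
        rows.append(pd.DataFrame({
            "cluster": lab,
            "gene": norm.genes,
            "rank_sum_statistic": stat,
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "significant": q < fdr,
        }))
    return pd.concat(rows, ignore_index=True)


def pseudobulk_de(
    pb: pd.DataFrame,
    groups: pd.Series | dict,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-gene rank-sum test on sample-level pseudobulk profiles.

    *groups* maps sample_id -> group label (exactly two levels, each with at
    least 3 samples).  BH across genes; ``significant`` means q < *fdr*.
    """
    groups = pd.Series(groups)
    groups = groups.loc[pb.index]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValidationError(f"pseudobulk_de needs exactly two groups, got {levels}")
    n_per = groups.value_counts()
    if n_per.min() < 3:
        raise ValidationError("pseudobulk_de needs >= 3 samples per group")
    a_mask = (groups == levels[0]).to_numpy()
    A = pb.to_numpy()[a_mask].T     # genes x samples_A
    B = pb.to_numpy()[~a_mask].T
    stats_p = np.array([wilcoxon_rank_sum(A[i], B[i])[1] for i in range(A.shape[0])])
    q = bh_adjust(stats_p)
    return pd.DataFrame({
        "gene": pb.columns,
        f"mean_{levels[0]}": A.mean(axis=1),
        f"mean_{levels[1]}": B.mean(axis=1),
        "p": stats_p,
        "q": q,
        "significant": q < fdr,
    })
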