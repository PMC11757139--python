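"""Differential abundance of cell clusters between patient groups.

Each sample contributes a composition vector (fraction of its cells in every
cluster).  The test statistic per cluster is the difference of group mean
proportions; its null distribution comes from shuffling the *sample-level*
group labels (patients, not cells, are the exchangeable units, since cells
within a patient are not independent).  P-values use the add-one correction
and are BH-adjusted across clusters.  Effect sizes are Cohen's h on the
pooled per-group proportions: ``h = 2 asin(sqrt(p1)) - 2 asin(sqrt(p2))``.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .io import ValidationError
from .markers import bh_adjust


def cohen_h(p1: float, p2: float) -> float:
    """Cohen's h effect size for two proportions (arcsine-transformed)."""
    p1, p2 = float(p1), float(p2)
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValidationError("proportions must lie in [0, 1]")
    return 2.0 * np.arcsin(np.sqrt(p1)) - 2.0 * np.arcsin(np.sqrt(p2))


def cluster_proportions(ann: pd.DataFrame) -> pd.DataFrame:
    """Per-sample cluster composition: (sample_id, group, cluster, n_cells,
    proportion); absent (sample, cluster) pairs appear with zeros."""
    if ann[["sample_id", "cluster"]].isna().any().any():
        raise ValidationError("cells without sample or cluster")
    counts = (
        ann.groupby(["sample_id", "cluster"], sort=True).size()
        .unstack(fill_value=0)
    )
    sample_group = ann.drop_duplicates("sample_id").set_index("sample_id")["group"]
    props = counts.div(counts.sum(axis=1), axis=0)
    long = pd.concat(
        [counts.stack().rename("n_cells"), props.stack().rename("proportion")], axis=1
    ).reset_index()
    long["group"] = long["sample_id"].map(sample_group)
    return long[["sample_id", "group", "cluster", "n_cells", "proportion"]]


def _proportion_matrix(props: pd.DataFrame):
    P = props.pivot(index="sample_id", columns="cluster", values="proportion")
    N = props.pivot(index="sample_id", columns="cluster", values="n_cells")
    groups = props.drop_duplicates("sample_id").set_index("sample_id")["group"].loc[P.index]
    return P, N, groups


def permutation_abundance_test(
    props: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
    group_order: tuple[str, str] = ("small", "large"),
    exact: bool = False,
) -> pd.DataFrame:
    """Sample-label permutation test of per-cluster abundance.

    statistic = mean proportion in ``group_order[1]`` minus mean in
    ``group_order[0]``.  With ``exact=True`` every reassignment of the group
    labels to samples is enumerated (p is then the exact tail fraction,
    identity included); otherwise *n_perm* random reassignments with the
    add-one correction.  Returns one row per cluster with group means,
    pooled proportions, p, BH q, Cohen's h (pooled) and direction.
    """
    lo, hi = group_order
    P, N, groups = _proportion_matrix(props)
    for g in group_order:
        if (groups == g).sum() < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")
    if set(groups) != set(group_order):
        raise ValidationError(f"groups {sorted(set(groups))} do not match {group_order}")
    if not exact and n_perm < 100:
        raise ValidationError("n_perm must be >= 100")

    X = P.to_numpy(float)                       # samples x clusters
    is_hi = (groups == hi).to_numpy()
    n_hi = int(is_hi.sum())
    obs = X[is_hi].mean(axis=0) - X[~is_hi].mean(axis=0)

    n = X.shape[0]
    if exact:
        null = np.array([
            X[list(c)].mean(axis=0) - np.delete(X, list(c), axis=0).mean(axis=0)
            for c in combinations(range(n), n_hi)
        ])
        p = (np.abs(null) >= np.abs(obs)[None, :] - 1e-12).mean(axis=0)
    else:
        rng = np.random.default_rng(seed)
        M = np.zeros((n_perm, n))
        for i in range(n_perm):
            M[i, rng.choice(n, size=n_hi, replace=False)] = 1.0
        null = (M @ X) / n_hi - ((1.0 - M) @ X) / (n - n_hi)
        hits = (np.abs(null) >= np.abs(obs)[None, :] - 1e-12).sum(axis=0)
        p = (1 + hits) / (1 + n_perm)

    q = bh_adjust(p)
    pooled_hi = N.to_numpy()[is_hi].sum(axis=0) / N.to_numpy()[is_hi].sum()
    pooled_lo = N.to_numpy()[~is_hi].sum(axis=0) / N.to_numpy()[~is_hi].sum()
    h = np.array([cohen_h(a, b) for a, b in zip(pooled_hi, pooled_lo)])
    return pd.DataFrame({
        "cluster": P.columns,
        f"mean_prop_{lo}": X[~is_hi].mean(axis=0),
        f"mean_prop_{hi}": X[is_hi].mean(axis=0),
        f"pooled_prop_{lo}": pooled_lo,
        f"pooled_prop_{hi}": pooled_hi,
        "statistic": obs,
        "p": p,
        "q": q,
        "cohen_h": h,
        "direction": np.where(obs >= 0, "increase", "decrease"),
    }).reset_index(drop=True)
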