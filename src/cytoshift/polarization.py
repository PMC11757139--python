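"""Gene-module polarization scoring and the four-way M1/M2 classification.

The per-cell module score is the mean log-normalized expression of the
signature genes minus the mean expression of control genes matched on
average expression: genes are ranked by their mean expression across all
cells, cut into ``nbin`` near-equal bins, and for every signature gene
``nctrl`` control genes are drawn from its bin (set genes excluded).

Cluster-level activity is the mean score inside a cluster minus the mean in
all other cells, with a label-permutation p-value.  A cluster is called
M1-like / M2-like / Mixed / Neither from the sign of each activity and
p < alpha (default 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSet, ValidationError
from .preprocess import NormMatrix

logger = logging.getLogger(__name__)

CATEGORIES = ["M1-like", "M2-like", "Mixed", "Neither"]


@dataclass
class ModuleScoreResult:
    set_name: str
    scores: pd.Series               # per-cell, indexed by barcode
    control_genes_used: list[str]   # pooled draw, with multiplicity
    genes_used: list[str]           # set genes present in the matrix
    nbin: int
    nctrl: int
    seed: int


def bin_genes_by_expression(norm: NormMatrix, nbin: int = 24) -> pd.Series:
    """Assign every gene to one of *nbin* average-expression bins.

    Genes are ranked by mean expression across cells (ties broken by gene
    symbol, so the map is deterministic and independent of input order) and
    cut into near-equal-size groups, lowest expression first.
    """
    if nbin < 2:
        raise ValidationError("nbin must be >= 2")
    if nbin > norm.n_genes:
        raise ValidationError(f"nbin={nbin} exceeds the {norm.n_genes} genes available")
    means = pd.Series(norm.gene_means(), index=norm.genes)
    order = means.sort_index().sort_values(kind="stable").index
    bins = pd.Series(0, index=order, dtype=int)
    for b, chunk in enumerate(np.array_split(np.arange(len(order)), nbin)):
        bins.iloc[chunk] = b
    return bins.loc[norm.genes]


def module_score(
    norm: NormMatrix,
    gene_set: GeneSet,
    nbin: int = 24,
    nctrl: int = 100,
    seed: int = 0,
    control_genes: list[str] | None = None,
) -> ModuleScoreResult:
    """Per-cell module score for *gene_set* with expression-matched controls.

    For each set gene present in the matrix, *nctrl* control genes are drawn
    from its expression bin (excluding all set genes; with replacement when
    the bin is smaller than *nctrl*); the score is the mean expression of
    the set genes minus the mean over the pooled control draw.  Passing
    *control_genes* overrides the draw (useful for calibration checks).
    """
    idx = norm.gene_index()
    present = [g for g in gene_set.genes if g in idx]
    absent = sorted(set(gene_set.genes) - set(present))
    if absent:
        logger.warning("module_score(%s): %d set genes absent from the matrix",
                       gene_set.name, len(absent))
    if not present:
        raise ValidationError(f"no genes of set {gene_set.name!r} are present")

    rng = np.random.default_rng(seed)
    if control_genes is None:
        bins = bin_genes_by_expression(norm, nbin=nbin)
        in_set = set(present)
        control_genes = []
        for g in present:
            pool = bins.index[(bins == bins[g]) & ~bins.index.isin(in_set)]
            if len(pool) == 0:
                raise ValidationError(f"no control candidates in the bin of {g}")
            replace = len(pool) < nctrl
            control_genes.extend(rng.choice(pool, size=nctrl, replace=replace).tolist())
    else:
        control_genes = list(control_genes)

    set_rows = np.array([idx[g] for g in present])
    ctrl_rows = np.array([idx[g] for g in control_genes])
    set_mean = np.asarray(norm.values[set_rows].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(norm.values[ctrl_rows].mean(axis=0)).ravel()
    return ModuleScoreResult(
        set_name=gene_set.name,
        scores=pd.Series(set_mean - ctrl_mean, index=norm.cells, name=gene_set.name),
        control_genes_used=control_genes,
        genes_used=present,
        nbin=nbin,
        nctrl=nctrl,
        seed=seed,
    )


def geneset_activity_test(
    scores: pd.Series | ModuleScoreResult,
    ann: pd.DataFrame,
    cluster: str,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test of a cluster's module-score activity.

    activity = mean score in the cluster - mean score in all other cells;
    the null shuffles cluster membership over cells; two-sided p with the
    add-one correction: ``(1 + #{|a*| >= |a|}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if isinstance(scores, ModuleScoreResult):
        scores = scores.scores
    s = scores.loc[ann["cell"]].to_numpy(float)
    mask = (ann["cluster"] == cluster).to_numpy()
    k = int(mask.sum())
    n = s.size
    if k == 0:
        raise ValidationError(f"cluster {cluster!r} is empty")
    if k == n:
        raise ValidationError(f"cluster {cluster!r} contains every cell")
    total = s.sum()

    def act(sub_sum: float) -> float:
        return sub_sum / k - (total - sub_sum) / (n - k)

    observed = act(s[mask].sum())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        sub = rng.choice(n, size=k, replace=False)
        if abs(act(s[sub].sum())) >= abs(observed):
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(observed), float(p)


def classify_cluster(
    m1: tuple[float, float],
    m2: tuple[float, float],
    alpha: float = 0.01,
) -> str:
    """Four-way call from (activity, p) pairs for the M1 and M2 signatures.

    A signature counts as positive only when its activity is above zero AND
    its p-value is below *alpha*; both positive -> Mixed, one -> that
    signature's call, none -> Neither.
    """
    m1_pos = m1[0] > 0 and m1[1] < alpha
    m2_pos = m2[0] > 0 and m2[1] < alpha
    if m1_pos and m2_pos:
        return "Mixed"
    if m1_pos:
        return "M1-like"
    if m2_pos:
        return "M2-like"
    return "Neither"


def classify_clusters(
    m1_scores: pd.Series | ModuleScoreResult,
    m2_scores: pd.Series | ModuleScoreResult,
    ann: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Activity tests and four-way calls for every cluster in *ann*."""
    rows = []
    for i, cluster in enumerate(sorted(ann["cluster"].unique())):
        m1 = geneset_activity_test(m1_scores, ann, cluster, n_perm=n_perm, seed=seed + 2 * i)
        m2 = geneset_activity_test(m2_scores, ann, cluster, n_perm=n_perm, seed=seed + 2 * i + 1)
        rows.append({
            "cluster": cluster,
            "m1_activity": m1[0], "m1_p": m1[1],
            "m2_activity": m2[0], "m2_p": m2[1],
            "category": classify_cluster(m1, m2, alpha=alpha),
        })
    return pd.DataFrame(rows)


def category_proportions(calls, ann: pd.DataFrame) -> pd.DataFrame:
    """Percent of each sample's cells in clusters of each polarization category.

    *calls* is either the frame from :func:`classify_clusters` or a mapping
    cluster -> category.  Every (sample, category) pair is present (zeros
    included) so per-sample percentages sum to 100.
    """
    if isinstance(calls, pd.DataFrame):
        mapping = dict(zip(calls["cluster"], calls["category"]))
    else:
        mapping = dict(calls)
    missing = set(ann["cluster"].unique()) - set(mapping)
    if missing:
        raise ValidationError(f"clusters without a polarization call: {sorted(missing)}")
    df = ann[["sample_id", "group", "cluster"]].copy()
    df["category"] = df["cluster"].map(mapping)
    sample_group = df.drop_duplicates("sample_id").set_index("sample_id")["group"]
    counts = (
        df.groupby(["sample_id", "category"], sort=True).size()
        .unstack(fill_value=0)
        .reindex(columns=CATEGORIES, fill_value=0)
    )
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValidationError("sample with zero cells in category_proportions")
    pct = counts.div(totals, axis=0) * 100.0
    out = pct.stack().rename("percent").reset_index()
    out["group"] = out["sample_id"].map(sample_group)
    return out[["sample_id", "group", "category", "percent"]]
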