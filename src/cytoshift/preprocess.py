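"""Cell-level quality control, log-normalization and pseudobulk aggregation.

QC keeps cells with an inclusive gene-count window (default 1,000-10,000
observed genes) and a strict mitochondrial-fraction cap (default < 22% of
reads on MT- genes).  Normalization is plain library-size scaling followed
by log1p: ``value = log(1 + count * scale_factor / cell_total)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, ValidationError, validate_annotations

logger = logging.getLogger(__name__)


@dataclass
class NormMatrix:
    """Log-normalized expression, genes x cells, same layout as CountMatrix."""

    genes: list[str]
    cells: list[str]
    values: sp.csr_matrix
    scale_factor: float = 10000.0

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def gene_means(self) -> np.ndarray:
        """Mean normalized expression per gene across all cells."""
        return np.asarray(self.values.mean(axis=1)).ravel()


@dataclass
class QCReport:
    n_in: int
    n_kept: int
    n_low_genes: int
    n_high_genes: int
    n_high_mito: int


def qc_filter(
    counts: CountMatrix,
    ann: pd.DataFrame | None = None,
    min_genes: int = 1000,
    max_genes: int = 10000,
    max_mito: float = 0.22,
    return_report: bool = False,
):
    """Retain cells with ``min_genes <= n_genes <= max_genes`` and
    ``mito_frac < max_mito`` (bounds on the gene window inclusive, the
    mitochondrial cap strict).

    ``n_genes`` and ``mito_frac`` are recomputed from the matrix; if an
    annotation frame is given it is subset and those two columns refreshed.
    Returns ``(CountMatrix, annotations)`` and, optionally, a QCReport.
    """
    n_genes_obs = counts.cells_per_gene_count()
    mito_frac = counts.mito_fraction()
    keep = (n_genes_obs >= min_genes) & (n_genes_obs <= max_genes) & (mito_frac < max_mito)

    report = QCReport(
        n_in=counts.n_cells,
        n_kept=int(keep.sum()),
        n_low_genes=int((n_genes_obs < min_genes).sum()),
        n_high_genes=int((n_genes_obs > max_genes).sum()),
        n_high_mito=int((mito_frac >= max_mito).sum()),
    )
    logger.info(
        "qc_filter: %d cells in, %d kept (%d below %d genes, %d above %d genes, "
        "%d at mito >= %.2f)",
        report.n_in, report.n_kept, report.n_low_genes, min_genes,
        report.n_high_genes, max_genes, report.n_high_mito, max_mito,
    )
    if report.n_kept == 0:
        raise ValidationError("qc_filter removed every cell")

    filtered = counts.subset_cells(keep)
    if ann is not None:
        validate_annotations(ann, counts)
        ann = ann.set_index("cell").loc[filtered.cells].reset_index()
    else:
        ann = pd.DataFrame({"cell": filtered.cells})
    ann = ann.copy()
    ann["n_genes"] = n_genes_obs[keep]
    ann["mito_frac"] = mito_frac[keep]
    if return_report:
        return filtered, ann, report
    return filtered, ann


def log_normalize(counts: CountMatrix, scale_factor: float = 10000.0) -> NormMatrix:
    """log1p of per-cell scaled counts; zeros stay zero, so sparsity is kept."""
    totals = counts.cell_totals().astype(float)
    if np.any(totals == 0):
        raise ValidationError("log_normalize: zero-total cell encountered; run qc_filter first")
    X = counts.counts.tocsc().astype(float)
    X = X @ sp.diags(scale_factor / totals)
    X.data = np.log1p(X.data)
    return NormMatrix(
        genes=list(counts.genes),
        cells=list(counts.cells),
        values=X.tocsr(),
        scale_factor=scale_factor,
    )


def pseudobulk(
    norm: NormMatrix,
    ann: pd.DataFrame,
    counts: CountMatrix | None = None,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Aggregate cells within samples: one row per sample, one column per gene.

    ``aggregate="mean"`` averages log-normalized values (scale-invariant to
    the number of cells per sample); ``aggregate="sum_counts"`` sums raw
    counts instead (requires *counts*).
    """
    if aggregate not in ("mean", "sum_counts"):
        raise ValidationError(f"unknown aggregate {aggregate!r}")
    ann = ann.set_index("cell").loc[norm.cells]
    if ann["sample_id"].isna().any():
        raise ValidationError("pseudobulk: cells without a sample_id")
    samples = ann["sample_id"].to_numpy()
    uniq = list(dict.fromkeys(samples))

    if aggregate == "sum_counts":
        if counts is None:
            raise ValidationError("aggregate='sum_counts' needs the count matrix")
        mat = counts.counts
        rows = [np.asarray(mat[:, samples == s].sum(axis=1)).ravel() for s in uniq]
    else:
        mat = norm.values
        rows = [np.asarray(mat[:, samples == s].mean(axis=1)).ravel() for s in uniq]
    return pd.DataFrame(rows, index=pd.Index(uniq, name="sample_id"), columns=norm.genes)
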