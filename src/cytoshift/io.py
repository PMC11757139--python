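"""Readers and writers for the formats the pipeline touches.

Count matrices travel as Matrix Market coordinate files (genes as rows, the
CellRanger convention) paired with ``features.tsv`` / ``barcodes.tsv``;
per-cell annotations as a header-ed TSV; gene sets as GMT.  The module also
exposes the two packaged in-paper fixtures: the printed M1/M2 macrophage
polarization signatures and the 20-patient demographics table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

MITO_PREFIX = "MT-"

ANNOTATION_COLUMNS = ["cell", "sample_id", "group", "cluster"]


class ValidationError(ValueError):
    """Raised when an input file or object violates its schema."""


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix.

    Parameters
    ----------
    genes : list of str
        Unique gene symbols, one per row.
    cells : list of str
        Unique cell barcodes, one per column.
    counts : scipy.sparse.csr_matrix
        Non-negative integer counts, shape ``(len(genes), len(cells))``.

    Mitochondrial genes are identified by the ``MT-`` symbol prefix
    (standard for GRCh38 symbol annotation).
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene symbols are not unique")
        if len(set(self.cells)) != len(self.cells):
            raise ValidationError("cell barcodes are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative counts")
        if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
            raise ValidationError("non-integer counts")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def mito_genes(self) -> list[str]:
        return [g for g in self.genes if g.startswith(MITO_PREFIX)]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def cells_per_gene_count(self) -> np.ndarray:
        """Number of genes with nonzero UMI, per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def mito_fraction(self) -> np.ndarray:
        """Fraction of each cell's counts on MT- genes (0 where total is 0)."""
        mito_rows = [i for i, g in enumerate(self.genes) if g.startswith(MITO_PREFIX)]
        totals = self.cell_totals().astype(float)
        if not mito_rows:
            return np.zeros(self.n_cells)
        mito = np.asarray(self.counts[mito_rows].sum(axis=0)).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / totals, 0.0)
        return frac

    def subset_cells(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            genes=list(self.genes),
            cells=[self.cells[i] for i in idx],
            counts=self.counts[:, idx].tocsr(),
        )


@dataclass
class GeneSet:
    """A named list of gene symbols (e.g. the M1 polarization signature)."""

    name: str
    genes: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate symbols")

    def __len__(self) -> int:
        return len(self.genes)


def _make_unique(symbols: list[str]) -> list[str]:
    """Deterministic numeric-suffix disambiguation of duplicate symbols.

    The second occurrence of GENE becomes GENE.1, the third GENE.2, etc.
    """
    seen: dict[str, int] = {}
    out = []
    n_dup = 0
    for s in symbols:
        if s in seen:
            seen[s] += 1
            new = f"{s}.{seen[s]}"
            # guard against a pre-existing symbol equal to the suffixed name
            while new in seen:
                seen[s] += 1
                new = f"{s}.{seen[s]}"
            out.append(new)
            seen[new] = 0
            n_dup += 1
        else:
            seen[s] = 0
            out.append(s)
    if n_dup:
        logger.warning("disambiguated %d duplicate gene symbols with numeric suffixes", n_dup)
    return out


def read_counts(matrix_path, features_path, barcodes_path) -> CountMatrix:
    """Read a CellRanger-style triplet (MTX + features TSV + barcodes TSV).

    Genes are rows; duplicate gene symbols are disambiguated with numeric
    suffixes and logged.
    """
    for p in (matrix_path, features_path, barcodes_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    mat = scipy.io.mmread(str(matrix_path))
    data = np.asarray(mat.todense() if sp.issparse(mat) else mat)
    if np.any(data != np.round(data)):
        raise ValidationError(f"{matrix_path}: non-integer matrix entries")
    features = pd.read_csv(features_path, sep="\t", header=None)
    genes = _make_unique(features.iloc[:, 0].astype(str).tolist())
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    counts = sp.csr_matrix(mat.astype(np.int64))
    if counts.shape != (len(genes), len(barcodes)):
        raise ValidationError(
            f"matrix is {counts.shape} but features/barcodes give "
            f"({len(genes)}, {len(barcodes)})"
        )
    return CountMatrix(genes=genes, cells=barcodes, counts=counts)


def write_counts(cm: CountMatrix, out_dir) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv into *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), cm.counts.tocoo(), field="integer")
    (out / "features.tsv").write_text("".join(f"{g}\n" for g in cm.genes))
    (out / "barcodes.tsv").write_text("".join(f"{c}\n" for c in cm.cells))


def read_annotations(path) -> pd.DataFrame:
    """Read the per-cell annotation TSV (cell, sample_id, group, cluster, ...)."""
    ann = pd.read_csv(path, sep="\t", dtype={"cell": str, "sample_id": str, "cluster": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValidationError(f"{path}: missing annotation columns {missing}")
    validate_annotations(ann)
    return ann


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def validate_annotations(ann: pd.DataFrame, cm: CountMatrix | None = None) -> None:
    if ann["cell"].duplicated().any():
        raise ValidationError("duplicate cell barcodes in annotations")
    if "mito_frac" in ann.columns:
        mf = ann["mito_frac"].to_numpy(float)
        if np.any((mf < 0) | (mf > 1)):
            raise ValidationError("mito_frac outside [0, 1]")
    if cm is not None:
        unknown = set(ann["cell"]) - set(cm.cells)
        if unknown:
            raise ValidationError(
                f"{len(unknown)} annotation barcodes absent from the count matrix"
            )


def read_gene_sets(gmt_path) -> list[GeneSet]:
    """Parse a GMT file: name, description, then genes, tab-separated."""
    sets = []
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{gmt_path}:{lineno}: GMT line has <3 fields")
            sets.append(GeneSet(name=fields[0], description=fields[1], genes=fields[2:]))
    return sets


def write_gene_sets(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def _data_path(name: str):
    return resources.files("cytoshift.data").joinpath(name)


def load_signatures() -> dict[str, GeneSet]:
    """The packaged M1 and M2 macrophage polarization signatures.

    The gene lists are stored verbatim as printed, including the entry
    ``SNF789`` in the M2 list (likely a typo for ZNF789 in the original,
    kept untouched so the fixture mirrors its source).
    """
    with resources.as_file(_data_path("m1_m2_signatures.gmt")) as p:
        sets = read_gene_sets(p)
    return {s.name: s for s in sets}


def load_table1() -> pd.DataFrame:
    """The packaged 20-patient demographics table.

    Columns: sample_id, group (small/large), age (years), bmi (kg/m^2),
    volume (mL prostate volume); 10 patients per group.
    """
    with resources.as_file(_data_path("table1_demographics.tsv")) as p:
        tbl = pd.read_csv(p, sep="\t", dtype={"sample_id": str})
    return tbl
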