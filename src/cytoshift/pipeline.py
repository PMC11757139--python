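"""End-to-end pipeline: QC -> normalize -> markers/DE -> polarization -> abundance -> stats.

The pipeline is a plain function over a :class:`PipelineConfig`; the CLI is
a thin wrapper.  Every output directory receives the result tables as CSV, a
verbatim YAML snapshot of the configuration, and a run log, so a bundle is
reproducible from its snapshot alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import abundance as ab
from . import markers as mk
from . import polarization as pol
from . import stats as st
from .io import ValidationError, load_signatures, read_annotations, read_counts
from .preprocess import log_normalize, pseudobulk, qc_filter

logger = logging.getLogger(__name__)

RESULT_TABLES = [
    "qc_annotations", "markers", "de", "module_scores", "polarization_calls",
    "category_proportions", "abundance", "category_group_stats",
]


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a full run; serialized into outputs."""

    matrix: str = "matrix.mtx"
    features: str = "features.tsv"
    barcodes: str = "barcodes.tsv"
    annotations: str = "annotations.tsv"
    group_col: str = "group"
    cluster_col: str = "cluster"
    min_genes: int = 1000
    max_genes: int = 10000
    max_mito: float = 0.22
    scale_factor: float = 10000.0
    markers_fdr: float = 0.01
    de_fdr: float = 0.05
    nbin: int = 24
    nctrl: int = 100
    n_perm: int = 10000
    alpha: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.max_mito <= 1):
            raise ValidationError("max_mito must lie in [0, 1]")
        if self.min_genes < 0 or self.max_genes < self.min_genes:
            raise ValidationError("need 0 <= min_genes <= max_genes")
        for name in ("markers_fdr", "de_fdr", "alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must lie in (0, 1)")
        if self.scale_factor <= 0 or self.nbin < 2 or self.nctrl < 1 or self.n_perm < 100:
            raise ValidationError("scale_factor/nbin/nctrl/n_perm out of domain")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir, input_dir=None) -> dict[str, pd.DataFrame]:
    """Execute every stage and write the result bundle into *out_dir*.

    Input paths in *config* are resolved against *input_dir* when given.
    Returns the result tables keyed by name.  Deterministic for a fixed
    config and seed.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("cytoshift")
    root.addHandler(handler)
    results: dict[str, pd.DataFrame] = {}

    def _resolve(p):
        return Path(input_dir) / p if input_dir is not None else Path(p)

    def stage(name):
        logger.info("stage %s", name)

    try:
        try:
            stage("load")
            counts = read_counts(_resolve(config.matrix), _resolve(config.features),
                                 _resolve(config.barcodes))
            ann = pd.read_csv(_resolve(config.annotations), sep="\t",
                              dtype={"cell": str, "sample_id": str})
            ann = ann.rename(columns={config.group_col: "group",
                                      config.cluster_col: "cluster"})
            ann["cluster"] = ann["cluster"].astype(str)
        except (OSError, ValidationError, KeyError) as e:
            raise StageError("load", e)

        try:
            stage("qc")
            counts, ann = qc_filter(counts, ann, min_genes=config.min_genes,
                                    max_genes=config.max_genes, max_mito=config.max_mito)
            results["qc_annotations"] = ann
        except ValidationError as e:
            raise StageError("qc", e)

        try:
            stage("normalize")
            norm = log_normalize(counts, scale_factor=config.scale_factor)
        except ValidationError as e:
            raise StageError("normalize", e)

        try:
            stage("markers")
            results["markers"] = mk.find_markers(norm, ann, fdr=config.markers_fdr)
        except ValidationError as e:
            raise StageError("markers", e)

        try:
            stage("de")
            pb = pseudobulk(norm, ann)
            groups = ann.drop_duplicates("sample_id").set_index("sample_id")["group"]
            results["de"] = mk.pseudobulk_de(pb, groups, fdr=config.de_fdr)
        except ValidationError as e:
            raise StageError("de", e)

        try:
            stage("score")
            sigs = load_signatures()
            m1 = pol.module_score(norm, sigs["M1"], nbin=config.nbin,
                                  nctrl=config.nctrl, seed=config.seed)
            m2 = pol.module_score(norm, sigs["M2"], nbin=config.nbin,
                                  nctrl=config.nctrl, seed=config.seed + 1)
            results["module_scores"] = pd.DataFrame(
                {"cell": norm.cells, "m1_score": m1.scores.to_numpy(),
                 "m2_score": m2.scores.to_numpy()})
        except ValidationError as e:
            raise StageError("score", e)

        try:
            stage("classify")
            calls = pol.classify_clusters(m1, m2, ann, alpha=config.alpha,
                                          n_perm=config.n_perm, seed=config.seed + 2)
            results["polarization_calls"] = calls
            results["category_proportions"] = pol.category_proportions(calls, ann)
        except ValidationError as e:
            raise StageError("classify", e)

        try:
            stage("abundance")
            props = ab.cluster_proportions(ann)
            results["abundance"] = ab.permutation_abundance_test(
                props, n_perm=config.n_perm, seed=config.seed + 3)
        except ValidationError as e:
            raise StageError("abundance", e)

        try:
            stage("stats")
            results["category_group_stats"] = category_group_stats(
                results["category_proportions"])
        except ValidationError as e:
            raise StageError("stats", e)

        for name, df in results.items():
            df.to_csv(out / f"{name}.csv", index=False)
    finally:
        root.removeHandler(handler)
        handler.close()
    return results


def category_group_stats(category_props: pd.DataFrame) -> pd.DataFrame:
    """Group comparison of per-sample category percentages (one row per
    polarization category): normality-gated test, p, and Cohen's d
    (large vs small)."""
    rows = []
    for cat, sub in category_props.groupby("category", sort=True):
        x = sub.loc[sub["group"] == "large", "percent"].to_numpy(float)
        y = sub.loc[sub["group"] == "small", "percent"].to_numpy(float)
        if x.size == 0 or y.size == 0:
            continue
        try:
            cmp = st.compare_groups(x, y)
        except ValidationError:
            continue
        rows.append({"category": cat, "mean_small": y.mean(), "mean_large": x.mean(),
                     "test_used": cmp.test_used, "p": cmp.p, "cohen_d": cmp.cohen_d})
    return pd.DataFrame(rows)
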