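"""Synthetic two-group single-cell cohorts with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: 20 patients in two groups, ~5,000 cells per patient, a modest number
of cell clusters whose per-patient proportions vary around group-level
targets (Dirichlet-multinomial), negative-binomial UMI counts with per-cell
library-size variation, planted per-cluster marker genes, planted M1/M2
signature "programs", and a per-cell mitochondrial read fraction realized by
routing counts to MT- genes.

Group "large" cluster proportions are ``baseline_props * abundance_fc``
renormalized, so a fold-change of 1 everywhere makes the two groups
exchangeable.  Signature programs multiply the negative-binomial mean of
every gene in the chosen printed signature(s) by ``exp(delta)`` for cells of
that cluster; signature genes are given moderately high base expression so
that the shift carries through to the log-normalized scale roughly
additively (score ~ delta).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, GeneSet, ValidationError, load_signatures

# Human mitochondrial protein-coding gene symbols (GRCh38, MT- prefix).
MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]

CATEGORIES = ["M1-like", "M2-like", "Mixed", "Neither"]


def _program_category(sets: Sequence[str]) -> str:
    s = set(sets)
    if s == {"M1"}:
        return "M1-like"
    if s == {"M2"}:
        return "M2-like"
    if s == {"M1", "M2"}:
        return "Mixed"
    return "Neither"


@dataclass
class SimulationConfig:
    """Study-scale defaults: 10 patients/group, ~5,000 cells each, 13 clusters.

    ``signature_programs`` maps cluster index -> (signature names, delta),
    e.g. ``{0: (("M1",), 1.0)}``; delta is the planted log-scale effect.
    ``abundance_fc`` is the per-cluster proportion fold-change of group
    "large" relative to "small" (1.0 = null).
    """

    n_samples_per_group: int = 10
    cells_per_sample: int = 5000          # Poisson mean
    n_genes: int = 2000
    n_clusters: int = 13
    baseline_props: Sequence[float] | None = None
    abundance_fc: Sequence[float] | None = None
    dirichlet_conc: float = 200.0
    marker_genes_per_cluster: int = 20
    marker_log2fc: float = 2.0
    signature_programs: Mapping[int, tuple[Sequence[str], float]] = field(default_factory=dict)
    nb_dispersion: float = 2.0
    libsize_lognorm_sigma: float = 0.35
    mito_frac_beta: tuple[float, float] = (2.0, 18.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_props is None:
            # geometrically decreasing shares, a typical cluster-size profile
            w = 0.85 ** np.arange(self.n_clusters)
            self.baseline_props = (w / w.sum()).tolist()
        if self.abundance_fc is None:
            self.abundance_fc = [1.0] * self.n_clusters
        self.validate()

    def validate(self) -> None:
        props = np.asarray(self.baseline_props, float)
        fc = np.asarray(self.abundance_fc, float)
        if props.shape != (self.n_clusters,) or fc.shape != (self.n_clusters,):
            raise ValidationError("baseline_props/abundance_fc length must equal n_clusters")
        if abs(props.sum() - 1.0) > 1e-9 or np.any(props <= 0):
            raise ValidationError("baseline_props must be positive and sum to 1")
        if np.any(fc <= 0) or not np.all(np.isfinite(fc)):
            raise ValidationError("abundance_fc must be positive and finite")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if min(self.n_samples_per_group, self.cells_per_sample, self.n_genes,
               self.n_clusters) <= 0 or self.marker_genes_per_cluster < 0:
            raise ValidationError("count parameters must be positive")
        if self.libsize_lognorm_sigma < 0 or min(self.mito_frac_beta) <= 0:
            raise ValidationError("noise parameters out of domain")
        for k, prog in self.signature_programs.items():
            sets, delta = prog
            if not 0 <= int(k) < self.n_clusters:
                raise ValidationError(f"program cluster {k} out of range")
            if not set(sets) <= {"M1", "M2"}:
                raise ValidationError(f"unknown signature(s) in program for cluster {k}")
            if delta < 0:
                raise ValidationError("program delta must be >= 0")

    def group_props(self, group: str) -> np.ndarray:
        props = np.asarray(self.baseline_props, float)
        if group == "small":
            return props
        scaled = props * np.asarray(self.abundance_fc, float)
        total = scaled.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValidationError("abundance_fc makes the large-group proportions non-normalizable")
        return scaled / total


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort."""

    group_props: pd.DataFrame          # clusters x {small, large}
    sample_props: pd.DataFrame         # samples x clusters, realized
    markers: dict[str, list[str]]      # cluster label -> planted marker genes
    programs: dict[str, tuple[list[str], float]]
    planted_category: dict[str, str]   # cluster label -> four-way category


def _build_gene_universe(cfg: SimulationConfig, signatures: dict[str, GeneSet]):
    sig_genes = list(signatures["M1"].genes) + [
        g for g in signatures["M2"].genes if g not in set(signatures["M1"].genes)
    ]
    n_markers = cfg.n_clusters * cfg.marker_genes_per_cluster
    n_fixed = len(MITO_GENES) + len(sig_genes) + n_markers
    if cfg.n_genes < n_fixed + 50:
        raise ValidationError(
            f"n_genes={cfg.n_genes} too small: need >= {n_fixed + 50} to hold "
            "mito + signature + marker genes plus background"
        )
    n_generic = cfg.n_genes - len(MITO_GENES) - len(sig_genes)
    generic = [f"G{i:05d}" for i in range(n_generic)]
    genes = MITO_GENES + sig_genes + generic
    markers = {
        f"C{k:02d}": generic[k * cfg.marker_genes_per_cluster:(k + 1) * cfg.marker_genes_per_cluster]
        for k in range(cfg.n_clusters)
    }
    return genes, markers


def simulate_cohort(cfg: SimulationConfig):
    """Simulate a cohort; returns ``(CountMatrix, annotations, SyntheticTruth)``.

    Reproducible for a fixed ``cfg.seed``: a single seed sequence is split
    hierarchically, one child stream per sample.
    """
    signatures = load_signatures()
    genes, markers = _build_gene_universe(cfg, signatures)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_mito = len(MITO_GENES)
    nonmito_genes = genes[n_mito:]
    n_nm = len(nonmito_genes)

    ss = np.random.SeedSequence(cfg.seed)
    root = np.random.default_rng(ss.spawn(1)[0])

    # Per-gene base mean counts (shared by all samples): background genes are
    # mostly low-expressed; signature genes moderately high so a log-scale
    # program shift survives log1p normalization.
    sig_names = set(signatures["M1"].genes) | set(signatures["M2"].genes)
    base = np.empty(n_nm)
    is_sig = np.array([g in sig_names for g in nonmito_genes])
    base[~is_sig] = root.lognormal(mean=np.log(0.5), sigma=1.2, size=(~is_sig).sum())
    base[is_sig] = root.lognormal(mean=np.log(5.0), sigma=0.4, size=is_sig.sum())

    # per-cluster mean multipliers
    cluster_labels = [f"C{k:02d}" for k in range(cfg.n_clusters)]
    nm_idx = {g: j for j, g in enumerate(nonmito_genes)}
    mult = np.ones((cfg.n_clusters, n_nm))
    for k, lab in enumerate(cluster_labels):
        for g in markers[lab]:
            mult[k, nm_idx[g]] = 2.0 ** cfg.marker_log2fc
    programs: dict[str, tuple[list[str], float]] = {}
    for k, (sets, delta) in cfg.signature_programs.items():
        lab = cluster_labels[int(k)]
        programs[lab] = (sorted(set(sets)), float(delta))
        for sname in sets:
            for g in signatures[sname].genes:
                mult[int(k), nm_idx[g]] *= np.exp(delta)

    groups = ["small"] * cfg.n_samples_per_group + ["large"] * cfg.n_samples_per_group
    sample_ids = [f"{g}_{i % cfg.n_samples_per_group + 1:02d}" for i, g in enumerate(groups)]
    child_seeds = ss.spawn(len(sample_ids))

    r = cfg.nb_dispersion
    blocks, ann_rows, sample_prop_rows = [], [], []
    for sid, grp, child in zip(sample_ids, groups, child_seeds):
        rng = np.random.default_rng(child)
        gp = cfg.group_props(grp)
        p_s = rng.dirichlet(cfg.dirichlet_conc * gp)
        n_cells = max(1, rng.poisson(cfg.cells_per_sample))
        cluster_of = rng.choice(cfg.n_clusters, size=n_cells, p=p_s)
        counts_k = np.bincount(cluster_of, minlength=cfg.n_clusters)
        sample_prop_rows.append(counts_k / n_cells)

        lib = rng.lognormal(mean=0.0, sigma=cfg.libsize_lognorm_sigma, size=n_cells)
        X = np.zeros((n_cells, n_nm), dtype=np.int64)
        for k in range(cfg.n_clusters):
            rows = np.flatnonzero(cluster_of == k)
            if rows.size == 0:
                continue
            mu = np.outer(lib[rows], base * mult[k])
            X[rows] = rng.negative_binomial(r, r / (r + mu))

        # mitochondrial routing: draw a target fraction f per cell and add
        # m = T f/(1-f) mito counts so that m/(m+T) ~= f
        a, b = cfg.mito_frac_beta
        f = rng.beta(a, b, size=n_cells)
        T = X.sum(axis=1)
        m = np.rint(T * f / (1.0 - f)).astype(np.int64)
        M = np.zeros((n_cells, n_mito), dtype=np.int64)
        pm = np.full(n_mito, 1.0 / n_mito)
        for i in np.flatnonzero(m > 0):
            M[i] = rng.multinomial(m[i], pm)

        full = np.hstack([M, X])
        blocks.append(sp.csr_matrix(full))
        totals = full.sum(axis=1)
        mito_frac = np.divide(M.sum(axis=1), totals, out=np.zeros(n_cells), where=totals > 0)
        n_genes_obs = (full > 0).sum(axis=1)
        ann_rows.extend(
            (f"{sid}:{i:05d}", sid, grp, cluster_labels[cluster_of[i]],
             int(n_genes_obs[i]), float(mito_frac[i]))
            for i in range(n_cells)
        )

    counts = sp.vstack(blocks).T.tocsr()  # genes x cells
    ann = pd.DataFrame(
        ann_rows, columns=["cell", "sample_id", "group", "cluster", "n_genes", "mito_frac"]
    )
    cm = CountMatrix(genes=genes, cells=ann["cell"].tolist(), counts=counts)

    truth = SyntheticTruth(
        group_props=pd.DataFrame(
            {"small": cfg.group_props("small"), "large": cfg.group_props("large")},
            index=cluster_labels,
        ),
        sample_props=pd.DataFrame(sample_prop_rows, index=sample_ids, columns=cluster_labels),
        markers=markers,
        programs=programs,
        planted_category={
            lab: _program_category(programs.get(lab, ([], 0.0))[0]) for lab in cluster_labels
        },
    )
    return cm, ann, truth
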