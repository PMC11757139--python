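import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cytoshift import (CountMatrix, SimulationConfig, load_signatures,
                       log_normalize, simulate_cohort)


@pytest.fixture(scope="session")
def signatures():
    return load_signatures()


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort with planted markers and an M1 program on the
    last (smallest) cluster; shared across tests that only read it."""
    cfg = SimulationConfig(
        n_samples_per_group=4,
        cells_per_sample=150,
        n_genes=600,
        n_clusters=5,
        marker_genes_per_cluster=10,
        marker_log2fc=2.0,
        signature_programs={4: (("M1",), 1.0)},
        seed=42,
    )
    cm, ann, truth = simulate_cohort(cfg)
    return cm, ann, truth, cfg


@pytest.fixture(scope="session")
def small_norm(small_cohort):
    cm, ann, truth, cfg = small_cohort
    return log_normalize(cm)


def make_count_matrix(dense, genes=None, cells=None) -> CountMatrix:
    dense = np.asarray(dense)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    cells = cells or [f"c{j}" for j in range(dense.shape[1])]
    return CountMatrix(genes=genes, cells=cells, counts=sp.csr_matrix(dense))


def annotations_for(cm, sample_of=None, cluster_of=None, group_of=None) -> pd.DataFrame:
    n = cm.n_cells
    return pd.DataFrame({
        "cell": cm.cells,
        "sample_id": sample_of if sample_of is not None else ["s1"] * n,
        "group": group_of if group_of is not None else ["small"] * n,
        "cluster": cluster_of if cluster_of is not None else ["A"] * n,
    })
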