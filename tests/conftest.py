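import numpy as np
import pandas as pd
import pytest

from hscage.datatypes import NormalizedMatrix
from hscage.qc_norm import lognormalize
from hscage.synthgen import ScConfig, SimConfig, generate_sc


def small_sim(seed: int = 7, **sc_overrides) -> SimConfig:
    """Reduced-size simulation config for fast module tests."""
    sc = dict(
        n_genes=400,
        n_mito_genes=10,
        n_young_cells=150,
        n_old_cells=250,
        n_aging_genes=30,
        n_young_genes=20,
        n_cluster_marker_genes=20,
        n_membrane_decoys=15,
    )
    sc.update(sc_overrides)
    return SimConfig(seed=seed, sc=ScConfig(**sc))


@pytest.fixture(scope="session")
def sc_small():
    """One small synthetic single-cell dataset shared across tests."""
    matrix, annotation, truth = generate_sc(small_sim(seed=7))
    nm = lognormalize(matrix)
    return matrix, annotation, truth, nm


def make_nm(values: np.ndarray, gene_ids=None, cell_ids=None) -> NormalizedMatrix:
    """Wrap a plain array of log-normalized values for direct unit tests."""
    values = np.asarray(values, dtype=float)
    g = gene_ids or [f"g{i+1}" for i in range(values.shape[0])]
    c = cell_ids or [f"c{i+1}" for i in range(values.shape[1])]
    return NormalizedMatrix(values, g, c, pd.DataFrame(index=pd.Index(c, name="cell_id")))
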