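import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from emtstage import sc_core, simdata
from emtstage.containers import CountMatrix, NormalizedMatrix


@pytest.fixture(scope="session")
def continuum_small():
    """A modest EMT-continuum simulation shared by read-only tests."""
    cfg = simdata.EMTSimConfig(
        n_cells=1200,
        n_genes=400,
        tf_onsets={"TFA": (0.4, 2.0), "TFB": (0.55, 2.0), "TFC": (0.9, 2.0)},
        seed=11,
    )
    counts, truth = simdata.simulate_emt_continuum(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def continuum_norm(continuum_small):
    _, counts, _ = continuum_small
    filtered = sc_core.filter_genes_min_cells(counts)
    return sc_core.normalize_log(filtered)


def make_norm(values: np.ndarray, genes=None, cells=None) -> NormalizedMatrix:
    """Wrap a dense non-negative array as a NormalizedMatrix for unit tests."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return NormalizedMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                     columns=pd.Index(cells, name="cell")),
        target_sum=1e4,
    )


def make_counts(dense: np.ndarray, genes=None, cells=None, mito=None) -> CountMatrix:
    dense = np.asarray(dense)
    genes = pd.Index(genes or [f"g{i}" for i in range(dense.shape[0])], name="gene")
    cells = pd.Index(cells or [f"c{i}" for i in range(dense.shape[1])], name="cell")
    gene_meta = pd.DataFrame(index=genes)
    if mito is not None:
        gene_meta["mito"] = np.asarray(mito, dtype=bool)
    return CountMatrix(sp.csr_matrix(dense), genes, cells, gene_meta)
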