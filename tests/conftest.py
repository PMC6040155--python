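import numpy as np
import pandas as pd
import pytest

import tissuegrn as tg


@pytest.fixture(scope="session")
def small_config() -> tg.SimulationConfig:
    """A three-tissue study small enough for sub-second simulation."""
    return tg.SimulationConfig(n_tf=10, n_genes=60, n_samples_per_tissue=40,
                               n_tissues=3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(base network, tissue networks, counts) under small_config."""
    return tg.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_expression(small_dataset):
    _, _, counts = small_dataset
    factors = tg.tmm_factors(counts)
    return tg.to_cpm(counts, factors, log_transform=True)


def make_edge_list(rows, tf_ids=None, tissue=""):
    """RankedEdgeList from (regulator, target, weight) triples."""
    df = pd.DataFrame(rows, columns=["regulator", "target", "weight"])
    tfs = frozenset(tf_ids) if tf_ids is not None else frozenset(df["regulator"])
    return tg.RankedEdgeList(df, tfs, tissue=tissue)


@pytest.fixture
def toy_grn():
    """Ten ranked edges from two TFs over six genes."""
    rows = [
        ("TF1", "G1", 0.9), ("TF1", "G2", 0.8), ("TF2", "G1", 0.7),
        ("TF2", "G3", 0.6), ("TF1", "G3", 0.5), ("TF2", "G4", 0.4),
        ("TF1", "G4", 0.3), ("TF2", "G2", 0.2), ("TF1", "TF2", 0.15),
        ("TF2", "TF1", 0.1),
    ]
    return make_edge_list(rows)


def expression_from_values(values: np.ndarray, gene_ids, library_ids=None,
                           scale=tg.expr.SCALE_LOG, tissue="t1"):
    library_ids = library_ids or [f"L{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=list(gene_ids), columns=library_ids)
    return tg.ExpressionMatrix(df, scale, {l: tissue for l in library_ids})
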