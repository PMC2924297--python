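import numpy as np
import pandas as pd
import pytest

import synechonet as sn


@pytest.fixture()
def tiny_compendium():
    """3 genes x 2 experiments with mixed replicate counts."""
    return sn.ExpressionCompendium(
        genes=["g1", "g2", "g3"],
        experiments=["expA", "expB"],
        values={
            ("g1", "expA"): (2.1, 1.9, 2.0, 2.2),
            ("g1", "expB"): (0.1, -0.2, 0.05, -0.1),
            ("g2", "expA"): (-1.5, -1.6, -1.4),
            ("g2", "expB"): (0.0,),
            ("g3", "expA"): (0.0, 0.0, 0.0, 0.0),
        },
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 3000 genes, 60 experiments, planted structure."""
    return sn.generate_compendium(seed=42)


@pytest.fixture(scope="session")
def default_gene_states(default_dataset):
    compendium, _ = default_dataset
    res = sn.discretize_compendium(compendium)
    return res.states.drop_columns(res.under_replicated)


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted compendium for fast pipeline-level tests."""
    return sn.generate_compendium(
        n_genes=220,
        n_experiments=24,
        n_core=25,
        n_regulators=2,
        targets_per_regulator=3,
        n_pathways=5,
        genes_per_pathway=6,
        seed=11,
    )


def state_frame(rows, columns, array):
    return sn.DiscreteStateMatrix(
        pd.DataFrame(np.asarray(array, float), index=rows, columns=columns)
    )
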