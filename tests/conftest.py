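import numpy as np
import pandas as pd
import pytest

from xenosig import ExpressionMatrix, SimulationConfig, generate_xenograft, load_signature


@pytest.fixture(scope="session")
def signature():
    return load_signature()


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down synthetic experiment: full planted structure, fewer
    background genes, so tests stay fast."""
    return SimulationConfig(n_human_genes=300, n_mouse_genes=200, seed=7)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return generate_xenograft(small_config)


@pytest.fixture()
def tiny_matrix():
    """A hand-sized human matrix: 3 probes x 4 samples."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [5.0, 5.5, 6.0, 6.5]],
        index=["p1", "p2", "p3"],
        columns=["T1", "T2", "T3", "T4"],
    )
    return ExpressionMatrix(df, species="human", annotation={"p1": "GENE1", "p2": "GENE2"})
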