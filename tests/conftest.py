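import numpy as np
import pandas as pd
import pytest

from cocultnet import differential, synthetic
from cocultnet.io import ExpressionMatrix, GeneSet


@pytest.fixture(scope="session")
def default_truth():
    return synthetic.default_truth()


@pytest.fixture(scope="session")
def coculture_fixture(default_truth):
    """The default synthetic study: counts, log2-CPM, proteome table."""
    expr = synthetic.simulate_coculture(default_truth)
    libs = differential.effective_library_sizes(expr)
    log2 = differential.normalize_log2cpm(expr, library_sizes=libs)
    protein = synthetic.simulate_proteome(expr, default_truth)
    return {"expr": expr, "log2": log2, "protein": protein, "truth": default_truth}


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples on the log2 scale, two 2-sample conditions."""
    values = pd.DataFrame(
        {
            "S1": [1.0, 4.0, 2.0],
            "S2": [2.0, 4.0, 2.2],
            "S3": [3.0, 4.0, 4.1],
            "S4": [4.0, 4.0, 3.9],
        },
        index=["G1", "G2", "G3"],
    )
    ann = pd.DataFrame(
        {"condition": ["a", "a", "b", "b"], "cell_line": "x", "batch": 1},
        index=["S1", "S2", "S3", "S4"],
    )
    return ExpressionMatrix(values, "log2cpm", ann)


@pytest.fixture
def gene_set():
    return lambda name, *genes: GeneSet(name, frozenset(genes))
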