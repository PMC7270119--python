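import numpy as np
import pandas as pd
import pytest

from hetexpress.io import ExpressionMatrix, TrioDesign


@pytest.fixture
def trio_a() -> TrioDesign:
    return TrioDesign(cross_id="A", maternal_id="A_P1", paternal_id="A_P2", hybrid_id="A_F1")


@pytest.fixture
def trio_b() -> TrioDesign:
    return TrioDesign(cross_id="B", maternal_id="B_P1", paternal_id="B_P2", hybrid_id="B_F1")


@pytest.fixture
def small_matrix(trio_a) -> ExpressionMatrix:
    """Three hand-picked genes for one cross: up-up, down-down, mixed."""
    values = pd.DataFrame(
        {
            "A_P1": [10.0, 40.0, 10.0],
            "A_F1": [40.0, 10.0, 40.0],
            "A_P2": [10.0, 40.0, 100.0],
        },
        index=pd.Index(["g_up", "g_down", "g_mixed"], name="gene_id"),
    )
    return ExpressionMatrix(values)


def write_expression_tsv(path, values: pd.DataFrame) -> str:
    values.to_csv(path, sep="\t")
    return str(path)
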