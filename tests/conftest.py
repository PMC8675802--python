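import numpy as np
import pandas as pd
import pytest

from rbmgrn import ExpressionMatrix, fixture_tables


@pytest.fixture(scope="session")
def tables() -> dict[str, pd.DataFrame]:
    return fixture_tables()


@pytest.fixture()
def raw_matrix(tables) -> ExpressionMatrix:
    """The 5x6 raw worked-example matrix."""
    return ExpressionMatrix(tables["table1"].copy())


@pytest.fixture()
def normalized_gene1(tables) -> np.ndarray:
    """Gene 1's normalized row: a valid [0, 1] training vector of length 6."""
    return tables["table2"].loc["Gene1"].to_numpy()
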