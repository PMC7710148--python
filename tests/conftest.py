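import numpy as np
import pandas as pd
import pytest

from multigsa import (
    DataType,
    ExpressionDataset,
    GeneSet,
    GeneSetCollection,
    TwoGroupDesign,
)


def two_group_design(n_ref: int, n_cmp: int) -> TwoGroupDesign:
    groups = {f"r{i}": "low" for i in range(n_ref)}
    groups.update({f"c{i}": "high" for i in range(n_cmp)})
    return TwoGroupDesign(
        comparison_variable="grp",
        reference_group="low",
        comparison_group="high",
        groups=groups,
    )


def make_dataset(
    matrix: np.ndarray,
    data_type: DataType = DataType.MICROARRAY_INTENSITY,
    name: str = "toy",
) -> ExpressionDataset:
    """Dataset whose first half of columns is the reference group."""
    g, n = matrix.shape
    n_ref = n // 2
    cols = [f"r{i}" for i in range(n_ref)] + [f"c{i}" for i in range(n - n_ref)]
    df = pd.DataFrame(
        matrix, index=[f"g{i}" for i in range(g)], columns=cols
    )
    return ExpressionDataset(
        name=name,
        matrix=df,
        data_type=data_type,
        design=two_group_design(n_ref, n - n_ref),
    )


@pytest.fixture
def toy_counts_dataset() -> ExpressionDataset:
    rng = np.random.default_rng(7)
    counts = rng.poisson(50, size=(30, 6)).astype(float)
    return make_dataset(counts, DataType.RNASEQ_RAW_COUNTS, "counts_toy")


@pytest.fixture
def toy_collection() -> GeneSetCollection:
    return GeneSetCollection(
        [
            GeneSet("P1", "first", frozenset({"g0", "g1", "g2", "g3"})),
            GeneSet("P2", "second", frozenset({"g2", "g3", "g4", "g5"})),
            GeneSet("P3", "third", frozenset({"g10", "g11", "g12"})),
        ]
    )
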