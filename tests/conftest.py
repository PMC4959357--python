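import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mlcrv import EST, LayerTable, normalize_est, table1_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def table1_est() -> EST:
    """The packaged 6-example worked-example similarity table (unrounded)."""
    return normalize_est(table1_fixture())


@pytest.fixture
def mixed_layer() -> LayerTable:
    """Small mixed-type layer with missing values in both column kinds."""
    values = pd.DataFrame(
        {
            "age": np.array([61.0, 72.5, np.nan, 55.0, 80.0, 67.0]),
            "score": np.array([3.0, 1.5, 2.0, np.nan, 4.5, 2.5]),
            "vol": np.array([5.5, 6.1, 6.4, 5.9, np.nan, 7.0]),
            "sex": np.array(["f", "m", None, "f", "m", "f"], dtype=object),
            "apoe": np.array(["e3", "e4", "e3", "e2", "e4", None], dtype=object),
        }
    )
    return LayerTable(
        name="clinical",
        example_ids=[f"p{i}" for i in range(6)],
        attributes=[
            ("age", "numeric"),
            ("score", "numeric"),
            ("vol", "numeric"),
            ("sex", "categorical"),
            ("apoe", "categorical"),
        ],
        values=values,
    )


def random_symmetric_est(rng: np.random.Generator, n: int, layer: str = "rand") -> EST:
    """Random similarity table in [0, 1] with unit diagonal, max exactly 1."""
    raw = rng.random((n, n))
    sym = (raw + raw.T) / 2
    np.fill_diagonal(sym, 1.0)
    return EST(matrix=sym, layer=layer, normalizer=1)


def ssd_oracle(values) -> float:
    """Textbook sum of squared deviates, independent of the package's path."""
    values = list(values)
    mean = sum(values) / len(values)
    return sum((v - mean) ** 2 for v in values)


def cluster_crv_oracle(matrix, cluster) -> float:
    """Brute-force CRV of a cluster: per-member within + outside deviate sums."""
    n = len(matrix)
    total = 0.0
    for i in cluster:
        inside = [matrix[i][j] for j in cluster]
        outside = [matrix[i][j] for j in range(n) if j not in cluster]
        total += ssd_oracle(inside)
        if outside:
            total += ssd_oracle(outside)
    return total


def block_est(blocks, n, within=0.9, cross=0.05, diagonal=1.0, layer="blocks") -> EST:
    """EST with planted blocks: high similarity inside, low across."""
    m = np.full((n, n), cross)
    for block in blocks:
        for i in block:
            for j in block:
                m[i, j] = within
    np.fill_diagonal(m, diagonal)
    return EST(matrix=m, layer=layer, normalizer=1)
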