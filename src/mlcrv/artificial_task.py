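"""The artificial real-vs-shuffled classification task.

Similarity estimation turns the unsupervised layer into a supervised problem:
the original examples are the positive class, and negatives are copies whose
values have been independently permuted *within each attribute column*.  The
negatives therefore keep every per-attribute marginal distribution (including
the missingness rate) but lose all co-occurrence between attributes — a rule
that beats chance on this task must capture jointly occurring attribute
values, which is exactly the structure clustering should recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layers_io import LayerTable, NUMERIC

__all__ = ["ArtificialTask", "make_artificial_task"]


@dataclass
class ArtificialTask:
    """Positives (the original layer) plus per-attribute shuffled negatives."""

    positives: LayerTable
    negatives: LayerTable

    @property
    def n_pos(self) -> int:
        return self.positives.n_examples

    @property
    def n_neg(self) -> int:
        return self.negatives.n_examples


def make_artificial_task(
    layer: LayerTable, rng: np.random.Generator, *, neg_ratio: int = 1
) -> ArtificialTask:
    """Build the two-class task for one layer.

    Each attribute column of the negatives is an independent uniform random
    permutation of the positive column; missing cells are permuted along with
    the values, so per-column value multisets (missing included) are preserved
    exactly.  ``neg_ratio`` shuffled copies are stacked (default 1, making
    "better than random" equal to precision above 0.5).
    """
    n = layer.n_examples
    neg_cols: dict[str, np.ndarray] = {}
    for attr, kind in layer.attributes:
        col = layer.values[attr].to_numpy()
        pieces = [col[rng.permutation(n)] for _ in range(neg_ratio)]
        neg_cols[attr] = np.concatenate(pieces)
    neg_frame = pd.DataFrame(neg_cols, index=pd.RangeIndex(n * neg_ratio))
    for attr, kind in layer.attributes:
        if kind == NUMERIC:
            neg_frame[attr] = neg_frame[attr].astype(float)
    negatives = LayerTable(
        name=f"{layer.name}::shuffled",
        example_ids=[f"neg{i}" for i in range(n * neg_ratio)],
        attributes=list(layer.attributes),
        values=neg_frame,
    )
    return ArtificialTask(positives=layer, negatives=negatives)
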