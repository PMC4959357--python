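"""Example similarity table (EST): normalized rule co-coverage.

The raw co-coverage counts are turned into similarities ``v_ij`` in
``[0, 1]`` by dividing the whole matrix by its single largest entry —
diagonal included, since the global maximum is typically (and in the packaged
worked example is) a diagonal count.  Values are kept at full floating
precision; downstream variability scores are sensitive to premature rounding.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .layers_io import InputError
from .rules import CoverageCounts

__all__ = ["EST", "normalize_est", "write_est"]


@dataclass
class EST:
    """N x N symmetric similarity matrix with values in [0, 1]."""

    matrix: np.ndarray  # float64
    layer: str = ""
    normalizer: int = 0  # the maximal raw count used as divisor

    @property
    def n_examples(self) -> int:
        return self.matrix.shape[0]


def normalize_est(counts: CoverageCounts) -> EST:
    """Divide every cell of the count matrix by its global maximum."""
    m = np.asarray(counts.matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InputError("co-coverage counts must form a square matrix")
    if (m < 0).any():
        raise InputError("co-coverage counts must be nonnegative")
    if not np.array_equal(m, m.T):
        raise InputError("co-coverage counts must be symmetric")
    top = int(m.max())
    if top == 0:
        raise InputError("no rule covered any example; cannot normalize an all-zero table")
    return EST(matrix=m.astype(np.float64) / top, layer=counts.layer, normalizer=top)


def write_est(est: EST, path: str | Path, example_ids: list[str] | None = None) -> None:
    """Export an EST as CSV with example ids as header and row labels."""
    ids = example_ids or [f"r{i}" for i in range(est.n_examples)]
    if len(ids) != est.n_examples:
        raise InputError("example id list does not match EST dimension")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([""] + ids)
        for i, row in enumerate(est.matrix):
            w.writerow([ids[i]] + [repr(float(v)) for v in row])
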