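"""The clustering-related variability (CRV) score and the DIFF merge gain.

For an example ``i`` in cluster ``C`` over an EST with rows ``v_i``:

* within-cluster component  ``CRV_i,wc = sum_{j in C} (v_ij - mean_{j in C} v_ij)^2``
  (the diagonal ``v_ii`` belongs to the within set, so a singleton has
  ``CRV_i,wc = 0``);
* outside-cluster component ``CRV_i,oc = sum_{j not in C} (v_ij - mean_{j not in C} v_ij)^2``
  (defined as 0 when the cluster already contains all examples);
* ``CRV_i = CRV_i,wc + CRV_i,oc``   and   ``CRV_C = sum_{i in C} CRV_i``.

The merge gain of two disjoint clusters is
``DIFF(a, b) = CRV_a + CRV_b - CRV_{a u b}``; a positive DIFF means merging
reduces the variability of the similarity estimates.  All arithmetic is full
precision; ``round_components=True`` reproduces the three-decimal per-example
component rounding used in printed walk-throughs of the score (which sum the
rounded components, e.g. a merged-cluster CRV of 0.030 where full precision
gives 0.031).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection

import numpy as np

from .est import EST
from .layers_io import UsageError

__all__ = ["CRVBreakdown", "example_crv", "cluster_crv", "merge_diff"]


@dataclass
class CRVBreakdown:
    """Per-example CRV components and the means they were taken around."""

    wc: float
    oc: float
    total: float
    mean_wc: float
    mean_oc: float  # NaN when the cluster contains all examples


def _as_members(cluster: Collection[int], n: int) -> np.ndarray:
    members = np.asarray(sorted(set(int(i) for i in cluster)), dtype=np.intp)
    if members.size == 0:
        raise UsageError("cluster is empty")
    if members.size != len(cluster):
        raise UsageError("cluster contains duplicate member indices")
    if members[0] < 0 or members[-1] >= n:
        raise UsageError(f"cluster members out of range 0..{n - 1}")
    return members


def _ssd(values: np.ndarray) -> tuple[float, float]:
    """Sum of squared deviates from the mean, and the mean."""
    mean = float(values.mean())
    return float(((values - mean) ** 2).sum()), mean


def example_crv(
    est: EST, i: int, cluster: Collection[int], *, round_components: bool = False
) -> CRVBreakdown:
    """CRV breakdown of example ``i`` within the cluster containing it."""
    n = est.n_examples
    members = _as_members(cluster, n)
    if i not in members:
        raise UsageError(f"example {i} is not a member of the given cluster")
    row = est.matrix[i]
    in_c = np.zeros(n, dtype=bool)
    in_c[members] = True
    wc, mean_wc = _ssd(row[in_c])
    if in_c.all():
        oc, mean_oc = 0.0, float("nan")
    else:
        oc, mean_oc = _ssd(row[~in_c])
    if round_components:
        wc, oc = round(wc, 3), round(oc, 3)
    return CRVBreakdown(wc=wc, oc=oc, total=wc + oc, mean_wc=mean_wc, mean_oc=mean_oc)


def cluster_crv(est: EST, cluster: Collection[int], *, round_components: bool = False) -> float:
    """CRV of a cluster: sum of its members' per-example CRV totals."""
    members = _as_members(cluster, est.n_examples)
    return float(
        sum(
            example_crv(est, int(i), members, round_components=round_components).total
            for i in members
        )
    )


def merge_diff(
    est: EST, a: Collection[int], b: Collection[int], *, round_components: bool = False
) -> float:
    """Variability reduction achieved by merging two disjoint clusters."""
    ma = _as_members(a, est.n_examples)
    mb = _as_members(b, est.n_examples)
    if np.intersect1d(ma, mb).size:
        raise UsageError("clusters to merge must be disjoint")
    union = np.concatenate([ma, mb])
    return (
        cluster_crv(est, ma, round_components=round_components)
        + cluster_crv(est, mb, round_components=round_components)
        - cluster_crv(est, union, round_components=round_components)
    )
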