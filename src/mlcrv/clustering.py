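"""Bottom-up cluster merging driven by CRV reduction, in one or more layers.

Starting from all-singleton clusters, every iteration scores every pair of
current clusters by its merge gain DIFF (per layer), takes the minimum over
layers, and merges the pair with the largest minimal gain — provided that
gain is strictly positive, i.e. merging reduces variability in *every*
layer.  The process stops as soon as no pair qualifies, which gives the
algorithm an intrinsic stopping criterion: the number of clusters is not a
parameter, and examples may simply remain unclustered (singleton clusters).

With a single layer the multi-layer rule degenerates exactly to the
single-layer algorithm.  Requiring simultaneous gains in several layers is a
conjunction of necessary conditions, so multi-layer clusters are never
coarser than what each layer alone would support.

All pair gains are recomputed from the current partition at every iteration
(CRV of an untouched cluster still changes when any other cluster changes,
because its members' outside-cluster sets shift).  The scan over pairs is
quadratic in the number of clusters, which makes the whole procedure suitable
for cohorts of up to a few thousand examples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .est import EST, normalize_est
from .layers_io import LayerTable, RunConfig, UsageError, align_layers

__all__ = [
    "Clustering",
    "MergeRecord",
    "MergeTrace",
    "single_layer_cluster",
    "multi_layer_cluster",
    "run_pipeline",
]

#: Positivity guard for merge gains: gains within round-off of zero do not
#: count as reductions (a mathematically zero DIFF can otherwise surface as
#: ~1e-16 and trigger spurious merges on degenerate similarity tables).
DIFF_EPS = 1e-12


@dataclass
class Clustering:
    """A partition of the N examples; clusters are sorted member tuples."""

    clusters: list[tuple[int, ...]]
    n_examples: int
    example_ids: list[str] | None = None

    def __post_init__(self) -> None:
        seen = [i for c in self.clusters for i in c]
        if sorted(seen) != list(range(self.n_examples)):
            raise UsageError("clusters must partition 0..N-1")

    def labels(self) -> np.ndarray:
        """Integer cluster label per example; singletons get label -1."""
        out = np.full(self.n_examples, -1, dtype=int)
        next_label = 0
        for members in self.clusters:
            if len(members) > 1:
                out[list(members)] = next_label
                next_label += 1
        return out

    @property
    def n_unclustered(self) -> int:
        return sum(1 for c in self.clusters if len(c) == 1)


@dataclass
class MergeRecord:
    iteration: int
    merged: tuple[tuple[int, ...], tuple[int, ...]]
    diff_per_layer: dict[str, float]
    min_diff: float


@dataclass
class MergeTrace:
    records: list[MergeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_records(self, example_ids: list[str] | None = None) -> list[dict]:
        def name(i: int) -> object:
            return example_ids[i] if example_ids else i

        return [
            {
                "iteration": r.iteration,
                "merged": [[name(i) for i in side] for side in r.merged],
                "diff_per_layer": dict(r.diff_per_layer),
                "min_diff": r.min_diff,
            }
            for r in self.records
        ]


def _layer_diff_matrix(v: np.ndarray, clusters: list[tuple[int, ...]]) -> np.ndarray:
    """All pairwise merge gains for one layer's EST, for the current partition.

    Uses the sum / sum-of-squares identity for each squared-deviate sum, so
    one pass over cluster members prices every candidate partner at once;
    the result matches the definitional ``merge_diff`` to round-off.
    """
    n = v.shape[0]
    k = len(clusters)
    v2 = v * v
    row_sum = v.sum(axis=1)
    row_sq = v2.sum(axis=1)
    sizes = np.array([len(c) for c in clusters], dtype=np.intp)
    cs = np.empty((n, k))
    cs2 = np.empty((n, k))
    for c, members in enumerate(clusters):
        idx = list(members)
        cs[:, c] = v[:, idx].sum(axis=1)
        cs2[:, c] = v2[:, idx].sum(axis=1)

    crv = np.empty(k)
    contrib = np.empty((k, k))  # contrib[a, b]: a's members' share of CRV_{a u b}
    for c, members in enumerate(clusters):
        idx = list(members)
        s, s2 = cs[idx, c], cs2[idx, c]
        wc = s2 - s * s / sizes[c]
        rem = n - sizes[c]
        if rem > 0:
            oc = (row_sq[idx] - s2) - (row_sum[idx] - s) ** 2 / rem
        else:
            oc = 0.0
        crv[c] = np.sum(wc + oc)

        ps = cs[idx, :] + s[:, None]
        ps2 = cs2[idx, :] + s2[:, None]
        m_pair = sizes + sizes[c]
        wc_p = ps2 - ps * ps / m_pair
        rem_p = n - m_pair
        safe = np.where(rem_p > 0, rem_p, 1)
        oc_p = (row_sq[idx][:, None] - ps2) - (row_sum[idx][:, None] - ps) ** 2 / safe
        oc_p = np.where(rem_p > 0, oc_p, 0.0)
        contrib[c, :] = (wc_p + oc_p).sum(axis=0)

    return crv[:, None] + crv[None, :] - (contrib + contrib.T)


def multi_layer_cluster(ests: Sequence[EST]) -> tuple[Clustering, MergeTrace]:
    """Greedy best-first merging under the all-layers gain criterion."""
    if not ests:
        raise UsageError("need at least one EST")
    n = ests[0].n_examples
    for e in ests[1:]:
        if e.n_examples != n:
            raise UsageError("all ESTs must have the same dimension")
    layer_names = []
    for k, e in enumerate(ests):
        base = e.layer or f"layer{k}"
        name = base
        suffix = 2
        while name in layer_names:  # keep trace keys unique per layer
            name = f"{base}.{suffix}"
            suffix += 1
        layer_names.append(name)
    matrices = [np.asarray(e.matrix, dtype=np.float64) for e in ests]

    clusters: list[tuple[int, ...]] = [(i,) for i in range(n)]
    trace = MergeTrace()
    iteration = 0
    while len(clusters) > 1:
        per_layer = [_layer_diff_matrix(v, clusters) for v in matrices]
        min_diff = np.minimum.reduce(per_layer)
        k = len(clusters)
        upper = np.triu(np.ones((k, k), dtype=bool), 1)
        best = min_diff[upper].max()
        if best <= DIFF_EPS:
            break
        # ties resolved by the lexicographically smallest pair of minimal
        # member indices: clusters are kept sorted by smallest member, so the
        # first hit in row-major upper-triangle order is the canonical one
        a, b = np.argwhere(upper & (min_diff == best))[0]
        iteration += 1
        left, right = clusters[a], clusters[b]
        trace.records.append(
            MergeRecord(
                iteration=iteration,
                merged=(left, right),
                diff_per_layer={
                    name: float(d[a, b]) for name, d in zip(layer_names, per_layer)
                },
                min_diff=float(best),
            )
        )
        merged = tuple(sorted(left + right))
        clusters = [c for j, c in enumerate(clusters) if j not in (a, b)]
        clusters.append(merged)
        clusters.sort(key=lambda c: c[0])
    return Clustering(clusters=clusters, n_examples=n), trace


def single_layer_cluster(est: EST) -> tuple[Clustering, MergeTrace]:
    """Single-layer variant: the multi-layer rule with one layer."""
    return multi_layer_cluster([est])


def run_pipeline(
    layers: Sequence[LayerTable], config: RunConfig
) -> tuple[Clustering, MergeTrace, list[EST]]:
    """Full run: per layer, artificial task -> rule ensemble -> EST; then merge.

    Per-layer randomness comes from sub-seeds at fixed offsets from the
    master seed, so adding a layer does not perturb the others and the whole
    run is reproducible bit-for-bit for a fixed seed.
    """
    from .artificial_task import make_artificial_task
    from .rules import build_ensemble, count_cocoverage

    layers = align_layers(layers)
    ests: list[EST] = []
    for li, layer in enumerate(layers):
        rng = np.random.default_rng(config.seed + 100_003 * (li + 1))
        task = make_artificial_task(layer, rng, neg_ratio=config.neg_ratio)
        ensemble = build_ensemble(task, config, rng)
        counts = count_cocoverage(ensemble, layer.n_examples)
        ests.append(normalize_est(counts))
    clustering, trace = multi_layer_cluster(ests)
    clustering.example_ids = list(layers[0].example_ids)
    return clustering, trace, ests
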