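"""Post-hoc cluster characterization: attribute means and label composition.

The merge engine reports many clusters, often small; in practice an analyst
inspects a handful of large ones.  These utilities compute per-cluster
descriptive summaries (means of numeric attributes over non-missing member
values, category frequencies for categorical ones) and, when a held-out
label such as a diagnosis is available, the cluster-by-label contingency
counts.  Descriptive statistics only — no significance testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .clustering import Clustering
from .layers_io import ConfigError, LayerTable, UsageError, CATEGORICAL, NUMERIC

__all__ = ["ClusterProfile", "cluster_profile", "label_composition"]

UNCLUSTERED = "unclustered"
OTHER_SMALL = "other_small"


@dataclass
class ClusterProfile:
    """Per-cluster sizes, numeric means and category frequencies.

    ``sizes`` covers every example: reported clusters, the ``unclustered``
    pseudo-group of singletons, and (when present) an ``other_small``
    aggregate of non-singleton clusters below the reporting threshold.
    """

    sizes: pd.Series
    means: pd.DataFrame  # reported groups x numeric attributes
    category_frequencies: dict[str, dict[str, dict[str, int]]]  # group -> attr -> counts
    members: dict[str, list[int]] = field(default_factory=dict)


def _group_examples(
    clustering: Clustering, min_size: int, top_k: int | None
) -> dict[str, list[int]]:
    if min_size < 1:
        raise ConfigError("min_size must be >= 1")
    big = sorted(
        (c for c in clustering.clusters if len(c) >= max(min_size, 2)),
        key=lambda c: (-len(c), c[0]),
    )
    if top_k is not None:
        big = big[:top_k]
    reported = set(i for c in big for i in c)
    groups = {f"C{j + 1}": list(c) for j, c in enumerate(big)}
    singles = [c[0] for c in clustering.clusters if len(c) == 1]
    if singles:
        groups[UNCLUSTERED] = sorted(singles)
    leftover = [
        i
        for c in clustering.clusters
        if len(c) > 1
        for i in c
        if i not in reported
    ]
    if leftover:
        groups[OTHER_SMALL] = sorted(leftover)
    return groups


def cluster_profile(
    clustering: Clustering,
    layers: Sequence[LayerTable],
    *,
    min_size: int = 5,
    top_k: int | None = None,
) -> ClusterProfile:
    """Summarize clusters of size >= ``min_size`` (optionally only the ``top_k`` largest).

    Groups are ordered by size, descending; singletons are pooled into an
    ``unclustered`` pseudo-group.  Means use non-missing member values only.
    """
    for layer in layers:
        if layer.n_examples != clustering.n_examples:
            raise UsageError("layer and clustering cover different example sets")
    groups = _group_examples(clustering, min_size, top_k)
    sizes = pd.Series({g: len(idx) for g, idx in groups.items()}, name="size")

    mean_rows: dict[str, dict[str, float]] = {g: {} for g in groups}
    cat_freqs: dict[str, dict[str, dict[str, int]]] = {g: {} for g in groups}
    for layer in layers:
        for attr, kind in layer.attributes:
            col = layer.values[attr]
            key = f"{layer.name}.{attr}" if len(layers) > 1 else attr
            for g, idx in groups.items():
                sub = col.iloc[idx]
                if kind == NUMERIC:
                    mean_rows[g][key] = float(sub.mean())  # skips NaN
                else:
                    counts = sub.dropna().value_counts()
                    cat_freqs[g][key] = {str(c): int(v) for c, v in counts.items()}
    means = pd.DataFrame.from_dict(mean_rows, orient="index").loc[list(groups)]
    return ClusterProfile(
        sizes=sizes, means=means, category_frequencies=cat_freqs, members=groups
    )


def label_composition(
    clustering: Clustering,
    labels: Sequence,
    *,
    min_size: int = 1,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Contingency counts of reported clusters against a held-out label.

    Rows are reported groups (plus pseudo-groups), columns label values; row
    sums equal group sizes.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != clustering.n_examples:
        raise UsageError(
            f"label vector has length {labels.shape[0]}, clustering covers "
            f"{clustering.n_examples} examples"
        )
    groups = _group_examples(clustering, max(min_size, 1), top_k)
    values = sorted(set(labels.tolist()), key=str)
    table = pd.DataFrame(0, index=list(groups), columns=values, dtype=int)
    for g, idx in groups.items():
        for v, cnt in zip(*np.unique(labels[idx], return_counts=True)):
            table.loc[g, v] = int(cnt)
    return table
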