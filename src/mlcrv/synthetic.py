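"""Synthetic inputs: a packaged worked-example count table and a cohort simulator.

The simulator emulates the situation the clustering method targets: a cohort
of ``n`` examples containing ``k`` latent subpopulations, each defined by
*co-occurring* attribute values expressed in every layer (the way, say, a
disease subtype shows up jointly in clinical scores and in biomarkers), plus
a fraction of background examples drawn from the pooled per-attribute
marginals — structure-free by construction, since marginals alone carry no
co-occurrence.  Group labels are returned separately and never placed in the
layers, mirroring how a held-out diagnosis is used for evaluation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layers_io import ConfigError, LayerTable, write_layer, CATEGORICAL, NUMERIC
from .rules import CoverageCounts

__all__ = ["TABLE1_EXAMPLE_IDS", "table1_fixture", "CohortParams", "SyntheticCohort", "generate_cohort", "write_cohort"]


TABLE1_EXAMPLE_IDS = ["ex1", "ex2", "ex3", "ex4", "ex5", "ex6"]

# 6-example rule co-coverage table from the method's published walk-through;
# diagonal = rules covering each example, global maximum 140 at (ex2, ex2).
_TABLE1_COUNTS = np.array(
    [
        [72, 5, 51, 48, 0, 19],
        [5, 140, 11, 4, 118, 20],
        [51, 11, 87, 62, 6, 9],
        [48, 4, 62, 91, 12, 7],
        [0, 118, 6, 12, 125, 18],
        [19, 20, 9, 7, 18, 55],
    ],
    dtype=np.int64,
)


def table1_fixture() -> CoverageCounts:
    """The packaged 6x6 worked-example co-coverage count matrix."""
    return CoverageCounts(matrix=_TABLE1_COUNTS.copy(), layer="table1")


@dataclass
class CohortParams:
    """Generator settings.

    ``signal`` in [0, 1] controls how sharply group members concentrate on
    their group prototype: numeric group centers are offset by ``signal``
    times a per-group effect (on a spread-3 scale) with residual spread
    ``1 - signal``; categorical members adopt the group's modal category with
    probability ``signal`` and draw uniformly otherwise.  At ``signal = 0``
    group members are indistinguishable from background noise.
    """

    n: int = 90
    k: int = 3
    attrs_per_layer: int = 10
    n_layers: int = 2
    signal: float = 0.9
    noise_fraction: float = 0.2
    missing_rate: float = 0.05
    seed: int = 0
    n_categories: int = 4
    numeric_fraction: float = 0.5
    #: Optional restriction of a group's signal to a single layer (group id ->
    #: layer index); in other layers its members draw from pooled marginals,
    #: which exercises the multi-layer no-merge behaviour.
    group_layer_only: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 1 or self.n < 2 * self.k:
            raise ConfigError("need n >= 2k so every planted group has >= 2 members")
        if self.attrs_per_layer < 5:
            raise ConfigError("need at least 5 attributes per layer")
        if self.n_layers < 1:
            raise ConfigError("need at least one layer")
        if not (0.0 <= self.signal <= 1.0):
            raise ConfigError("signal must lie in [0, 1]")
        if not (0.0 <= self.noise_fraction < 1.0) or not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("noise_fraction and missing_rate must lie in [0, 1)")


@dataclass
class SyntheticCohort:
    layers: list[LayerTable]
    labels: np.ndarray  # planted group per example; 0 = background noise
    params: CohortParams


#: Separation scale of numeric group centers, in units of the base spread.
_CENTER_SCALE = 3.0


def generate_cohort(params: CohortParams) -> SyntheticCohort:
    """Simulate a multi-layer cohort with planted co-occurrence structure."""
    rng = np.random.default_rng(params.seed)
    n, k = params.n, params.k

    n_noise = int(round(params.noise_fraction * n))
    n_struct = n - n_noise
    if n_struct < 2 * k:
        raise ConfigError("noise fraction leaves too few structured examples")
    base = n_struct // k
    group_sizes = [base + (1 if g < n_struct % k else 0) for g in range(k)]
    labels = np.zeros(n, dtype=int)
    order = rng.permutation(n)
    pos = 0
    for g, size in enumerate(group_sizes, start=1):
        labels[order[pos : pos + size]] = g
        pos += size
    weights = np.array(group_sizes, dtype=float) / n_struct

    m_num = int(round(params.numeric_fraction * params.attrs_per_layer))
    layer_tables: list[LayerTable] = []
    for li in range(params.n_layers):
        columns: dict[str, np.ndarray] = {}
        attributes: list[tuple[str, str]] = []
        for j in range(params.attrs_per_layer):
            numeric = j < m_num
            attr = f"L{li + 1}_{'num' if numeric else 'cat'}{j + 1}"
            # per-group effective signal in this layer
            s_g = np.array(
                [
                    params.signal
                    if params.group_layer_only.get(g + 1, li) == li
                    else 0.0
                    for g in range(k)
                ]
            )
            if numeric:
                centers = rng.normal(0.0, _CENTER_SCALE, size=k)
                col = np.empty(n, dtype=float)
                for i in range(n):
                    # noise draws from the pooled marginal: a random group's
                    # distribution, independently per attribute — marginals
                    # match the structured examples but co-occurrence is gone
                    g = labels[i] if labels[i] > 0 else int(rng.choice(k, p=weights)) + 1
                    s = s_g[g - 1]
                    col[i] = s * centers[g - 1] + (1.0 - s) * rng.normal()
                attributes.append((attr, NUMERIC))
                columns[attr] = col
            else:
                modal = rng.integers(params.n_categories, size=k)
                cats = [f"c{q}" for q in range(params.n_categories)]
                col = np.empty(n, dtype=object)
                for i in range(n):
                    g = labels[i] if labels[i] > 0 else int(rng.choice(k, p=weights)) + 1
                    s = s_g[g - 1]
                    if rng.random() < s:
                        col[i] = cats[int(modal[g - 1])]
                    else:
                        col[i] = cats[int(rng.integers(params.n_categories))]
                attributes.append((attr, CATEGORICAL))
                columns[attr] = col
        if params.missing_rate > 0:
            for attr, kind in attributes:
                mask = rng.random(n) < params.missing_rate
                # keep at least one observed value per column
                if mask.all():
                    mask[int(rng.integers(n))] = False
                if kind == NUMERIC:
                    col = columns[attr]
                    col[mask] = np.nan
                else:
                    col = columns[attr]
                    col[mask] = None
        frame = pd.DataFrame(columns, index=pd.RangeIndex(n))
        layer_tables.append(
            LayerTable(
                name=f"layer{li + 1}",
                example_ids=[f"s{i + 1:04d}" for i in range(n)],
                attributes=attributes,
                values=frame,
            )
        )
    return SyntheticCohort(layers=layer_tables, labels=labels, params=params)


def write_cohort(cohort: SyntheticCohort, out: str | Path) -> dict[str, Path]:
    """Write one CSV per layer plus a held-out labels CSV."""
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for layer in cohort.layers:
        path = out / f"{layer.name}.csv"
        write_layer(layer, path)
        written[layer.name] = path
    labels_path = out / "labels.csv"
    pd.DataFrame(
        {"id": cohort.layers[0].example_ids, "group": cohort.labels}
    ).to_csv(labels_path, index=False)
    written["labels"] = labels_path
    return written
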