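"""Multi-layer tabular input/output and run configuration.

A *layer* is one table of attributes (numeric and/or categorical, missing
values allowed) over a shared, ordered set of examples.  Several layers over
the same examples form a multi-layer cohort, e.g. clinical descriptors in one
table and biological measurements in another.  This module reads and validates
such tables, checks cross-layer alignment, and writes clustering results.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MlcrvError",
    "LayerFormatError",
    "InputError",
    "AlignmentError",
    "ConfigError",
    "UsageError",
    "LayerTable",
    "RunConfig",
    "DEFAULT_MISSING_TOKENS",
    "read_layer",
    "write_layer",
    "align_layers",
    "write_results",
]

NUMERIC = "numeric"
CATEGORICAL = "categorical"

#: Cell contents interpreted as missing on input (configurable per call).
DEFAULT_MISSING_TOKENS = ("", "NA")

#: Layers narrower than this trigger a warning: similarity estimation relies
#: on co-occurrence across many attributes and degrades on very narrow tables.
MIN_RECOMMENDED_ATTRIBUTES = 5


class MlcrvError(Exception):
    """Base class for all package errors."""


class LayerFormatError(MlcrvError):
    """Malformed input file (ragged rows, missing header...)."""


class InputError(MlcrvError):
    """Well-formed file whose content violates a layer invariant."""


class AlignmentError(MlcrvError):
    """Layers do not share the same examples in the same order."""


class ConfigError(MlcrvError):
    """Invalid run configuration."""


class UsageError(MlcrvError):
    """API misuse (e.g. example not member of the cluster passed with it)."""


@dataclass
class LayerTable:
    """One attribute layer: an N x M mixed-type table over ordered examples.

    Numeric columns are held as float (``NaN`` = missing); categorical columns
    as object arrays of strings (``None`` = missing).
    """

    name: str
    example_ids: list[str]
    attributes: list[tuple[str, str]]  # (attribute name, kind)
    values: pd.DataFrame  # N x M; columns match attribute names

    def __post_init__(self) -> None:
        n, m = self.values.shape
        if n < 2:
            raise InputError(f"layer {self.name!r}: need at least 2 examples, got {n}")
        if m < 1:
            raise InputError(f"layer {self.name!r}: need at least 1 attribute")
        if len(self.example_ids) != n:
            raise InputError(f"layer {self.name!r}: {len(self.example_ids)} ids for {n} rows")
        if len(self.attributes) != m:
            raise InputError(f"layer {self.name!r}: attribute list does not match table width")
        for attr, kind in self.attributes:
            if kind not in (NUMERIC, CATEGORICAL):
                raise InputError(f"layer {self.name!r}: unknown kind {kind!r} for {attr!r}")
            col = self.values[attr]
            if col.isna().all():
                raise InputError(f"layer {self.name!r}: column {attr!r} is entirely missing")
        if m < MIN_RECOMMENDED_ATTRIBUTES:
            warnings.warn(
                f"layer {self.name!r} has only {m} attributes; similarity estimates "
                "from rule co-coverage are unreliable on very narrow tables",
                stacklevel=2,
            )
        if len(set(self.example_ids)) != n:
            warnings.warn(f"layer {self.name!r} contains duplicated example ids", stacklevel=2)

    @property
    def n_examples(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def attribute_kind(self, attr: str) -> str:
        for name, kind in self.attributes:
            if name == attr:
                return kind
        raise KeyError(attr)


@dataclass
class RunConfig:
    """Parameters of a full similarity-estimation + clustering run.

    ``n_rules`` is the size of the rule ensemble per layer (50,000 is the
    production default; far smaller ensembles suffice for small cohorts).
    ``min_rule_precision`` is a strict lower bound: a rule is retained only if
    its precision on the artificial real-vs-shuffled task *exceeds* it, i.e.
    the rule is better than a random classifier at the default 1:1 class ratio.
    """

    n_rules: int = 50_000
    max_conditions_per_rule: int = 3
    min_rule_precision: float = 0.5
    neg_ratio: int = 1
    seed: int = 0
    layers: list[str] = field(default_factory=list)
    output_dir: str = "results"
    emit_est: bool = False

    def __post_init__(self) -> None:
        if self.n_rules < 1:
            raise ConfigError(f"n_rules must be >= 1, got {self.n_rules}")
        if self.max_conditions_per_rule < 1:
            raise ConfigError("max_conditions_per_rule must be >= 1")
        if not (0.5 <= self.min_rule_precision < 1.0):
            raise ConfigError(
                f"min_rule_precision must lie in [0.5, 1.0), got {self.min_rule_precision}"
            )
        if self.neg_ratio < 1:
            raise ConfigError("neg_ratio must be >= 1")


def _infer_kind(raw: Sequence[str | None]) -> str:
    """A column is numeric iff every non-missing cell parses as a float."""
    seen = False
    for cell in raw:
        if cell is None:
            continue
        seen = True
        try:
            float(cell)
        except ValueError:
            return CATEGORICAL
    return NUMERIC if seen else CATEGORICAL


def read_layer(
    path: str | Path,
    *,
    name: str | None = None,
    delimiter: str | None = None,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    id_column: bool = False,
    kinds: dict[str, str] | None = None,
) -> LayerTable:
    """Read a CSV/TSV layer with a header row into a validated :class:`LayerTable`.

    Parameters
    ----------
    delimiter
        Field separator; inferred from the extension when omitted
        (``.tsv``/``.tab`` -> tab, else comma).
    missing_tokens
        Cell contents read as missing.  Both the empty string and ``"NA"``
        by default.
    id_column
        When true, the first column carries example identifiers; otherwise
        row order is identity and ids ``r0, r1, ...`` are assigned.
    kinds
        Optional per-attribute override of the inferred kind
        (``{"APOE4": "categorical"}``).
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    missing = set(missing_tokens)

    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    if not rows:
        raise LayerFormatError(f"{path}: empty file")
    header, body = rows[0], rows[1:]
    width = len(header)
    for k, row in enumerate(body, start=2):
        if len(row) != width:
            raise LayerFormatError(
                f"{path}: row {k} has {len(row)} fields, header has {width}"
            )
    if not body:
        raise InputError(f"{path}: no data rows")

    if id_column:
        ids = [row[0] for row in body]
        header = header[1:]
        body = [row[1:] for row in body]
        if not header:
            raise InputError(f"{path}: id column only, no attributes")
    else:
        ids = [f"r{i}" for i in range(len(body))]

    cells: list[list[str | None]] = [
        [None if cell in missing else cell for cell in row] for row in body
    ]
    columns: dict[str, object] = {}
    attributes: list[tuple[str, str]] = []
    for j, attr in enumerate(header):
        raw = [row[j] for row in cells]
        kind = (kinds or {}).get(attr) or _infer_kind(raw)
        if kind == NUMERIC:
            col = np.array([np.nan if c is None else float(c) for c in raw], dtype=float)
        else:
            col = np.array(raw, dtype=object)
        attributes.append((attr, kind))
        columns[attr] = col
    frame = pd.DataFrame(columns, index=pd.RangeIndex(len(body)))
    return LayerTable(name=name or path.stem, example_ids=ids, attributes=attributes, values=frame)


def write_layer(layer: LayerTable, path: str | Path, *, id_column: bool = True) -> None:
    """Write a layer back to CSV; round-trips values, kinds and missingness."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        out = csv.writer(fh)
        names = [a for a, _ in layer.attributes]
        out.writerow((["id"] if id_column else []) + names)
        for i in range(layer.n_examples):
            row: list[str] = [layer.example_ids[i]] if id_column else []
            for attr, kind in layer.attributes:
                v = layer.values[attr].iloc[i]
                if v is None or (kind == NUMERIC and np.isnan(v)):
                    row.append("")
                else:
                    row.append(repr(float(v)) if kind == NUMERIC else str(v))
            out.writerow(row)


def align_layers(layers: Sequence[LayerTable]) -> list[LayerTable]:
    """Verify all layers cover the same examples in the same order.

    Clustering operates on one shared example set; every layer must list
    identical ids in identical positions.  Returns the layers unchanged.
    """
    if not layers:
        raise AlignmentError("no layers given")
    ref = layers[0]
    for other in layers[1:]:
        if other.n_examples != ref.n_examples:
            raise AlignmentError(
                f"layer {other.name!r} has {other.n_examples} examples, "
                f"{ref.name!r} has {ref.n_examples}"
            )
        if other.example_ids != ref.example_ids:
            bad = [
                (i, a, b)
                for i, (a, b) in enumerate(zip(ref.example_ids, other.example_ids))
                if a != b
            ]
            shown = ", ".join(f"pos {i}: {a!r} vs {b!r}" for i, a, b in bad[:10])
            raise AlignmentError(
                f"layer {other.name!r} misaligned with {ref.name!r} at "
                f"{len(bad)} positions ({shown})"
            )
    return list(layers)


def write_results(clustering, trace, out: str | Path, *, config: RunConfig | None = None) -> dict[str, Path]:
    """Write assignments CSV, merge-trace JSON and run metadata under ``out``.

    Singleton clusters are labelled ``unclustered`` in the assignments file —
    staying unclustered is a first-class outcome of the method, not a failure.
    Output is byte-deterministic given the same clustering and trace.
    """
    from .clustering import Clustering, MergeTrace  # local import avoids a cycle

    assert isinstance(clustering, Clustering) and isinstance(trace, MergeTrace)
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)

    ids = clustering.example_ids or [f"r{i}" for i in range(clustering.n_examples)]
    labels = [""] * clustering.n_examples
    sizes = [1] * clustering.n_examples
    next_id = 1
    for members in clustering.clusters:  # canonical order: by smallest member
        if len(members) == 1:
            labels[members[0]] = "unclustered"
        else:
            tag = f"C{next_id}"
            next_id += 1
            for i in members:
                labels[i] = tag
                sizes[i] = len(members)

    assignments = out / "assignments.csv"
    with open(assignments, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["example_id", "cluster_id", "cluster_size"])
        for i in range(clustering.n_examples):
            w.writerow([ids[i], labels[i], sizes[i]])

    trace_path = out / "trace.json"
    with open(trace_path, "w", encoding="utf-8") as fh:
        json.dump(trace.to_records(ids), fh, indent=1, sort_keys=True)
        fh.write("\n")

    meta_path = out / "run_meta.json"
    from . import __version__

    meta = {"version": __version__}
    if config is not None:
        meta["config"] = asdict(config)
        meta["seed"] = config.seed
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"assignments": assignments, "trace": trace_path, "meta": meta_path}
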