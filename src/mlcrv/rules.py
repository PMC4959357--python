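"""Random conjunctive-rule ensembles and their co-coverage counts.

The similarity signal comes from a large ensemble of shallow conjunctive
rules, each required to discriminate the original examples from their
attribute-shuffled copies better than chance.  The three requirements the
method places on the ensemble — many classifiers, as diverse as possible,
each better than random — are met by uniform random sampling of rule bodies:

* a condition count drawn uniformly from ``1..max_conditions``;
* that many distinct attributes drawn uniformly;
* numeric conditions ``attr <= t`` / ``attr > t`` with the threshold taken
  from the observed value of a uniformly drawn example, categorical
  conditions ``attr == c`` with an observed category;
* retained only if precision on the artificial task strictly exceeds the
  configured bound (0.5 at the default 1:1 class ratio) and at least one
  positive example is covered.

An example with a missing value on any conditioned attribute is not covered:
coverage asserts similarity only where evidence exists.  Duplicate rules may
be retained; the downstream normalization absorbs multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .artificial_task import ArtificialTask
from .layers_io import ConfigError, InputError, RunConfig, NUMERIC

__all__ = [
    "Condition",
    "Rule",
    "RuleEnsemble",
    "CoverageCounts",
    "sample_rule",
    "build_ensemble",
    "count_cocoverage",
]


@dataclass(frozen=True)
class Condition:
    attribute: str
    operator: str  # "<=" or ">" (numeric), "==" (categorical)
    value: float | str


@dataclass
class Rule:
    conditions: tuple[Condition, ...]
    coverage_pos: np.ndarray  # bool, length n_pos
    precision: float
    n_covered_total: int


@dataclass
class RuleEnsemble:
    rules: list[Rule]
    n_requested: int
    layer_name: str
    n_candidates: int = 0

    @property
    def acceptance_rate(self) -> float:
        return len(self.rules) / self.n_candidates if self.n_candidates else 0.0

    def coverage_matrix(self) -> np.ndarray:
        """Boolean (n_rules x n_pos) positive-coverage matrix."""
        return np.stack([r.coverage_pos for r in self.rules])


@dataclass
class CoverageCounts:
    """Symmetric N x N rule co-coverage counts; diagonal = per-example totals."""

    matrix: np.ndarray  # int64
    layer: str = ""


class _TaskColumns:
    """Columns of positives+negatives pre-encoded for fast mask evaluation.

    Numeric columns stay float (NaN = missing, comparisons with NaN are False,
    giving missing-fails-condition semantics for free); categorical columns
    are integer-coded with -1 for missing.
    """

    def __init__(self, task: ArtificialTask):
        self.n_pos = task.n_pos
        self.n_total = task.n_pos + task.n_neg
        self.names: list[str] = []
        self.kinds: list[str] = []
        self.numeric: list[np.ndarray | None] = []
        self.codes: list[np.ndarray | None] = []
        self.categories: list[list[str] | None] = []
        self.obs_idx: list[np.ndarray] = []  # indices of non-missing cells
        for attr, kind in task.positives.attributes:
            pos = task.positives.values[attr].to_numpy()
            neg = task.negatives.values[attr].to_numpy()
            self.names.append(attr)
            self.kinds.append(kind)
            if kind == NUMERIC:
                col = np.concatenate([pos, neg]).astype(float)
                self.numeric.append(col)
                self.codes.append(None)
                self.categories.append(None)
                self.obs_idx.append(np.flatnonzero(~np.isnan(col)))
            else:
                col = np.concatenate([pos, neg])
                observed = sorted({c for c in col if c is not None})
                lookup = {c: k for k, c in enumerate(observed)}
                codes = np.array([-1 if c is None else lookup[c] for c in col], dtype=np.int32)
                self.numeric.append(None)
                self.codes.append(codes)
                self.categories.append(observed)
                self.obs_idx.append(np.flatnonzero(codes >= 0))
        self.eligible = [j for j, obs in enumerate(self.obs_idx) if obs.size > 0]
        if not self.eligible:
            raise InputError("no attribute has any observed value")


def _prepare(task: ArtificialTask) -> _TaskColumns:
    cols = getattr(task, "_mlcrv_columns", None)
    if cols is None:
        cols = _TaskColumns(task)
        task._mlcrv_columns = cols  # cached; task tables are treated as immutable
    return cols


def _sample_conditions(cols: _TaskColumns, max_conditions: int, rng: np.random.Generator):
    c = int(rng.integers(1, max_conditions + 1))
    c = min(c, len(cols.eligible))
    attrs = rng.choice(len(cols.eligible), size=c, replace=False)
    picked = [cols.eligible[int(a)] for a in attrs]
    mask = np.ones(cols.n_total, dtype=bool)
    conditions = []
    for j in picked:
        obs = cols.obs_idx[j]
        pick = int(obs[int(rng.integers(obs.size))])
        if cols.kinds[j] == NUMERIC:
            col = cols.numeric[j]
            threshold = float(col[pick])
            if rng.integers(2) == 0:
                conditions.append(Condition(cols.names[j], "<=", threshold))
                mask &= col <= threshold
            else:
                conditions.append(Condition(cols.names[j], ">", threshold))
                mask &= col > threshold
        else:
            codes = cols.codes[j]
            code = int(codes[pick])
            conditions.append(Condition(cols.names[j], "==", cols.categories[j][code]))
            mask &= codes == code
    return tuple(conditions), mask


def sample_rule(
    task: ArtificialTask, max_conditions: int, rng: np.random.Generator
) -> Rule:
    """Draw one candidate rule and evaluate it on the full artificial task."""
    cols = _prepare(task)
    conditions, mask = _sample_conditions(cols, max_conditions, rng)
    covered_total = int(mask.sum())
    covered_pos = mask[: cols.n_pos]
    n_pos_covered = int(covered_pos.sum())
    precision = n_pos_covered / covered_total if covered_total else 0.0
    return Rule(
        conditions=conditions,
        coverage_pos=covered_pos.copy(),
        precision=precision,
        n_covered_total=covered_total,
    )


#: Candidate budget multiplier before declaring the layer structure-free.
MAX_ATTEMPTS_PER_RULE = 200


def build_ensemble(
    task: ArtificialTask, config: RunConfig, rng: np.random.Generator
) -> RuleEnsemble:
    """Sample candidates until ``config.n_rules`` better-than-random rules are retained.

    Raises
    ------
    ConfigError
        If ``n_rules`` < 1 (via :class:`RunConfig` validation when constructed
        normally).
    InputError
        If ``200 * n_rules`` candidates fail to fill the quota — the layer
        carries no joint structure distinguishable from shuffled data.
    """
    if config.n_rules < 1:
        raise ConfigError("n_rules must be >= 1")
    cols = _prepare(task)
    retained: list[Rule] = []
    attempts = 0
    budget = MAX_ATTEMPTS_PER_RULE * config.n_rules
    while len(retained) < config.n_rules:
        if attempts >= budget:
            raise InputError(
                f"layer {task.positives.name!r}: {attempts} candidate rules yielded only "
                f"{len(retained)}/{config.n_rules} better-than-random rules; the layer "
                "carries no joint structure distinguishable from shuffled data"
            )
        attempts += 1
        conditions, mask = _sample_conditions(cols, config.max_conditions_per_rule, rng)
        covered_total = int(mask.sum())
        if covered_total == 0:
            continue
        covered_pos = mask[: cols.n_pos]
        n_pos_covered = int(covered_pos.sum())
        if n_pos_covered == 0:
            continue
        precision = n_pos_covered / covered_total
        if precision > config.min_rule_precision:
            retained.append(
                Rule(conditions, covered_pos.copy(), precision, covered_total)
            )
    return RuleEnsemble(
        rules=retained,
        n_requested=config.n_rules,
        layer_name=task.positives.name,
        n_candidates=attempts,
    )


def count_cocoverage(ensemble: RuleEnsemble, n_examples: int) -> CoverageCounts:
    """Count, for every pair of original examples, the rules covering both.

    The diagonal holds the total number of rules covering each example.  The
    matrix is the Gram matrix of the boolean coverage matrix, so symmetry and
    the bound ``count(i, j) <= min(count(i, i), count(j, j))`` hold by
    construction.
    """
    cover = ensemble.coverage_matrix()
    if cover.shape[1] != n_examples:
        raise InputError(
            f"ensemble covers {cover.shape[1]} examples, expected {n_examples}"
        )
    f = cover.astype(np.float64)
    counts = np.rint(f.T @ f).astype(np.int64)
    return CoverageCounts(matrix=counts, layer=ensemble.layer_name)
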