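import numpy as np
import pandas as pd
import pytest

from mlcrv import (
    InputError,
    LayerTable,
    RunConfig,
    build_ensemble,
    count_cocoverage,
    make_artificial_task,
    sample_rule,
)


def _numeric_layer(values: np.ndarray, n_cols=5) -> LayerTable:
    cols = {f"a{j}": values.astype(float) for j in range(n_cols)}
    return LayerTable(
        name="num",
        example_ids=[f"r{i}" for i in range(len(values))],
        attributes=[(k, "numeric") for k in cols],
        values=pd.DataFrame(cols),
    )


def _block_layer(n_per_block=20, n_attrs=6) -> LayerTable:
    """Two blocks with block-specific categorical profiles on every attribute."""
    rng = np.random.default_rng(5)
    n = 2 * n_per_block
    cols = {}
    for j in range(n_attrs):
        block0, block1 = f"A{j}", f"B{j}"
        col = np.array([block0] * n_per_block + [block1] * n_per_block, dtype=object)
        flip = rng.random(n) < 0.1  # slight impurity so rules are not all trivial
        col[flip] = np.where(np.array([block0] * n) == col, block1, block0)[flip]
        cols[f"c{j}"] = col
    return LayerTable(
        name="blocks",
        example_ids=[f"r{i}" for i in range(n)],
        attributes=[(k, "categorical") for k in cols],
        values=pd.DataFrame(cols),
    )


class TestSampleRule:
    def test_numeric_thresholds_within_observed_range(self):
        layer = _numeric_layer(np.arange(1.0, 11.0))
        task = make_artificial_task(layer, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        for _ in range(1000):
            rule = sample_rule(task, 3, rng)
            for cond in rule.conditions:
                if cond.operator in ("<=", ">"):
                    assert 1.0 <= cond.value <= 10.0

    def test_categorical_values_are_observed_categories(self):
        layer = _block_layer()
        task = make_artificial_task(layer, np.random.default_rng(0))
        rng = np.random.default_rng(2)
        for _ in range(300):
            rule = sample_rule(task, 3, rng)
            for cond in rule.conditions:
                assert cond.operator == "=="
                assert cond.value in set(layer.values[cond.attribute])

    def test_missing_value_fails_condition(self):
        vals = np.arange(1.0, 11.0)
        cols = {f"a{j}": vals.copy() for j in range(5)}
        cols["a0"][0] = np.nan  # example 0 missing on a0
        layer = LayerTable(
            name="m",
            example_ids=[f"r{i}" for i in range(10)],
            attributes=[(k, "numeric") for k in cols],
            values=pd.DataFrame(cols),
        )
        task = make_artificial_task(layer, np.random.default_rng(0))
        rng = np.random.default_rng(3)
        seen_a0 = 0
        for _ in range(500):
            rule = sample_rule(task, 3, rng)
            if any(c.attribute == "a0" for c in rule.conditions):
                seen_a0 += 1
                assert not rule.coverage_pos[0]
        assert seen_a0 > 0

    def test_precision_matches_manual_recount(self):
        layer = _block_layer()
        task = make_artificial_task(layer, np.random.default_rng(0))
        rng = np.random.default_rng(4)
        pos, neg = task.positives.values, task.negatives.values
        for _ in range(50):
            rule = sample_rule(task, 3, rng)

            def covered(frame):
                ok = np.ones(len(frame), dtype=bool)
                for c in rule.conditions:
                    col = frame[c.attribute].to_numpy()
                    ok &= np.array([v is not None and v == c.value for v in col])
                return ok

            n_pos = covered(pos).sum()
            n_tot = n_pos + covered(neg).sum()
            assert np.array_equal(rule.coverage_pos, covered(pos))
            assert rule.precision == pytest.approx(n_pos / n_tot if n_tot else 0.0)


class TestBuildEnsemble:
    def test_all_retained_rules_beat_random(self):
        task = make_artificial_task(_block_layer(), np.random.default_rng(0))
        ens = build_ensemble(task, RunConfig(n_rules=200, seed=0), np.random.default_rng(1))
        assert len(ens.rules) == 200
        for rule in ens.rules:
            assert rule.precision > 0.5
            assert rule.coverage_pos.any()

    def test_quota_loop_is_deterministic(self):
        task = make_artificial_task(_block_layer(), np.random.default_rng(0))
        cfg = RunConfig(n_rules=100, seed=0)
        a = build_ensemble(task, cfg, np.random.default_rng(7))
        b = build_ensemble(task, cfg, np.random.default_rng(7))
        assert a.n_candidates == b.n_candidates
        assert [r.conditions for r in a.rules] == [r.conditions for r in b.rules]
        ca = count_cocoverage(a, task.n_pos).matrix
        cb = count_cocoverage(b, task.n_pos).matrix
        assert np.array_equal(ca, cb)

    def test_block_structure_yields_within_block_rules(self):
        layer = _block_layer(n_per_block=20)
        task = make_artificial_task(layer, np.random.default_rng(0))
        ens = build_ensemble(task, RunConfig(n_rules=300, seed=0), np.random.default_rng(2))
        within = 0
        for rule in ens.rules:
            idx = np.flatnonzero(rule.coverage_pos)
            frac0 = (idx < 20).mean()
            if frac0 >= 0.9 or frac0 <= 0.1:
                within += 1
        assert within / len(ens.rules) >= 0.8

    def test_acceptance_rate_higher_on_structured_than_shuffled_data(self):
        # one dominant block (30 of 40 examples share a slightly impure
        # categorical profile) against background examples with unique values
        rng_fix = np.random.default_rng(5)
        n, n_block = 40, 30
        cols = {}
        for j in range(6):
            col = np.empty(n, dtype=object)
            for i in range(n):
                if i < n_block and rng_fix.random() >= 0.05:
                    col[i] = f"A{j}"
                else:
                    col[i] = f"u{i}_{j}"
            cols[f"c{j}"] = col
        layer = LayerTable(
            name="oneblock",
            example_ids=[f"r{i}" for i in range(n)],
            attributes=[(k, "categorical") for k in cols],
            values=pd.DataFrame(cols),
        )
        structured = make_artificial_task(layer, np.random.default_rng(0))
        # a layer that is itself already shuffled carries no joint structure
        null_layer = make_artificial_task(layer, np.random.default_rng(50)).negatives
        null = make_artificial_task(null_layer, np.random.default_rng(0))
        cfg = RunConfig(n_rules=300, seed=0)
        a = build_ensemble(structured, cfg, np.random.default_rng(1))
        b = build_ensemble(null, cfg, np.random.default_rng(1))
        assert a.acceptance_rate / b.acceptance_rate > 1.5


class TestCountCocoverage:
    def _ensemble_from_masks(self, masks, n):
        from mlcrv.rules import Rule, RuleEnsemble

        rules = [
            Rule(conditions=(), coverage_pos=np.asarray(m, dtype=bool), precision=1.0,
                 n_covered_total=int(np.sum(m)))
            for m in masks
        ]
        return RuleEnsemble(rules=rules, n_requested=len(rules), layer_name="t")

    def test_single_rule_counts(self):
        mask = [False, True, True, True, False]
        counts = count_cocoverage(self._ensemble_from_masks([mask], 5), 5).matrix
        assert counts[1, 2] == counts[1, 3] == counts[2, 3] == 1
        assert list(np.diag(counts)) == [0, 1, 1, 1, 0]
        assert counts[0, 1] == 0

    def test_identical_rules_count_twice(self):
        mask = [True, True, False]
        counts = count_cocoverage(self._ensemble_from_masks([mask, mask], 3), 3).matrix
        assert counts[0, 1] == 2

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(8)
        masks = rng.random((20, 12)) < 0.4
        counts = count_cocoverage(self._ensemble_from_masks(list(masks), 12), 12).matrix
        expect = np.zeros((12, 12), dtype=int)
        for m in masks:
            for i in range(12):
                for j in range(12):
                    if m[i] and m[j]:
                        expect[i, j] += 1
        assert np.array_equal(counts, expect)
        # structural invariants: symmetry and the pair/diagonal bound
        assert np.array_equal(counts, counts.T)
        for i in range(12):
            for j in range(12):
                if i != j:
                    assert counts[i, j] <= min(counts[i, i], counts[j, j])
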