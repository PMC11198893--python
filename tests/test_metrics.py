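"""Evaluation metrics vs. independent naive implementations, aggregation
semantics, and Pearson validation behaviour."""

import numpy as np
import pandas as pd
import pytest

import brushfuse as bf
from brushfuse import attribution as at
from brushfuse import metrics as mx

from conftest import make_events


# ---- independent naive oracles ------------------------------------------

def naive_prf(pred, true):
    tp = sum(1 for p, t in zip(pred, true) if p and t)
    fp = sum(1 for p, t in zip(pred, true) if p and not t)
    fn = sum(1 for p, t in zip(pred, true) if not p and t)
    prec = tp / (tp + fp) if tp + fp else float("nan")
    rec = tp / (tp + fn) if tp + fn else float("nan")
    if prec != prec or rec != rec or prec + rec == 0:
        f1 = float("nan")
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return prec, rec, f1


def naive_jaccard(pred_sets, true_sets):
    vals = []
    for p, t in zip(pred_sets, true_sets):
        p, t = set(p), set(t)
        vals.append(1.0 if not (p | t) else len(p & t) / len(p | t))
    return sum(vals) / len(vals)


def naive_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


class TestBoundaryMetrics:
    def test_printed_formula_example(self):
        # TP=2, FP=1, FN=0 -> precision 2/3, recall 1, F1 0.8
        pred = [True, True, True, False]
        true = [True, True, False, False]
        m = bf.boundary_metrics(pred, true)
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == 1.0
        assert m.f1 == pytest.approx(0.8)

    def test_perfect_prediction(self):
        m = bf.boundary_metrics([True, False, True], [True, False, True])
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_no_positive_predictions_gives_nan_not_zero(self):
        m = bf.boundary_metrics([False, False], [True, False])
        assert np.isnan(m.precision)
        assert m.recall == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            bf.boundary_metrics([True], [True, False])

    def test_agrees_with_naive_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(1, 30)
            pred = rng.random(n) < rng.random()
            true = rng.random(n) < rng.random()
            m = bf.boundary_metrics(pred, true)
            for got, want in zip(
                (m.precision, m.recall, m.f1), naive_prf(pred, true)
            ):
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)


class TestAverageJaccard:
    def test_formula(self):
        assert bf.average_jaccard([{"A"}, {"A"}], [{"A"}, {"B"}]) == 0.5
        assert bf.average_jaccard([{"A", "B"}], [{"A"}]) == 0.5

    def test_both_empty_scores_one(self):
        assert bf.average_jaccard([set()], [set()]) == 1.0

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            bf.average_jaccard([], [])

    def test_bounds_and_identity(self):
        rng = np.random.default_rng(1)
        animals = list("abcdef")
        for _ in range(200):
            n = rng.integers(1, 20)
            pred = [set(rng.choice(animals, rng.integers(0, 4), replace=False)) for _ in range(n)]
            s = bf.average_jaccard(pred, pred)
            assert s == 1.0

    def test_agrees_with_naive_on_random_inputs(self):
        rng = np.random.default_rng(2)
        animals = list("abcdefgh")
        for _ in range(1000):
            n = int(rng.integers(1, 15))
            pred = [set(rng.choice(animals, rng.integers(0, 4), replace=False)) for _ in range(n)]
            true = [set(rng.choice(animals, rng.integers(0, 4), replace=False)) for _ in range(n)]
            assert bf.average_jaccard(pred, true) == pytest.approx(
                naive_jaccard(pred, true), abs=1e-12
            )


class TestMultilabelPR:
    def _cands(self, rows):
        out = {"unit_id": np.arange(len(rows))}
        for s in range(4):
            out[f"animal_{s + 1}"] = [r[s] for r in rows]
            out[f"interval_{s + 1}"] = 0.0
        return pd.DataFrame(out)

    def test_perfect_predictions(self):
        cands = self._cands([("a", "b", "c", "d")] * 4)
        sets = [{"a"}, {"b"}, {"c"}, {"d"}]
        res = bf.multilabel_pr(sets, sets, cands)
        assert res["per_slot_precision"] == [1.0, 1.0, 1.0, 1.0]
        assert res["per_slot_recall"] == [1.0, 1.0, 1.0, 1.0]

    def test_half_right_slot_one(self):
        cands = self._cands([("a", "b", "c", "d")] * 4)
        pred = [{"a"}] * 4
        true = [{"a"}, {"a"}, {"b"}, {"c"}]
        res = bf.multilabel_pr(pred, true, cands)
        assert res["per_slot_precision"][0] == 0.5

    def test_macro_average_on_hand_computed_fixture(self):
        cands = self._cands(
            [("a", "b", "c", at.MISSING)] * 10
        )
        pred = [{"a"}] * 5 + [{"b"}] * 5
        true = [{"a"}] * 4 + [{"c"}] + [{"b"}] * 3 + [{"a"}] * 2
        res = bf.multilabel_pr(pred, true, cands)
        # slot1: tp=4 fp=1 fn=2 -> p=0.8, r=2/3; slot2: tp=3 fp=2 fn=0 -> p=0.6, r=1
        assert res["per_slot_precision"][:2] == pytest.approx([0.8, 0.6])
        assert res["per_slot_recall"][:2] == pytest.approx([2 / 3, 1.0])
        # slot3 has truth but no predictions (p undefined); slot4 empty slot
        with np.errstate(invalid="ignore"):
            assert res["macro_precision"] == pytest.approx(np.nanmean([0.8, 0.6]))


class TestPearsonDaily:
    def _table(self, values, cows=None, day=0):
        cows = cows or [f"c{i}" for i in range(len(values))]
        return pd.DataFrame({"cow_id": cows, "day": day, "seconds": values})

    def test_identity_r_one(self):
        t = self._table([10.0, 50.0, 200.0, 400.0])
        assert bf.pearson_daily(t, t) == pytest.approx(1.0)

    def test_scale_invariance(self):
        t = self._table([10.0, 50.0, 200.0, 400.0])
        half = t.assign(seconds=t["seconds"] * 0.5)
        assert bf.pearson_daily(half, t) == pytest.approx(1.0)

    def test_affine_invariance(self):
        t = self._table([10.0, 50.0, 200.0, 400.0])
        aff = t.assign(seconds=t["seconds"] * 3.0 + 7.0)
        assert bf.pearson_daily(aff, t) == pytest.approx(1.0)

    def test_missing_animals_count_as_zero(self):
        truth = self._table([100.0, 200.0, 300.0, 400.0])
        est = truth.iloc[:3]
        r_full = bf.pearson_daily(est, truth)
        padded = pd.concat(
            [est, pd.DataFrame({"cow_id": ["c3"], "day": [0], "seconds": [0.0]})]
        )
        assert r_full == pytest.approx(bf.pearson_daily(padded, truth))

    def test_degenerate_inputs_give_nan(self):
        t2 = self._table([1.0, 2.0])
        assert np.isnan(bf.pearson_daily(t2, t2))
        flat = self._table([5.0, 5.0, 5.0])
        assert np.isnan(bf.pearson_daily(flat, self._table([1.0, 2.0, 3.0])))

    def test_shuffled_estimates_bracket_zero(self):
        rng = np.random.default_rng(3)
        truth = self._table(list(rng.uniform(50, 1500, 24)))
        rs = []
        for _ in range(100):
            est = truth.assign(seconds=rng.permutation(truth["seconds"].to_numpy()))
            rs.append(bf.pearson_daily(est, truth))
        assert min(rs) < 0 < max(rs)
        assert abs(np.mean(rs)) < 0.15

    def test_agrees_with_naive_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            n = int(rng.integers(3, 30))
            x = rng.uniform(0, 1000, n)
            y = x * rng.uniform(0.1, 2) + rng.normal(0, 100, n)
            est = self._table(list(y))
            truth = self._table(list(x))
            assert bf.pearson_daily(est, truth) == pytest.approx(
                naive_pearson(x, y), abs=1e-12
            )


class TestAggregateDailyUse:
    def _units(self, starts, durations):
        ev = make_events(starts, durations)
        from brushfuse.harness import event_units

        return event_units(ev)

    def _assign(self, users_per_unit):
        return pd.DataFrame(
            {
                "unit_id": np.arange(len(users_per_unit)),
                "predicted_users": [frozenset(u) for u in users_per_unit],
                "method": "proximity",
                "source": "vision",
            }
        )

    def test_simple_sum(self):
        units = self._units([0.0, 100.0], [3.0, 4.0])
        daily = bf.aggregate_daily_use(units, self._assign([{"A"}, {"A"}]))
        assert daily.to_dict(orient="records") == [
            {"cow_id": "A", "day": 0, "seconds": 7.0}
        ]

    def test_full_vs_split_credit(self):
        units = self._units([0.0], [10.0])
        full = bf.aggregate_daily_use(units, self._assign([{"A", "B"}]), credit="full")
        assert sorted(full["seconds"]) == [10.0, 10.0]
        split = bf.aggregate_daily_use(units, self._assign([{"A", "B"}]), credit="split")
        assert sorted(split["seconds"]) == [5.0, 5.0]

    def test_unattributed_units_ignored(self):
        units = self._units([0.0, 100.0], [3.0, 4.0])
        daily = bf.aggregate_daily_use(units, self._assign([set(), {"A"}]))
        assert daily["seconds"].tolist() == [4.0]

    def test_empty_assignments_give_empty_table(self):
        units = self._units([0.0], [3.0])
        daily = bf.aggregate_daily_use(units, self._assign([set()]))
        assert len(daily) == 0

    def test_split_credit_conserves_total_seconds(self):
        rng = np.random.default_rng(5)
        n = 50
        units = self._units(np.arange(n) * 100.0, rng.uniform(1, 20, n))
        users = [
            set(rng.choice(list("abcd"), rng.integers(1, 4), replace=False))
            for _ in range(n)
        ]
        daily = bf.aggregate_daily_use(units, self._assign(users), credit="split")
        assert daily["seconds"].sum() == pytest.approx(units["duration_s"].sum())

    def test_day_assignment_spans_midnight(self):
        units = self._units([10.0, 86400.0 + 5.0], [3.0, 4.0])
        daily = bf.aggregate_daily_use(units, self._assign([{"A"}, {"A"}]))
        assert daily["day"].tolist() == [0, 1]
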