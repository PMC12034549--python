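"""Metrics, repeated-run statistics, Mann-Whitney U, ablation, benchmark."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ppdnet.evaluation import (
    ConfusionMatrix,
    ModelSpec,
    RunSummary,
    ablate,
    benchmark,
    confusion,
    mann_whitney,
    metrics,
    repeated_runs,
    run_experiment,
)
from ppdnet.schema import SplitConfig


def brute_force_metrics(tp, fp, fn, tn):
    """Independent recomputation of all nine metrics from first
    principles (plain formulas, zero-denominator convention 0)."""
    total = tp + fp + fn + tn
    div = lambda a, b: a / b if b else 0.0
    precision = div(tp, tp + fp)
    recall = div(tp, tp + fn)
    specificity = div(tn, tn + fp)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "accuracy": (tp + tn) / total,
        "precision": precision,
        "recall": recall,
        "f1": div(2 * precision * recall, precision + recall),
        "mcc": div(tp * tn - fp * fn, mcc_den),
        "specificity": specificity,
        "npv": div(tn, tn + fn),
        "fpr": 1 - specificity,
        "fnr": 1 - recall,
    }


def enumerate_mann_whitney(a, b):
    """Exact two-sided p by enumerating every assignment of pooled ranks."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = stats.rankdata(pooled)
    u_of = lambda idx: ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
    u_obs = u_of(range(n1))
    us = np.array([u_of(c) for c in itertools.combinations(range(len(pooled)), n1)])
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(p, 1.0)


class TestConfusion:
    def test_direct_counts(self):
        cm = confusion([1, 1, 0], [1, 0, 0])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 0)

    def test_perfect_prediction_has_no_errors(self):
        cm = confusion([1, 0, 1], [1, 0, 1])
        assert cm.fp == cm.fn == 0

    def test_inverted_prediction_has_no_hits(self):
        cm = confusion([1, 0], [0, 1])
        assert cm.tp == cm.tn == 0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 2], [0, 1])


class TestMetrics:
    def test_worked_example(self):
        rep = metrics(ConfusionMatrix(tp=3, fp=1, fn=2, tn=4))
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.6)
        assert rep.f1 == pytest.approx(0.6667, abs=1e-4)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.npv == pytest.approx(0.6667, abs=1e-4)
        assert rep.fpr == pytest.approx(0.2)
        assert rep.fnr == pytest.approx(0.4)
        assert rep.mcc == pytest.approx(0.4082, abs=1e-4)

    def test_perfect_prediction(self):
        rep = metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=5))
        assert rep.accuracy == rep.f1 == rep.mcc == 1.0
        assert rep.fpr == rep.fnr == 0.0

    def test_all_positive_predictions(self):
        rep = metrics(ConfusionMatrix(tp=6, fp=4, fn=0, tn=0))
        assert rep.specificity == 0.0
        assert rep.fpr == 1.0

    def test_zero_denominator_flagged_not_nan(self):
        rep = metrics(ConfusionMatrix(tp=0, fp=0, fn=2, tn=3))
        assert rep.precision == 0.0
        assert "precision" in rep.zero_denominator

    @settings(max_examples=300, derandomize=True)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_matches_brute_force_and_identities(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        rep = metrics(ConfusionMatrix(tp, fp, fn, tn))
        expected = brute_force_metrics(tp, fp, fn, tn)
        for name, val in expected.items():
            assert getattr(rep, name) == pytest.approx(val, abs=1e-12)
        assert rep.fpr == pytest.approx(1 - rep.specificity)
        assert rep.fnr == pytest.approx(1 - rep.recall)
        assert -1.0 <= rep.mcc <= 1.0

    @settings(max_examples=100, derandomize=True)
    @given(
        tp=st.integers(1, 30), fp=st.integers(0, 30),
        fn=st.integers(0, 30), tn=st.integers(1, 30),
    )
    def test_mcc_invariant_under_class_swap(self, tp, fp, fn, tn):
        a = metrics(ConfusionMatrix(tp, fp, fn, tn)).mcc
        b = metrics(ConfusionMatrix(tn, fn, fp, tp)).mcc
        assert a == pytest.approx(b, abs=1e-12)


class TestMannWhitney:
    def test_separated_samples_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_samples_give_p_one(self):
        a = [0.9, 0.91, 0.92, 0.93]
        res = mann_whitney(a, a)
        assert res.u_statistic == len(a) ** 2 / 2
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = rng.normal(size=5)
            b = rng.normal(0.8, size=6)
            u, p = enumerate_mann_whitney(a, b)
            res = mann_whitney(a, b)
            assert res.method == "exact"
            assert res.u_statistic == pytest.approx(u)
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_normal_approx_close_to_exact(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.normal(size=6)
            b = rng.normal(0.5, size=6)
            _, p_exact = enumerate_mann_whitney(a, b)
            p_norm = mann_whitney(a, b, method="normal_approx").p_value
            assert abs(p_norm - p_exact) <= 0.01

    def test_u_statistics_sum_to_product(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=8), rng.normal(size=13)
        u1 = mann_whitney(a, b).u_statistic
        u2 = mann_whitney(b, a).u_statistic
        assert u1 + u2 == pytest.approx(len(a) * len(b))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestRunSummary:
    def test_two_point_series(self):
        s = RunSummary.from_series([0.8, 1.0])
        assert s.mean == pytest.approx(0.9)
        assert s.std == pytest.approx(0.1414, abs=1e-4)
        assert (s.worst, s.best) == (0.8, 1.0)

    def test_constant_series(self):
        s = RunSummary.from_series([0.9] * 5)
        assert s.std == 0.0
        assert s.worst == s.best == s.median == 0.9

    def test_statistics_match_brute_force(self):
        rng = np.random.default_rng(1)
        acc = rng.uniform(0.7, 1.0, 30)
        s = RunSummary.from_series(acc)
        assert s.worst == acc.min() and s.best == acc.max()
        assert s.mean == pytest.approx(acc.sum() / 30)
        assert s.median == pytest.approx(np.sort(acc)[14:16].mean())
        assert s.std == pytest.approx(
            np.sqrt(((acc - acc.mean()) ** 2).sum() / 29)
        )
        assert s.worst <= s.median <= s.best


def _fast_spec(fast_cfg):
    return ModelSpec(fcnn_cfg=fast_cfg, dnn_cfg=fast_cfg, dnn_rate=0.5)


class TestRunExperiment:
    def test_deterministic_per_seed(self, synth_small, fast_cfg):
        r1 = run_experiment(synth_small, _fast_spec(fast_cfg), seed=5)
        r2 = run_experiment(synth_small, _fast_spec(fast_cfg), seed=5)
        assert r1 == r2

    @pytest.mark.parametrize("frac", [0.9, 0.8, 0.7, 0.6])
    def test_benchmark_ratios_accepted(self, synth_small, fast_cfg, frac):
        rep = run_experiment(
            synth_small, _fast_spec(fast_cfg), SplitConfig(train_fraction=frac), seed=1
        )
        assert 0.0 <= rep.accuracy <= 1.0


class TestRepeatedRuns:
    def test_deterministic_and_sized(self, synth_small, fast_cfg):
        s1 = repeated_runs(synth_small, _fast_spec(fast_cfg), k=3, seed=2)
        s2 = repeated_runs(synth_small, _fast_spec(fast_cfg), k=3, seed=2)
        assert np.array_equal(s1.accuracies, s2.accuracies)
        assert len(s1.accuracies) == 3

    def test_default_protocol_is_thirty_runs(self):
        import inspect

        assert inspect.signature(repeated_runs).parameters["k"].default == 30

    def test_fixed_split_varies_only_initialization(self, synth_small, fast_cfg):
        s = repeated_runs(
            synth_small, _fast_spec(fast_cfg), k=3, protocol="fixed-split", seed=4
        )
        assert len(s.accuracies) == 3

    def test_too_few_runs_rejected(self, synth_small, fast_cfg):
        with pytest.raises(ValueError):
            repeated_runs(synth_small, _fast_spec(fast_cfg), k=1)


class TestAblate:
    def test_three_rows_nine_metrics(self, synth_small, fast_cfg):
        rows = ablate(synth_small, _fast_spec(fast_cfg), seed=3)
        assert set(rows) == {"fcnn", "dnn", "ensemble"}
        for rep in rows.values():
            assert len(rep.as_dict()) == 9

    def test_degenerate_rate_zero_same_seed_rows_identical(self, synth_small, fast_cfg):
        spec = ModelSpec(fcnn_cfg=fast_cfg, dnn_cfg=fast_cfg, dnn_rate=0.0)
        rows = ablate(synth_small, spec, seed=None)
        assert rows["fcnn"] == rows["dnn"] == rows["ensemble"]


class _ConstantClassifier:
    def fit(self, X, y):
        vals, counts = np.unique(y, return_counts=True)
        self.label = vals[np.argmax(counts)]
        return self

    def predict(self, X):
        return np.full(len(X), self.label)


class _BrokenClassifier:
    def fit(self, X, y):
        raise RuntimeError("boom")

    def predict(self, X):  # pragma: no cover
        raise AssertionError


class TestBenchmark:
    def test_constant_baseline_and_failure_isolation(self, synth_small, fast_cfg):
        report = benchmark(
            synth_small,
            adapters={
                "majority": lambda seed: _ConstantClassifier(),
                "broken": lambda seed: _BrokenClassifier(),
            },
            k=3,
            spec=_fast_spec(fast_cfg),
            seed=6,
        )
        assert "majority" in report.summaries
        # constant majority predictions score the positive share of each test set
        assert 0.55 <= report.summaries["majority"].mean <= 0.75
        assert set(report.comparisons) == {"majority"}
        assert "broken" in report.failures

    def test_proposed_vs_itself_is_insignificant(self, synth_small, fast_cfg):
        s = repeated_runs(synth_small, _fast_spec(fast_cfg), k=4, seed=8)
        res = mann_whitney(s.accuracies, s.accuracies)
        assert res.p_value == pytest.approx(1.0)

    def test_sklearn_baselines_run(self, synth_small, fast_cfg):
        from ppdnet.evaluation import sklearn_baselines

        adapters = {k: v for k, v in sklearn_baselines().items() if k in ("LR", "NBC")}
        report = benchmark(synth_small, adapters=adapters, k=2, spec=_fast_spec(fast_cfg), seed=1)
        assert not report.failures
        assert set(report.comparisons) == {"LR", "NBC"}
        for s in report.summaries.values():
            assert 0.0 <= s.worst <= s.best <= 1.0
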