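import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitalsentry import confusion, mae_rmse, rank_auc, roc_and_auc, roc_points
from vitalsentry.evaluation import ConfusionCounts
from vitalsentry.exceptions import ShapeError


class TestMaeRmse:
    def test_perfect_forecast(self):
        assert mae_rmse([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)

    def test_equal_magnitude_errors_make_them_equal(self):
        mae, rmse = mae_rmse([1.0, -1.0, 1.0, -1.0], [0.0, 0.0, 0.0, 0.0])
        assert mae == rmse == 1.0

    def test_hand_value(self):
        mae, rmse = mae_rmse([0.0, 2.0], [0.0, 0.0])
        assert mae == pytest.approx(1.0)
        assert rmse == pytest.approx(np.sqrt(2.0))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mae_rmse([], [])

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            mae_rmse([1.0], [1.0, 2.0])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    def test_rmse_at_least_mae(self, errs):
        mae, rmse = mae_rmse(errs, [0.0] * len(errs))
        assert rmse >= mae - 1e-9 * max(1.0, rmse)


class TestConfusion:
    def test_mixed_counts(self):
        c = confusion(["healthy", "healthy", "unhealthy", "unhealthy"],
                      ["healthy", "unhealthy", "healthy", "unhealthy"])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)
        assert c.tpr == 0.5 and c.fpr == 0.5 and c.accuracy == 0.5

    def test_perfect_prediction(self):
        a = [1, 1, 0, 0, 1]
        c = confusion(a, a)
        assert c.tpr == 1.0 and c.fpr == 0.0 and c.accuracy == 1.0

    def test_printed_count_arithmetic(self):
        # 1924 of 2000 subjects correct -> 96.2 % overall accuracy
        actual = np.array([1] * 1387 + [0] * 613)
        predicted = np.concatenate([
            np.r_[np.ones(1343), np.zeros(44)],     # 44 healthy flagged unhealthy
            np.r_[np.ones(32), np.zeros(581)],      # 581 of 613 unhealthy caught
        ]).astype(int)
        c = confusion(actual, predicted)
        assert c.tp + c.tn == 1924 and c.total == 2000
        assert c.accuracy == pytest.approx(0.962)
        # 581 of 613 unhealthy correctly flagged -> 94.8 %
        unhealthy_acc = c.tn / (c.tn + c.fp)
        assert unhealthy_acc == pytest.approx(0.948, abs=5e-4)

    def test_empty_class_warns_nan(self):
        c = ConfusionCounts(tp=3, tn=0, fp=0, fn=2)
        with pytest.warns(UserWarning, match="FPR"):
            assert np.isnan(c.fpr)

    def test_label_strings_and_ints_agree(self):
        a = confusion([1, 0, 1], [0, 0, 1])
        b = confusion(["healthy", "unhealthy", "healthy"],
                      ["unhealthy", "unhealthy", "healthy"])
        assert (a.tp, a.tn, a.fp, a.fn) == (b.tp, b.tn, b.fp, b.fn)


def pairwise_auc(scores, labels):
    """Exhaustive pairwise oracle: P(healthy outranks unhealthy), ties ½."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


class TestRankAuc:
    def test_perfect_separation(self):
        assert rank_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_half(self):
        assert rank_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_ranked_example(self):
        # healthy {0.8, 0.3} rank 4, 2; AUC = (6 − 3)/4 = 0.75
        assert rank_auc([0.8, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)
        assert pairwise_auc([0.8, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="unhealthy"):
            rank_auc([0.5, 0.6], [1, 1])
        with pytest.raises(ValueError, match="healthy"):
            rank_auc([0.5, 0.6], [0, 0])

    @settings(max_examples=60, deadline=None)
    @given(
        st.integers(1, 100), st.integers(1, 100), st.integers(0, 2**31 - 1),
        st.booleans(),
    )
    def test_matches_pairwise_oracle(self, m, n, seed, quantize):
        rng = np.random.default_rng(seed)
        labels = np.r_[np.ones(m, dtype=int), np.zeros(n, dtype=int)]
        scores = rng.normal(size=m + n)
        if quantize:  # force ties
            scores = np.round(scores)
        assert rank_auc(scores, labels) == pytest.approx(
            pairwise_auc(scores, labels), abs=1e-12
        )

    @settings(max_examples=20, deadline=None)
    @given(st.integers(2, 40), st.integers(0, 2**31 - 1))
    def test_monotone_transform_invariance(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.normal(size=n)
        a = rank_auc(scores, labels)
        assert rank_auc(np.exp(scores), labels) == pytest.approx(a, abs=1e-12)
        assert rank_auc(3 * scores - 7, labels) == pytest.approx(a, abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        scores = np.round(rng.normal(size=200), 1)
        assert rank_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestRoc:
    def test_endpoints(self):
        roc = roc_points(np.random.default_rng(0).normal(size=20),
                         [1, 0] * 10)
        np.testing.assert_allclose(roc[0], [0.0, 0.0])
        np.testing.assert_allclose(roc[-1], [1.0, 1.0])

    def test_monotone_points(self):
        rng = np.random.default_rng(1)
        roc = roc_points(np.round(rng.normal(size=50), 1), rng.integers(0, 2, 50))
        assert np.all(np.diff(roc[:, 0]) >= 0)
        assert np.all(np.diff(roc[:, 1]) >= 0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(2, 80), st.integers(0, 2**31 - 1), st.booleans())
    def test_trapezoid_area_equals_rank_auc(self, n, seed, quantize):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        losses = rng.exponential(size=n)
        if quantize:
            losses = np.round(losses, 1)
        out = roc_and_auc(losses, labels)
        area = np.trapezoid(out["roc"][:, 1], out["roc"][:, 0])
        assert abs(area - out["auc"]) < 1e-9


class TestEvaluateModels:
    @pytest.fixture()
    def stub_setup(self, tiny_split, tiny_scaler):
        class Stub:
            """Scores an hour by its absolute deviation from channel means."""

            def __init__(self, w):
                self.w = w

            def score_samples(self, Xn):
                return np.abs(Xn - 0.5).sum(axis=-1) * self.w

            def reconstruct(self, Xn):
                return np.clip(Xn, 0.25, 0.75)

        from vitalsentry import MonitorConfig

        _, test = tiny_split
        def cfg(w):
            return MonitorConfig(model=Stub(w), normalizer=tiny_scaler, threshold=0.6)
        return test, cfg

    def test_identical_models_identical_reports(self, stub_setup):
        from vitalsentry import evaluate_models

        test, cfg = stub_setup
        reports = evaluate_models(test, {"a": cfg(1.0), "b": cfg(1.0)})
        ra, rb = reports["a"], reports["b"]
        assert ra.pooled_auc == rb.pooled_auc
        assert ra.subject_aucs == rb.subject_aucs
        assert ra.subject_confusion == rb.subject_confusion
        assert ra.mae == rb.mae and ra.rmse == rb.rmse

    def test_pooled_counts_conserved(self, stub_setup):
        from vitalsentry import evaluate_models

        test, cfg = stub_setup
        reports = evaluate_models(test, {"a": cfg(1.0)})
        c = reports["a"].pooled_confusion
        assert c.total == sum(len(s) for s in test.series)
        sc = reports["a"].subject_confusion
        assert sc.total == len(test.series)

    def test_auc_invariant_to_score_scaling(self, stub_setup):
        from vitalsentry import evaluate_models

        test, cfg = stub_setup
        reports = evaluate_models(test, {"a": cfg(1.0), "b": cfg(3.0)})
        assert reports["a"].pooled_auc == pytest.approx(reports["b"].pooled_auc)
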