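"""Training loop semantics (early stopping, best-epoch restoration),
imbalance handling, metrics and confidence-interval arithmetic."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from copdscreen.metrics import (ConfusionMatrix, confidence_interval,
                                evaluate_predictions, metrics_from_confusion,
                                round_half_up, summarize_folds)
from copdscreen.nn import AdamW, Linear, ModelConfig, Tensor, build_model, cross_entropy
from copdscreen.training import (EarlyStopper, TrainConfig, make_loss,
                                 train_model, evaluate_model)

RNG = np.random.default_rng(0)


class TestEarlyStopper:
    def test_plateau_trace_stops_after_five_returns_epoch_two(self):
        # selection-metric sequence [0.5, 0.6, 0.6, 0.6, 0.6], patience 3
        stopper = EarlyStopper(patience=3)
        trace = [0.5, 0.6, 0.6, 0.6, 0.6]
        stopped_at = None
        for epoch, v in enumerate(trace, start=1):
            stopper.update(v, epoch)
            if stopper.should_stop:
                stopped_at = epoch
                break
        assert stopped_at == 5
        assert stopper.best_epoch == 2

    def test_undefined_metric_epochs_do_not_count_toward_patience(self):
        stopper = EarlyStopper(patience=2)
        for epoch, v in enumerate([np.nan, np.nan, np.nan, np.nan], start=1):
            assert not stopper.update(v, epoch)
            assert not stopper.should_stop
        assert stopper.update(0.5, 5)
        assert stopper.best_epoch == 5

    def test_monotone_improvement_never_stops(self):
        stopper = EarlyStopper(patience=2)
        for epoch, v in enumerate([0.1, 0.2, 0.3, 0.4], start=1):
            stopper.update(v, epoch)
            assert not stopper.should_stop


class TestMakeLoss:
    def test_balanced_counts_unit_weights(self):
        w = make_loss("class_weight", {"Healthy": 10, "COPD": 10})
        assert np.allclose(w, [1.0, 1.0])

    def test_inverse_frequency_mean_one(self):
        # counts 90 majority / 10 minority -> weights {0.2, 1.8}
        w = make_loss("class_weight", {"Healthy": 90, "COPD": 10})
        assert np.allclose(w, [0.2, 1.8])
        assert np.isclose(w.mean(), 1.0)

    def test_oversample_and_none_are_unweighted(self):
        assert make_loss("oversample") is None
        assert make_loss("none") is None

    def test_zero_count_class_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            make_loss("class_weight", {"Healthy": 0, "COPD": 10})


class TestTrainModel:
    def _toy(self, n=24, T=16, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 80, T)).astype(np.float32)
        y = np.arange(n) % 2
        X[y == 1, 20:30, :] += 2.0
        return X, y.astype(np.int64)

    def test_max_epochs_one_runs_exactly_one_epoch(self):
        X, y = self._toy()
        model = build_model(ModelConfig(channels=8, embedding_dim=8, seed=0))
        _, hist = train_model(model, X, y, X, y,
                              TrainConfig(max_epochs=1, early_stop_patience=1,
                                          batch_size=8, seed=0))
        assert len(hist) == 1

    def test_returns_best_epoch_parameters(self):
        X, y = self._toy()
        model = build_model(ModelConfig(channels=8, embedding_dim=8, seed=1))
        model, hist = train_model(model, X, y, X, y,
                                  TrainConfig(max_epochs=5, batch_size=8, seed=0))
        final = evaluate_model(model, X, y)
        best_val_f1 = np.nanmax(hist["val_f1"].to_numpy(dtype=float))
        assert final.f1 == pytest.approx(best_val_f1, abs=1e-6)

    def test_nan_loss_aborts_with_diagnostics(self):
        X, y = self._toy()
        X[0, 0, 0] = np.nan
        model = build_model(ModelConfig(channels=8, embedding_dim=8, seed=0))
        with pytest.raises(RuntimeError, match="loss at epoch"):
            train_model(model, X, y, X, y,
                        TrainConfig(max_epochs=1, early_stop_patience=1, seed=0))

    def test_single_class_training_rejected(self):
        X, _ = self._toy()
        y = np.zeros(len(X), dtype=np.int64)
        model = build_model(ModelConfig(channels=8, embedding_dim=8, seed=0))
        with pytest.raises(ValueError, match="both classes"):
            train_model(model, X, y, X, y, TrainConfig(seed=0))


def test_linearly_separable_toy_converges():
    # 2-D features with margin, logistic head trained by the same optimizer
    rng = np.random.default_rng(1)
    n = 200
    y = np.arange(n) % 2
    X = rng.normal(size=(n, 2)) * 0.3 + np.where(y[:, None] == 1, 1.0, -1.0)
    head = Linear(2, 2, rng)
    opt = AdamW(head.parameters(), lr=0.05)
    for _ in range(50):
        loss = cross_entropy(head(Tensor(X.astype(np.float32))), y)
        opt.zero_grad()
        loss.backward()
        opt.step()
    preds = np.argmax(head(Tensor(X.astype(np.float32))).data, axis=1)
    assert (preds == y).mean() >= 0.99


class TestEvaluate:
    def test_printed_confusion_matrix_metrics(self):
        # tp=87, fn=19, tn=3, fp=2 -> 81.1% accuracy, 82.1% recall, 60.0% spec
        fm = metrics_from_confusion(ConfusionMatrix(tp=87, fp=2, tn=3, fn=19))
        assert round_half_up(fm.accuracy, 1) == 81.1
        assert round_half_up(fm.recall, 1) == 82.1
        assert round_half_up(fm.specificity, 1) == 60.0

    def test_perfect_predictions(self):
        y = ["COPD"] * 5 + ["Healthy"] * 5
        fm = evaluate_predictions(y, y, scores=[1.0] * 5 + [0.0] * 5)
        for v in (fm.accuracy, fm.precision, fm.recall, fm.f1, fm.specificity,
                  fm.roc_auc):
            assert v == pytest.approx(100.0)

    def test_random_scores_null_auc(self):
        rng = np.random.default_rng(5)
        n = 10**4
        y = ["COPD" if i % 2 else "Healthy" for i in range(n)]
        scores = rng.random(n)
        preds = ["COPD" if s >= 0.5 else "Healthy" for s in scores]
        fm = evaluate_predictions(y, preds, scores)
        assert fm.roc_auc == pytest.approx(50.0, abs=2.0)

    def test_undefined_ratio_reports_nan_with_warning(self):
        y_true = ["COPD", "COPD", "Healthy"]
        y_pred = ["Healthy"] * 3  # no positive predictions -> precision NaN
        with pytest.warns(UserWarning, match="precision undefined"):
            fm = evaluate_predictions(y_true, y_pred)
        assert np.isnan(fm.precision)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_predictions([], [])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           tn=st.integers(0, 50), fn=st.integers(0, 50))
    def test_confusion_identities(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fm = metrics_from_confusion(ConfusionMatrix(tp, fp, tn, fn))
        assert fm.accuracy == pytest.approx(100 * (tp + tn) / (tp + fp + tn + fn))
        if np.isfinite(fm.recall):
            assert fm.recall / 100 * (tp + fn) == pytest.approx(tp)
        for v in fm.as_dict().values():
            assert np.isnan(v) or 0 <= v <= 100


class TestConfidenceInterval:
    @pytest.mark.parametrize("mean,std,lo,hi", [
        (90.86, 3.76, 88.17, 93.55),   # accuracy row, k=10
        (95.12, 2.03, 93.67, 96.57),   # F1 row, k=10
    ])
    def test_printed_rows_exact_to_2_decimals(self, mean, std, lo, hi):
        a, b = confidence_interval(mean, std, 10)
        assert round_half_up(a, 2) == lo and round_half_up(b, 2) == hi

    @pytest.mark.parametrize("mean,std,lo,hi", [
        (96.71, 2.06, 95.24, 98.19),   # precision row
        (93.65, 3.30, 91.30, 96.01),   # recall row
    ])
    def test_rows_with_rounded_stds_within_printed_precision(self, mean, std, lo, hi):
        # the printed +-std is itself rounded to 2 dp, which moves a bound by
        # up to ~0.016; agree to within 0.02 of the printed interval
        a, b = confidence_interval(mean, std, 10)
        assert abs(a - lo) <= 0.02 and abs(b - hi) <= 0.02

    def test_zero_spread_degenerate_interval(self):
        assert confidence_interval(88.0, 0.0, 5) == (88.0, 88.0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            confidence_interval(90.0, 1.0, 1)


def test_summarize_folds_reproduces_ci_formula():
    from copdscreen.metrics import FoldMetrics
    vals = [88.0, 92.0, 95.0, 90.0, 91.0]
    folds = [FoldMetrics(accuracy=v, precision=v, recall=v, f1=v,
                         specificity=v) for v in vals]
    s = summarize_folds(folds)
    m, sd = np.mean(vals), np.std(vals, ddof=1)
    lo, hi = confidence_interval(m, sd, 5)
    assert s.mean["accuracy"] == pytest.approx(m)
    assert s.ci95["accuracy"] == (pytest.approx(lo), pytest.approx(hi))
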