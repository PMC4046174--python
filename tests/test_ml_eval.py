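"""Metrics, F-score, OOB permutation importance, grids and the protocol."""

from fractions import Fraction

import numpy as np
import pytest

from mirfeat.ml_eval import (
    ConfusionCounts,
    EvalResult,
    OOBForest,
    TuningGrids,
    fscore,
    g2de_param_count,
    metrics,
    permutation_importance,
    protocol_arithmetic,
    protocol_splits,
    run_protocol,
    select_by_fscore,
    tune_rf,
    tune_svm,
)


def metrics_oracle(tp, fn, tn, fp):
    """Independent exact-fraction implementation of the five measures."""
    out = {}
    total = tp + fn + tn + fp

    def frac(num, den):
        return float(100 * Fraction(num, den)) if den else None

    out["Acc"] = frac(tp + tn, total)
    out["Se"] = frac(tp, tp + fn)
    out["Sp"] = frac(tn, tn + fp)
    out["Fm"] = frac(2 * tp, 2 * tp + fn + fp)
    den = (tp + fp) * (tn + fn) * (tp + fn) * (tn + fp)
    out["Mcc"] = (
        100 * (tp * tn - fp * fn) / den**0.5 if den else None
    )
    return out


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(TP=459, FN=0, TN=459, FP=0))
        assert (m.Acc, m.Se, m.Sp, m.Fm, m.Mcc) == (100,) * 5

    def test_worked_counts_match_oracle(self):
        cc = ConfusionCounts(TP=90, FN=10, TN=95, FP=5)
        m = metrics(cc)
        oracle = metrics_oracle(*cc)
        assert m.Acc == pytest.approx(92.5)
        assert m.Se == pytest.approx(90.0)
        assert m.Sp == pytest.approx(95.0)
        assert m.Fm == pytest.approx(92.3077, abs=5e-5)
        for name, val in oracle.items():
            assert getattr(m, name) == pytest.approx(val, abs=1e-9)
        # cross-check Mcc against sklearn on equivalent label vectors
        from sklearn.metrics import matthews_corrcoef

        y_true = [1] * 100 + [0] * 100
        y_pred = [1] * 90 + [0] * 10 + [1] * 5 + [0] * 95
        assert m.Mcc == pytest.approx(
            100 * matthews_corrcoef(y_true, y_pred), abs=1e-9
        )

    def test_symmetric_counts_zero_mcc(self):
        m = metrics(ConfusionCounts(TP=25, FN=25, TN=25, FP=25))
        assert m.Mcc == 0.0

    def test_zero_denominators_flagged(self):
        m = metrics(ConfusionCounts(TP=0, FN=0, TN=10, FP=0))
        assert "Se" in m.undefined
        assert "Mcc" in m.undefined
        assert m.Se == 0.0

    def test_random_sweep_matches_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            tp, fn, tn, fp = rng.integers(0, 16, 4)
            m = metrics(ConfusionCounts(int(tp), int(fn), int(tn), int(fp)))
            for name, val in metrics_oracle(tp, fn, tn, fp).items():
                if val is None:
                    assert name in m.undefined
                else:
                    assert getattr(m, name) == pytest.approx(val, abs=1e-9)

    def test_fm_harmonic_mean_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            tp, fn, tn, fp = (int(x) for x in rng.integers(1, 50, 4))
            m = metrics(ConfusionCounts(tp, fn, tn, fp))
            prec = 100 * tp / (tp + fp)
            harmonic = 2 * m.Se * prec / (m.Se + prec)
            assert m.Fm == pytest.approx(harmonic, abs=1e-9)


class TestFscore:
    def test_hand_example(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([1, 1, -1, -1])
        assert fscore(X, y)[0] == pytest.approx(2.0)

    def test_identical_distributions_zero(self):
        X = np.array([[1.0], [2.0], [1.0], [2.0]])
        y = np.array([1, 1, -1, -1])
        assert fscore(X, y)[0] == 0.0

    def test_zero_within_variance_inf_flag(self):
        X = np.array([[1.0], [1.0], [2.0], [2.0]])
        y = np.array([1, 1, -1, -1])
        assert np.isinf(fscore(X, y)[0])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(40, 6))
        y = np.where(rng.random(40) < 0.5, 1, -1)
        if abs(y.sum()) >= 38:
            y[:2] = [1, -1]
        scores = fscore(X, y)
        pos, neg = X[y == 1], X[y == -1]
        for i in range(6):
            xb, xp, xn = X[:, i].mean(), pos[:, i].mean(), neg[:, i].mean()
            num = (xp - xb) ** 2 + (xn - xb) ** 2
            den = (
                ((pos[:, i] - xp) ** 2).sum() / (len(pos) - 1)
                + ((neg[:, i] - xn) ** 2).sum() / (len(neg) - 1)
            )
            assert scores[i] == pytest.approx(num / den)

    def test_select_by_threshold(self):
        rng = np.random.default_rng(2)
        n = 120
        y = np.array([1] * (n // 2) + [-1] * (n // 2))
        X = rng.normal(size=(n, 13))
        X[y == 1, :3] += 2.0  # three informative columns
        names = [f"f{i}" for i in range(13)]
        sel = select_by_fscore(X, y, names, thresholds=[0.0, 0.5, 1e9])
        assert sel[0.0][0] in ("f0", "f1", "f2")
        assert len(sel[0.0]) == 13
        assert set(sel[0.5]) == {"f0", "f1", "f2"}
        assert sel[1e9] == []


class _MockOOBLearner:
    """One OOB resample of 580 vectors: 500 correct on the original matrix,
    36 after any permutation of its single column."""

    def __init__(self, X, y):
        self.X0 = X.copy()
        self.y = y

    def oob_resamples(self):
        def predict(X):
            if np.array_equal(X, self.X0):
                pred = self.y.copy()
                pred[500:] = -pred[500:]  # 80 wrong: 500 correct
            else:
                pred = -self.y.copy()
                pred[:36] = self.y[:36]  # 36 correct
            return pred

        return [(predict, np.arange(len(self.y)))]


class TestPermutationImportance:
    def test_worked_count_example(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(580, 1))
        y = np.where(rng.random(580) < 0.5, 1, -1)
        imp = permutation_importance(_MockOOBLearner(X, y), X, y, seed=1)
        assert imp[0] == pytest.approx(464.0)

    def test_noise_column_near_zero(self):
        rng = np.random.default_rng(3)
        n = 580
        y = np.array([1] * (n // 2) + [-1] * (n // 2))
        X = np.column_stack([y + rng.normal(0, 0.3, n), rng.normal(size=n)])
        forest = OOBForest(n_trees=50, seed=5).fit(X, y)
        imp = permutation_importance(forest, X, y, seed=5)
        assert abs(imp[1]) < 3.0
        assert imp[0] > 50.0

    def test_separating_column_importance(self):
        rng = np.random.default_rng(9)
        n = 200
        y = np.array([1] * (n // 2) + [-1] * (n // 2))
        X = np.column_stack([y * 1.0, rng.normal(size=n)])
        forest = OOBForest(n_trees=30, seed=2).fit(X, y)
        imp = permutation_importance(forest, X, y, seed=2)
        oob_sizes = [len(o) for _, o in forest.oob_resamples()]
        # permuting the only informative column costs about half the OOB set
        assert imp[0] > 0.3 * np.mean(oob_sizes)


class TestGridsAndTuning:
    def test_printed_grids(self):
        g = TuningGrids()
        assert g.svm_C[0] == 2.0**-5 and g.svm_C[-1] == 2.0**15
        assert len(g.svm_C) == 11
        assert g.svm_gamma[0] == 2.0**-15 and g.svm_gamma[-1] == 2.0**3
        assert len(g.svm_gamma) == 10
        assert g.rf_trees == (30, 40, 50, 60, 70, 80, 90, 100, 150, 250,
                              350, 450)
        assert g.rf_mtry_mult == (0.5, 0.75, 1.0, 1.25, 1.5)

    def small_data(self):
        rng = np.random.default_rng(6)
        n = 60
        y = np.array([1] * (n // 2) + [-1] * (n // 2))
        X = rng.normal(size=(n, 4))
        X[y == 1, 0] += 3.0
        return X, y

    def test_svm_tuning_reproducible(self):
        X, y = self.small_data()
        grid = TuningGrids(svm_C=(0.5, 2.0), svm_gamma=(0.05, 0.2))
        a = tune_svm(X, y, grid, seed=1)
        b = tune_svm(X, y, grid, seed=1)
        assert a == b

    def test_svm_tiebreak_prefers_small_c_gamma(self):
        X, y = self.small_data()
        # a grid where both points separate perfectly: tie on accuracy
        grid = TuningGrids(svm_C=(1.0, 100.0), svm_gamma=(0.1,))
        C, gamma, acc = tune_svm(X, y, grid, seed=0)
        if acc == 1.0:
            assert C == 1.0

    def test_rf_tuning_reproducible(self):
        X, y = self.small_data()
        grid = TuningGrids(rf_trees=(30, 40), rf_mtry_mult=(0.5, 1.0))
        assert tune_rf(X, y, grid, seed=3) == tune_rf(X, y, grid, seed=3)

    def test_g2de_parameter_count(self):
        assert g2de_param_count(6, 7) == 216


class TestProtocol:
    def test_published_design_arithmetic(self):
        a = protocol_arithmetic(1377)
        assert a["gen_per_class"] == 459
        assert a["n_increments"] == 13
        assert a["largest_training_set"] == 1742

    def test_small_design_arithmetic(self):
        a = protocol_arithmetic(402)
        assert a["gen_per_class"] == 134
        assert a["n_increments"] == 4
        assert a["largest_training_set"] == 536

    def test_gen_disjoint_from_training(self):
        for gp, gn, tp, tn in protocol_splits(300, 300, seed=8, reps=5):
            assert not set(gp) & set(tp)
            assert not set(gn) & set(tn)
            assert len(gp) == len(gn) == 100

    def test_insufficient_data_errors(self):
        with pytest.raises(ValueError, match="increment"):
            list(protocol_splits(60, 60, seed=0))

    def separable(self, n=260):
        rng = np.random.default_rng(4)
        y = np.array([1] * (n // 2) + [-1] * (n // 2))
        X = rng.normal(size=(n, 3))
        X[y == 1, 0] += 6.0
        return X, y

    def test_separable_data_all_hundred(self):
        X, y = self.separable()
        grid = TuningGrids(svm_C=(1.0,), svm_gamma=(0.1,))
        res = run_protocol(X, y, learner="svm", grids=grid, seed=1, reps=3,
                           increment=20)
        for name in ("Acc", "Se", "Sp", "Fm", "Mcc"):
            assert res.mean(name) == 100.0
            assert res.sd(name) == 0.0

    def test_protocol_deterministic(self):
        X, y = self.separable()
        grid = TuningGrids(svm_C=(1.0,), svm_gamma=(0.1,))
        r1 = run_protocol(X, y, grids=grid, seed=2, reps=2, increment=20)
        r2 = run_protocol(X, y, grids=grid, seed=2, reps=2, increment=20)
        assert [m.as_dict() for m in r1.per_rep] == [
            m.as_dict() for m in r2.per_rep
        ]

    def test_rf_protocol_runs(self):
        X, y = self.separable(200)
        grid = TuningGrids(rf_trees=(30,), rf_mtry_mult=(1.0,))
        res = run_protocol(X, y, learner="rf", grids=grid, seed=3, reps=2,
                           increment=20)
        assert res.mean("Acc") > 95.0

    def test_summary_format(self):
        r = EvalResult(
            per_rep=[metrics(ConfusionCounts(10, 0, 10, 0))] * 2,
            learner="svm",
        )
        assert "Acc = 100.0 ± 0.0" in r.summary()
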