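"""Classification metrics, feature-selection statistics and the repeated
holdout evaluation protocol.

Metrics are reported on the 0–100 scale: accuracy, sensitivity,
specificity, F-measure and the Matthews correlation coefficient,

    Acc = 100 (TP+TN) / (TP+FN+TN+FP)
    Se  = 100 TP / (TP+FN)
    Sp  = 100 TN / (TN+FP)
    Fm  = 100 · 2TP / (2TP+FN+FP)
    Mcc = 100 (TP·TN − FP·FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP))

The protocol repeats, by default 10 times: draw a class-balanced held-out
test partition (GEN) of ⌊n⁺/3⌋ sequences per class, build balanced training
sets from the remainder in increments of 67 per class, tune the learner on
the training set only (SVM: 5-fold CV accuracy over the published
C × γ grid; RF: lowest out-of-bag error over the published
trees × mtry-multiplier grid), and evaluate the tuned model on GEN.
Results are summarized as mean ± SD over repetitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "metrics",
    "fscore",
    "select_by_fscore",
    "permutation_importance",
    "OOBForest",
    "TuningGrids",
    "tune_svm",
    "tune_rf",
    "protocol_splits",
    "run_protocol",
    "EvalResult",
    "g2de_param_count",
]

METRIC_NAMES = ("Acc", "Se", "Sp", "Fm", "Mcc")


class ConfusionCounts(NamedTuple):
    TP: int
    FN: int
    TN: int
    FP: int

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionCounts":
        yt = np.asarray(y_true)
        yp = np.asarray(y_pred)
        pos = yt == 1
        return cls(
            TP=int(np.sum(pos & (yp == 1))),
            FN=int(np.sum(pos & (yp != 1))),
            TN=int(np.sum(~pos & (yp != 1))),
            FP=int(np.sum(~pos & (yp == 1))),
        )


@dataclass(frozen=True)
class Metrics:
    """Acc/Se/Sp/Fm/Mcc on the 0–100 scale; undefined metrics are 0-valued
    and listed in ``undefined``."""

    Acc: float
    Se: float
    Sp: float
    Fm: float
    Mcc: float
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def metrics(cc: ConfusionCounts) -> Metrics:
    """Compute the five performance measures from confusion counts."""
    tp, fn, tn, fp = cc
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be non-negative")
    undefined = set()
    total = tp + fn + tn + fp

    def ratio(name: str, num: float, denom: float) -> float:
        if denom == 0:
            undefined.add(name)
            return 0.0
        return 100.0 * num / denom

    acc = ratio("Acc", tp + tn, total)
    se = ratio("Se", tp, tp + fn)
    sp = ratio("Sp", tn, tn + fp)
    fm = ratio("Fm", 2 * tp, 2 * tp + fn + fp)
    denom = (tp + fp) * (tn + fn) * (tp + fn) * (tn + fp)
    if denom == 0:
        undefined.add("Mcc")
        mcc = 0.0
    else:
        mcc = 100.0 * (tp * tn - fp * fn) / math.sqrt(denom)
    return Metrics(Acc=acc, Se=se, Sp=sp, Fm=fm, Mcc=mcc,
                   undefined=frozenset(undefined))


# ---------------------------------------------------------------------------
# Feature selection


def fscore(X: np.ndarray, y: Sequence[int]) -> np.ndarray:
    """Per-feature F-score: between-class separation over pooled
    within-class variance.

    F(i) = [(x̄⁺−x̄)² + (x̄⁻−x̄)²] /
           [(1/(n⁺−1)) Σ⁺ (x−x̄⁺)² + (1/(n⁻−1)) Σ⁻ (x−x̄⁻)²]

    Features with zero pooled within-class variance score +inf when the
    class means differ and 0 otherwise (the infinite-score flag).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos, neg = X[y == 1], X[y != 1]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs at least 2 instances")
    grand = X.mean(axis=0)
    mp, mn = pos.mean(axis=0), neg.mean(axis=0)
    num = (mp - grand) ** 2 + (mn - grand) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    out = np.empty(X.shape[1])
    zero = den == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out[~zero] = num[~zero] / den[~zero]
    out[zero] = np.where(num[zero] > 0, np.inf, 0.0)
    return out


def select_by_fscore(
    X: np.ndarray,
    y: Sequence[int],
    feature_names: Sequence[str],
    thresholds: Iterable[float],
) -> dict[float, list[str]]:
    """For each threshold, the features with F-score >= threshold, ordered by
    score descending (ties broken by canonical feature order)."""
    scores = fscore(X, y)
    order = sorted(
        range(len(feature_names)), key=lambda i: (-scores[i], i)
    )
    out: dict[float, list[str]] = {}
    for t in thresholds:
        out[t] = [feature_names[i] for i in order if scores[i] >= t]
    return out


class OOBForest:
    """A bagged decision-tree ensemble with explicit out-of-bag bookkeeping.

    Each tree is fitted on a bootstrap resample; the complementary
    out-of-bag rows are retained per tree so that Breiman-style permutation
    importance (correct-count difference on OOB vectors) can be computed.
    """

    def __init__(self, n_trees: int = 100, max_features: int | str = "sqrt",
                 seed: int = 0) -> None:
        self.n_trees = n_trees
        self.max_features = max_features
        self.seed = seed
        self._trees: list = []
        self._oob: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: Sequence[int]) -> "OOBForest":
        from sklearn.tree import DecisionTreeClassifier

        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.seed)
        n = len(y)
        self._trees, self._oob = [], []
        for t in range(self.n_trees):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[boot], y[boot])
            self._trees.append(tree)
            self._oob.append(oob)
        self._X, self._y = X, y
        return self

    def oob_resamples(self):
        """Per-tree (predict_fn, oob_indices) pairs."""
        return [(tree.predict, oob) for tree, oob in zip(self._trees, self._oob)]

    def predict(self, X: np.ndarray) -> np.ndarray:
        votes = np.stack([t.predict(X) for t in self._trees])
        out = []
        for col in votes.T:
            vals, counts = np.unique(col, return_counts=True)
            out.append(vals[np.argmax(counts)])
        return np.array(out)


def permutation_importance(
    learner,
    X: np.ndarray,
    y: Sequence[int],
    seed: int = 0,
) -> np.ndarray:
    """Out-of-bag permutation importance on the correct-count scale.

    For every feature i and every OOB resample exposed by the learner, count
    the correctly classified OOB vectors before and after permuting column i
    within the OOB rows; the importance of feature i is the mean difference
    over resamples.  (E.g. 500 correct before and 36 after a permutation
    gives an importance of 464.)

    The learner must expose ``oob_resamples() -> [(predict_fn, oob_idx)]``;
    :class:`OOBForest` does.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    resamples = list(learner.oob_resamples())
    if not resamples:
        raise ValueError("learner exposed no OOB resamples")
    d = X.shape[1]
    diffs = np.zeros((len(resamples), d))
    for r, (predict, oob) in enumerate(resamples):
        Xo, yo = X[oob], y[oob]
        before = int(np.sum(predict(Xo) == yo))
        for i in range(d):
            Xp = Xo.copy()
            Xp[:, i] = Xp[rng.permutation(len(Xo)), i]
            after = int(np.sum(predict(Xp) == yo))
            diffs[r, i] = before - after
    return diffs.mean(axis=0)


def g2de_param_count(k: int, d: int) -> int:
    """Parameter count of a generalized-Gaussian mixture density classifier
    with k components in d dimensions: k(d+2)(d+1)/2."""
    return k * (d + 2) * (d + 1) // 2


# ---------------------------------------------------------------------------
# Learner tuning


@dataclass(frozen=True)
class TuningGrids:
    """The published hyper-parameter grids.

    SVM (RBF): C ∈ 2^{-5,-3,…,15}, γ ∈ 2^{-15,-13,…,3}.
    RF: trees ∈ {30,…,450}, mtry = multiplier · sqrt(d) with multipliers
    {0.5, 0.75, 1, 1.25, 1.5}.
    """

    svm_C: tuple[float, ...] = tuple(2.0 ** e for e in range(-5, 16, 2))
    svm_gamma: tuple[float, ...] = tuple(2.0 ** e for e in range(-15, 4, 2))
    rf_trees: tuple[int, ...] = (30, 40, 50, 60, 70, 80, 90, 100, 150, 250,
                                 350, 450)
    rf_mtry_mult: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5)


def tune_svm(
    X: np.ndarray,
    y: Sequence[int],
    grid: TuningGrids | None = None,
    seed: int = 0,
    cv: int = 5,
) -> tuple[float, float, float]:
    """5-fold CV accuracy over the C × γ grid.

    Returns (C, gamma, cv_accuracy); ties resolved toward the smallest C,
    then the smallest γ.  Features are standardized inside each CV fold.
    """
    from sklearn.model_selection import StratifiedKFold
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    grid = grid or TuningGrids()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best = (-1.0, None, None)
    for C in sorted(grid.svm_C):
        for gamma in sorted(grid.svm_gamma):
            correct = 0
            for tr, te in folds:
                clf = make_pipeline(
                    StandardScaler(), SVC(C=C, gamma=gamma, kernel="rbf")
                )
                clf.fit(X[tr], y[tr])
                correct += int(np.sum(clf.predict(X[te]) == y[te]))
            acc = correct / len(y)
            if acc > best[0]:
                best = (acc, C, gamma)
    return best[1], best[2], best[0]


def tune_rf(
    X: np.ndarray,
    y: Sequence[int],
    grid: TuningGrids | None = None,
    seed: int = 0,
) -> tuple[int, int, float]:
    """Lowest OOB error over the trees × mtry grid.

    Returns (n_trees, mtry, oob_error); ties resolved toward fewer trees,
    then smaller mtry.
    """
    from sklearn.ensemble import RandomForestClassifier

    grid = grid or TuningGrids()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    d = X.shape[1]
    best = (np.inf, None, None)
    for trees in sorted(grid.rf_trees):
        for mult in sorted(grid.rf_mtry_mult):
            mtry = max(1, min(d, round(mult * math.sqrt(d))))
            rf = RandomForestClassifier(
                n_estimators=trees, max_features=mtry, oob_score=True,
                random_state=seed, n_jobs=1,
            )
            rf.fit(X, y)
            err = 1.0 - rf.oob_score_
            if err < best[0]:
                best = (err, trees, mtry)
    return best[1], best[2], best[0]


# ---------------------------------------------------------------------------
# Protocol


def protocol_splits(
    n_pos: int,
    n_neg: int,
    seed: int,
    reps: int = 10,
    gen_frac: float = 1.0 / 3.0,
    increment: int = 67,
):
    """Index-level splits of the repeated-holdout protocol.

    Yields, per repetition, ``(gen_pos, gen_neg, train_pos, train_neg)``
    where the train arrays hold the full remainder in sampling order;
    training sets of k increments use the first 67·k entries of each.
    Positions index the positive (0..n_pos-1) and negative (0..n_neg-1)
    pools separately.
    """
    gen_per_class = int(n_pos * gen_frac)
    if gen_per_class < 1 or n_neg < gen_per_class:
        raise ValueError("not enough records for a balanced GEN partition")
    n_inc = min(n_pos - gen_per_class, n_neg - gen_per_class) // increment
    if n_inc < 1:
        raise ValueError(
            f"remainder too small for one training increment of {increment} "
            f"per class (need GEN {gen_per_class} + {increment} per class)"
        )
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        pos_perm = rng.permutation(n_pos)
        neg_perm = rng.permutation(n_neg)
        yield (
            pos_perm[:gen_per_class],
            neg_perm[:gen_per_class],
            pos_perm[gen_per_class:],
            neg_perm[gen_per_class:],
        )


def protocol_arithmetic(
    n_pos: int, gen_frac: float = 1.0 / 3.0, increment: int = 67,
    n_neg: int | None = None,
) -> dict[str, int]:
    """Experiment-design numbers for a balanced design of n_pos positives:
    per-class GEN size, number of training increments, and the largest
    balanced training-set size."""
    n_neg = n_pos if n_neg is None else n_neg
    gen = int(n_pos * gen_frac)
    n_inc = min(n_pos - gen, n_neg - gen) // increment
    return {
        "gen_per_class": gen,
        "n_increments": n_inc,
        "largest_training_set": 2 * increment * n_inc,
    }


@dataclass
class EvalResult:
    """Per-repetition metrics and their mean ± SD."""

    per_rep: list[Metrics]
    learner: str
    chosen_params: list[tuple] = field(default_factory=list)

    def mean(self, name: str) -> float:
        return float(np.mean([getattr(m, name) for m in self.per_rep]))

    def sd(self, name: str) -> float:
        vals = [getattr(m, name) for m in self.per_rep]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> str:
        parts = [
            f"{n} = {self.mean(n):.1f} ± {self.sd(n):.1f}"
            for n in METRIC_NAMES
        ]
        return f"[{self.learner}] " + ", ".join(parts)

    def as_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        for n in METRIC_NAMES:
            row[f"{n}_mean"] = self.mean(n)
            row[f"{n}_sd"] = self.sd(n)
        return row


def run_protocol(
    X: np.ndarray,
    y: Sequence[int],
    learner: str = "svm",
    grids: TuningGrids | None = None,
    seed: int = 0,
    reps: int = 10,
    train_increments: int | None = None,
    increment: int = 67,
) -> EvalResult:
    """Run the repeated-holdout protocol on a feature matrix.

    ``y`` holds +1 for positives and −1 (or 0) for negatives.  By default
    the largest balanced training set the data supports is used (the size at
    which the published experiments converged); ``train_increments`` selects
    a smaller number of 67-per-class increments.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    X = np.asarray(X, dtype=float)
    y = np.where(np.asarray(y) == 1, 1, -1)
    grids = grids or TuningGrids()
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == -1)
    arith = protocol_arithmetic(len(pos_idx), n_neg=len(neg_idx),
                                increment=increment)
    k = arith["n_increments"] if train_increments is None else train_increments
    if not (1 <= k <= arith["n_increments"]):
        raise ValueError(
            f"train_increments must be in [1, {arith['n_increments']}]"
        )
    per_class = increment * k

    per_rep: list[Metrics] = []
    chosen: list[tuple] = []
    for rep, (gp, gn, tp_pool, tn_pool) in enumerate(
        protocol_splits(len(pos_idx), len(neg_idx), seed=seed, reps=reps,
                        increment=increment)
    ):
        tr = np.concatenate([
            pos_idx[tp_pool[:per_class]], neg_idx[tn_pool[:per_class]]
        ])
        te = np.concatenate([pos_idx[gp], neg_idx[gn]])
        Xtr, ytr = X[tr], y[tr]
        Xte, yte = X[te], y[te]
        rep_seed = seed * 1000 + rep
        if learner == "svm":
            C, gamma, _ = tune_svm(Xtr, ytr, grids, seed=rep_seed)
            model = make_pipeline(
                StandardScaler(), SVC(C=C, gamma=gamma, kernel="rbf")
            )
            chosen.append((C, gamma))
        elif learner == "rf":
            trees, mtry, _ = tune_rf(Xtr, ytr, grids, seed=rep_seed)
            model = RandomForestClassifier(
                n_estimators=trees, max_features=mtry,
                random_state=rep_seed, n_jobs=1,
            )
            chosen.append((trees, mtry))
        else:
            raise ValueError(f"unknown learner {learner!r} (svm or rf)")
        model.fit(Xtr, ytr)
        cc = ConfusionCounts.from_predictions(yte, model.predict(Xte))
        per_rep.append(metrics(cc))
    return EvalResult(per_rep=per_rep, learner=learner, chosen_params=chosen)
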