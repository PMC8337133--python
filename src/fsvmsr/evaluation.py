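"""Evaluation protocol: whole/per-class accuracy, stratified k-fold CV,
(C, gamma) grid search, ROC/AUC, and the repeated-CV two-sample t-test.

Accuracy follows the per-class decomposition

    whole ACC = 100 * sum_i TP_i / M,    ACC_i = 100 * TP_i / M_i,

so the whole accuracy is always the class-size-weighted mean of the
per-class accuracies.  Folds are stratified: with classes of 11-17 members
out of 59, unstratified 10-fold splits can lose a class from a training
fold entirely.  Memberships and the standardizer are fitted per training
fold only — test rows never touch the self-representation stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import Dataset, fit_standardizer
from .errors import (
    DegenerateStatisticError,
    DimensionMismatchError,
    EmptyClassError,
    InvalidParameterError,
)
from .fsvm import FSVMHyperParams, fit_multiclass, predict
from .self_representation import DEFAULT_LAMBDA, compute_memberships

__all__ = [
    "EvalResult",
    "CVReport",
    "GridSearchReport",
    "TTestReport",
    "score",
    "stratified_kfold",
    "cross_validate",
    "grid_search",
    "roc_auc",
    "repeated_cv_ttest",
    "welch_ttest",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
]

#: default hyperparameter search ranges: C in 2^-5..2^10, gamma in 2^-10..2^5,
#: multiplicative step 2.
DEFAULT_C_GRID = tuple(2.0**p for p in range(-5, 11))
DEFAULT_GAMMA_GRID = tuple(2.0**p for p in range(-10, 6))


@dataclass(frozen=True)
class EvalResult:
    whole_acc: float  # percent
    per_class_acc: tuple  # percent per class; None where the class is absent
    confusion: np.ndarray  # c x c counts, rows = truth
    M: int
    M_per_class: tuple
    TP_per_class: tuple


def score(pred, truth, c: int) -> EvalResult:
    """Per-class and whole accuracy from predicted vs true class indices (1..c).

    A class absent from ``truth`` has undefined per-class accuracy, reported
    as None (never as 0)."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise DimensionMismatchError("pred and truth must have equal length")
    if truth.size == 0:
        raise InvalidParameterError("cannot score an empty test set")
    if np.any((truth < 1) | (truth > c)) or np.any((pred < 1) | (pred > c)):
        raise InvalidParameterError(f"labels must lie in 1..{c}")
    conf = np.zeros((c, c), dtype=int)
    for t, p in zip(truth, pred):
        conf[t - 1, p - 1] += 1
    M_i = conf.sum(axis=1)
    TP_i = np.diag(conf)
    whole = 100.0 * TP_i.sum() / truth.size
    per_class = tuple(
        100.0 * TP_i[k] / M_i[k] if M_i[k] > 0 else None for k in range(c)
    )
    return EvalResult(
        whole_acc=whole,
        per_class_acc=per_class,
        confusion=conf,
        M=int(truth.size),
        M_per_class=tuple(int(m) for m in M_i),
        TP_per_class=tuple(int(t) for t in TP_i),
    )


def stratified_kfold(labels, k: int, seed: int):
    """Deterministic stratified partition into k folds of test indices.

    Per-class counts across folds differ by at most 1; classes smaller than
    k simply miss some folds (so leave-one-out, k = N, is permitted).
    Each class's shuffled members are dealt to the currently smallest
    folds, which also keeps total fold sizes within 1 of each other.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    if k > labels.shape[0]:
        raise InvalidParameterError(f"k={k} exceeds N={labels.shape[0]}")
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        for start in range(0, idx.size, k):
            chunk = idx[start:start + k]
            sizes = np.array([len(f) for f in folds])
            order = np.argsort(sizes, kind="stable")
            for j, i in enumerate(chunk):
                folds[order[j]].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds]


@dataclass(frozen=True)
class CVReport:
    fold_results: tuple
    mean_whole_acc: float
    sd_whole_acc: float
    mean_per_class_acc: tuple
    sd_per_class_acc: tuple
    seed: int
    pooled_scores: np.ndarray | None  # held-out decision values (binary only)
    pooled_truth: np.ndarray | None


def _fold_accs(fold_results, c):
    whole = np.array([fr.whole_acc for fr in fold_results])
    per_class = []
    for k in range(c):
        vals = [fr.per_class_acc[k] for fr in fold_results
                if fr.per_class_acc[k] is not None]
        per_class.append(np.array(vals))
    return whole, per_class


def cross_validate(
    dataset: Dataset,
    params: FSVMHyperParams,
    k: int = 10,
    seed: int = 0,
    method: str = "fsvm_sr",
    gamma_sim: float | None = None,
    lam: float = DEFAULT_LAMBDA,
) -> CVReport:
    """Stratified k-fold CV of the one-vs-one classifier.

    ``method`` is "fsvm_sr" (memberships from self-representation on each
    training fold) or "svm" (all memberships 1 — the unweighted baseline).
    The similarity bandwidth gamma_sim defaults to the classifier gamma.
    Per fold: standardizer and memberships are fitted on training rows only.
    """
    if method not in ("fsvm_sr", "svm"):
        raise InvalidParameterError(f"unknown method {method!r}")
    y = dataset.labels
    classes = sorted(np.unique(y))
    c = len(classes)
    if classes != list(range(1, c + 1)):
        raise InvalidParameterError("labels must be contiguous class indices 1..c")
    folds = stratified_kfold(y, k, seed)
    if gamma_sim is None:
        gamma_sim = params.gamma

    results = []
    pooled_scores, pooled_truth = [], []
    for test_idx in folds:
        train_mask = np.ones(dataset.N, dtype=bool)
        train_mask[test_idx] = False
        train = dataset.subset(np.flatnonzero(train_mask))
        if len(np.unique(train.labels)) < c:
            raise EmptyClassError("a training fold lost a class entirely")
        std = fit_standardizer(train)
        train_std = Dataset(
            std.transform(train.features), train.labels, train.feature_names
        )
        if method == "fsvm_sr":
            s = compute_memberships(
                train_std.features, gamma_sim=gamma_sim, lam=lam, standardize=False
            ).memberships
        else:
            s = np.ones(train.N)
        model = fit_multiclass(train_std, s, params)
        Xte = std.transform(dataset.features[test_idx])
        pred, scores_ = predict(model, Xte)
        results.append(score(pred, y[test_idx], c))
        if c == 2 and scores_ is not None:
            pooled_scores.append(scores_)
            pooled_truth.append(np.where(y[test_idx] == 1, 1, -1))

    whole, per_class = _fold_accs(results, c)
    return CVReport(
        fold_results=tuple(results),
        mean_whole_acc=float(whole.mean()),
        sd_whole_acc=float(whole.std(ddof=1)) if len(whole) > 1 else 0.0,
        mean_per_class_acc=tuple(
            float(v.mean()) if v.size else None for v in per_class
        ),
        sd_per_class_acc=tuple(
            float(v.std(ddof=1)) if v.size > 1 else 0.0 for v in per_class
        ),
        seed=seed,
        pooled_scores=np.concatenate(pooled_scores) if pooled_scores else None,
        pooled_truth=np.concatenate(pooled_truth) if pooled_truth else None,
    )


@dataclass(frozen=True)
class GridSearchReport:
    grid: tuple  # tuples (C, gamma, mean_acc, sd_acc)
    best_C: float
    best_gamma: float
    best_mean_acc: float
    C_range: tuple
    gamma_range: tuple


def grid_search(
    dataset: Dataset,
    k: int = 10,
    seed: int = 0,
    method: str = "fsvm_sr",
    C_range=DEFAULT_C_GRID,
    gamma_range=DEFAULT_GAMMA_GRID,
    lam: float = DEFAULT_LAMBDA,
) -> GridSearchReport:
    """Exhaustive (C, gamma) search by mean CV whole accuracy.

    Folds are fixed across cells (same seed), so cells are comparable.
    Ties are broken by smaller C, then smaller gamma.
    """
    if not C_range or not gamma_range:
        raise InvalidParameterError("search ranges must be non-empty")
    cells = []
    best = None
    for C in C_range:
        for gamma in gamma_range:
            rep = cross_validate(
                dataset, FSVMHyperParams(C=C, gamma=gamma), k=k, seed=seed,
                method=method, lam=lam,
            )
            cells.append((C, gamma, rep.mean_whole_acc, rep.sd_whole_acc))
            key = (-rep.mean_whole_acc, C, gamma)
            if best is None or key < best[0]:
                best = (key, C, gamma, rep.mean_whole_acc)
    return GridSearchReport(
        grid=tuple(cells),
        best_C=best[1],
        best_gamma=best[2],
        best_mean_acc=best[3],
        C_range=tuple(C_range),
        gamma_range=tuple(gamma_range),
    )


def roc_auc(scores, truth):
    """AUC by the rank (Mann–Whitney) method with half credit for ties,
    plus the ROC point list (FPR, TPR) swept over thresholds.

    ``truth`` is a vector in {-1, +1}; higher scores should indicate +1.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    pos = truth == 1
    neg = ~pos
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateStatisticError("ROC needs both classes in truth")
    ranks = stats.rankdata(scores)  # average ranks give tie half-credit
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(pos[order])
    fps = np.cumsum(neg[order])
    # collapse threshold ties: keep the last index of each distinct score
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), len(scores) - 1]
    points = [(0.0, 0.0)] + [
        (fps[i] / n_neg, tps[i] / n_pos) for i in distinct
    ]
    return float(auc), points


@dataclass(frozen=True)
class TTestReport:
    t_stat: float
    p_value: float
    accs_a: np.ndarray
    accs_b: np.ndarray
    degenerate: bool


def repeated_cv_ttest(
    dataset: Dataset,
    params_a: FSVMHyperParams,
    params_b: FSVMHyperParams,
    method_a: str = "fsvm_sr",
    method_b: str = "svm",
    repeats: int = 20,
    k: int = 10,
    base_seed: int = 0,
    lam: float = DEFAULT_LAMBDA,
) -> TTestReport:
    """Welch two-sample t-test on per-repeat mean whole accuracies.

    Each repeat r uses fold seed base_seed + r for BOTH methods, so the two
    accuracy streams face identical fold assignments.  Two-sided p-value.
    Zero variance in both streams is degenerate: p is reported as exactly
    1 (equal means) or 0 (different means) and flagged.
    """
    if repeats < 2:
        raise InvalidParameterError("repeats must be >= 2")
    accs_a = np.array([
        cross_validate(dataset, params_a, k=k, seed=base_seed + r,
                       method=method_a, lam=lam).mean_whole_acc
        for r in range(repeats)
    ])
    accs_b = np.array([
        cross_validate(dataset, params_b, k=k, seed=base_seed + r,
                       method=method_b, lam=lam).mean_whole_acc
        for r in range(repeats)
    ])
    return welch_ttest(accs_a, accs_b)


def welch_ttest(accs_a, accs_b) -> TTestReport:
    """Two-sided Welch t-test on two accuracy streams, with the degenerate
    zero-variance-in-both case flagged (p = 1 for equal means, else 0)."""
    accs_a = np.asarray(accs_a, dtype=float)
    accs_b = np.asarray(accs_b, dtype=float)
    var_a, var_b = accs_a.var(ddof=1), accs_b.var(ddof=1)
    if var_a == 0.0 and var_b == 0.0:
        same = accs_a.mean() == accs_b.mean()
        return TTestReport(
            t_stat=0.0 if same else np.inf,
            p_value=1.0 if same else 0.0,
            accs_a=accs_a, accs_b=accs_b, degenerate=True,
        )
    t, p = stats.ttest_ind(accs_a, accs_b, equal_var=False)
    return TTestReport(
        t_stat=float(t), p_value=float(p),
        accs_a=accs_a, accs_b=accs_b, degenerate=False,
    )
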