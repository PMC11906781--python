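"""PLS-DA classification with repeated double cross-validation.

PLS-DA here is PLS2 regression on a one-hot class indicator matrix with
argmax class assignment.  Model complexity (number of latent variables) is
tuned by venetian-blinds cross-validation in an inner loop; an outer loop
of "cancellation groups" estimates generalization performance, and the
whole double loop is repeated with re-randomized splits (rDCV).  Variable
importance in projection (VIP) scores are accumulated over every outer
model, and a label-permutation test supplies the null distribution of the
accuracy.

The PLS engine is scikit-learn's NIPALS implementation; everything around
it (one-hot coding, fold protocol, VIP, metrics, permutation) is defined
here so the procedure is fully specified and reproducible.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .core import rng_for


class PLSDAError(ValueError):
    pass


@dataclass
class PLSDAModel:
    pls: PLSRegression
    class_order: list[str]
    n_components: int
    n_features: int

    @property
    def x_weights(self) -> np.ndarray:
        return self.pls.x_weights_

    @property
    def x_scores(self) -> np.ndarray:
        return self.pls.x_scores_

    @property
    def y_loadings(self) -> np.ndarray:
        return self.pls.y_loadings_

    @property
    def coefficients(self) -> np.ndarray:
        return self.pls.coef_


def _one_hot(y: np.ndarray, class_order: list[str]) -> np.ndarray:
    Y = np.zeros((len(y), len(class_order)))
    lookup = {c: j for j, c in enumerate(class_order)}
    for i, label in enumerate(y):
        Y[i, lookup[label]] = 1.0
    return Y


def fit_plsda(X: np.ndarray, y, n_components: int, class_order: list[str] | None = None) -> PLSDAModel:
    """Fit a PLS2 model on one-hot class indicators.

    Y columns follow ``class_order`` (sorted unique labels by default), which
    also fixes the deterministic argmax tie-break in prediction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_components < 1:
        raise PLSDAError("n_components must be >= 1")
    classes = sorted(set(y)) if class_order is None else list(class_order)
    if len(set(y)) < 2:
        raise PLSDAError("PLS-DA needs at least two classes")
    n, p = X.shape
    if n_components > min(n - 1, p):
        raise PLSDAError(f"n_components={n_components} exceeds min(n-1, p)={min(n - 1, p)}")
    Y = _one_hot(y, classes)
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign 'y residual constant' at high A
        pls.fit(X, Y)
    return PLSDAModel(pls=pls, class_order=classes, n_components=n_components, n_features=p)


def predict_classes(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    """Argmax over predicted one-hot responses; ties go to the first class in class_order."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.array([], dtype=object)
    if X.shape[1] != model.n_features:
        raise PLSDAError(f"expected {model.n_features} features, got {X.shape[1]}")
    Yhat = model.pls.predict(X)
    idx = np.argmax(Yhat, axis=1)  # first maximum wins: the stated tie-break
    return np.asarray(model.class_order, dtype=object)[idx]


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a ) with
    SSY_a = (t_a't_a)(q_a'q_a), the Y-variance captured by component a.
    The mean squared VIP equals 1 by construction.
    """
    W = model.x_weights
    T = model.x_scores
    Q = model.y_loadings
    p, A = W.shape
    ssy = np.array([(T[:, a] @ T[:, a]) * (Q[:, a] @ Q[:, a]) for a in range(A)])
    total = ssy.sum()
    if total <= 0:
        raise PLSDAError("model explains zero Y-variance; VIP undefined")
    wnorm2 = (W**2) / np.maximum((W**2).sum(axis=0), np.finfo(float).tiny)
    return np.sqrt(p * (wnorm2 @ ssy) / total)


# -- cross-validation machinery ----------------------------------------------

def _stratified_order(y: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
    """Interleave classes round-robin (optionally shuffling within class)."""
    y = np.asarray(y)
    per_class = []
    for c in pd.unique(y):
        idx = np.where(y == c)[0]
        if rng is not None:
            idx = rng.permutation(idx)
        per_class.append(list(idx))
    order = []
    for k in range(max(len(lst) for lst in per_class)):
        for lst in per_class:
            if k < len(lst):
                order.append(lst[k])
    return np.array(order, dtype=int)


def _venetian_folds(y: np.ndarray, folds: int, rng: np.random.Generator | None = None) -> np.ndarray:
    """Fold id per sample: position mod folds along the class-stratified ordering."""
    order = _stratified_order(y, rng)
    fold = np.empty(len(y), dtype=int)
    fold[order] = np.arange(len(y)) % folds
    return fold


def _predict_truncated(model: PLSDAModel, X: np.ndarray, n_components: int) -> np.ndarray:
    """Class predictions using only the first ``n_components`` latent variables.

    NIPALS components are nested: the A-component model's leading a
    components coincide with the a-component model, so one fit at max A
    serves every smaller candidate (exact to machine precision).
    """
    pls = model.pls
    T = (np.asarray(X, dtype=float) - pls._x_mean) @ pls.x_rotations_[:, :n_components]
    Yhat = pls._y_mean + T @ pls.y_loadings_[:, :n_components].T
    idx = np.argmax(Yhat, axis=1)
    return np.asarray(model.class_order, dtype=object)[idx]


def select_nlv(X, y, max_A: int, folds: int = 5, seed: int = 0) -> int:
    """Choose the latent-variable count by venetian-blinds cross-validation.

    Returns the A in 1..max_A minimizing mean CV misclassification, the
    smallest A on ties.  Errors if a training fold lacks a class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise PLSDAError("folds must be >= 2")
    if max_A < 1:
        raise PLSDAError("max_A must be >= 1")
    classes = sorted(set(y))
    fold = _venetian_folds(y, folds, rng_for(seed, "select_nlv"))
    cap = min(max_A, min(len(y) - int(np.bincount(fold).max()) - 1, X.shape[1]))
    cap = max(cap, 1)
    errs = np.zeros(cap)
    counts = np.zeros(cap)
    for f in range(folds):
        test = fold == f
        if not test.any():
            continue
        ytr = y[~test]
        if set(ytr) != set(classes):
            raise PLSDAError(
                f"training split of fold {f} lacks a class; use fewer folds or more samples"
            )
        m = fit_plsda(X[~test], ytr, cap, class_order=classes)
        for a in range(1, cap + 1):
            pred = _predict_truncated(m, X[test], a)
            errs[a - 1] += (pred != y[test]).sum()
            counts[a - 1] += test.sum()
    mean_err = errs / counts
    return int(np.argmin(mean_err)) + 1  # argmin takes the smallest A on ties


@dataclass
class RDCVResult:
    """Aggregated repeated-double-CV performance (percentages)."""

    accuracy_mean: float
    accuracy_sd: float
    class_order: list[str]
    sensitivity_mean: dict[str, float]
    sensitivity_sd: dict[str, float]
    specificity_mean: dict[str, float]
    specificity_sd: dict[str, float]
    misclassification_matrix: pd.DataFrame  # true class x predicted class, row % summing to 100
    vip_frequency: np.ndarray  # per feature, fraction of outer models with VIP > threshold
    chosen_A_distribution: dict[int, int]
    repeats: int
    seed: int
    per_repetition_accuracy: np.ndarray = field(default=None)  # type: ignore[assignment]


def classification_metrics(confusion: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-class sensitivity/specificity and overall accuracy, in percent.

    Rows of ``confusion`` are true classes, columns predicted.  A class with
    no true samples gets NaN sensitivity (reported as missing).
    """
    C = np.asarray(confusion, dtype=float)
    total = C.sum()
    if total == 0:
        raise PLSDAError("empty confusion matrix")
    tp = np.diag(C)
    row = C.sum(axis=1)
    col = C.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(row > 0, tp / row, np.nan) * 100.0
    tn = total - row - col + tp
    fp = col - tp
    spec = tn / (tn + fp) * 100.0
    acc = tp.sum() / total * 100.0
    return sens, spec, float(acc)


def _stratified_groups(y: np.ndarray, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Random class-stratified assignment into n_groups cancellation groups.

    Each class's shuffled samples are dealt round-robin across the groups
    from a random per-class starting offset, so group sizes per class differ
    by at most one: training folds stay as class-balanced as the counts
    allow (important for unbiased null behaviour of the outer loop).
    """
    y = np.asarray(y)
    groups = np.empty(len(y), dtype=int)
    for c in pd.unique(y):
        idx = rng.permutation(np.where(y == c)[0])
        start = int(rng.integers(n_groups))
        groups[idx] = (start + np.arange(len(idx))) % n_groups
    return groups


def rdcv(
    X,
    y,
    outer: int = 10,
    inner: int = 10,
    repeats: int = 50,
    max_A: int = 5,
    seed: int = 0,
    vip_threshold: float = 1.0,
    autoscale_folds: bool = True,
) -> RDCVResult:
    """Repeated double cross-validation of PLS-DA.

    Per repetition: samples are split at random (class-stratified) into
    ``outer`` cancellation groups; for each held-out group the inner loop
    picks the latent-variable count on the remaining samples only, the model
    is fit on those samples (with fold-local autoscaling when
    ``autoscale_folds``) and the group is predicted.  Metrics are reported
    as mean +- SD over repetitions; VIP exceedance frequencies are pooled
    over all outer models.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    if repeats < 1:
        raise PLSDAError("repeats must be >= 1")
    if n < outer:
        raise PLSDAError(f"need at least outer={outer} samples, got {n}")
    classes = sorted(set(y))
    counts = pd.Series(y).value_counts()
    if (counts < outer).any():
        warnings.warn(
            "some classes have fewer samples than outer groups; folds will be uneven",
            stacklevel=2,
        )

    acc, sens, spec = [], [], []
    mis = np.zeros((len(classes), len(classes)))
    vip_hits = np.zeros(p)
    n_models = 0
    chosen: Counter[int] = Counter()
    cls_idx = {c: i for i, c in enumerate(classes)}

    for rep in range(repeats):
        rng = rng_for(seed, f"rdcv-rep{rep}")
        groups = _stratified_groups(y, outer, rng)
        confusion = np.zeros((len(classes), len(classes)))
        for g in range(outer):
            test = groups == g
            if not test.any():
                continue
            Xtr, ytr = X[~test], y[~test]
            if set(ytr) != set(classes):
                raise PLSDAError("outer training split lacks a class; reduce outer groups")
            Xte = X[test]
            if autoscale_folds:
                mu = Xtr.mean(axis=0)
                sd = Xtr.std(axis=0, ddof=1)
                sd[sd <= 0] = 1.0
                Xtr = (Xtr - mu) / sd
                Xte = (Xte - mu) / sd
            cap = min(max_A, len(ytr) - 1 - int(np.ceil(len(ytr) / inner)), p)
            A = select_nlv(Xtr, ytr, max_A=max(cap, 1), folds=inner, seed=seed + 7919 * rep + g)
            chosen[A] += 1
            model = fit_plsda(Xtr, ytr, A, class_order=classes)
            pred = predict_classes(model, Xte)
            for t_lab, p_lab in zip(y[test], pred):
                confusion[cls_idx[t_lab], cls_idx[p_lab]] += 1
            vip_hits += vip_scores(model) > vip_threshold
            n_models += 1
        s, sp, a = classification_metrics(confusion)
        acc.append(a)
        sens.append(s)
        spec.append(sp)
        row_sum = confusion.sum(axis=1, keepdims=True)
        mis += np.divide(confusion, row_sum, out=np.zeros_like(confusion), where=row_sum > 0)

    acc = np.asarray(acc)
    sens = np.asarray(sens)
    spec = np.asarray(spec)
    mis = mis / repeats * 100.0
    ddof = 1 if repeats > 1 else 0
    return RDCVResult(
        accuracy_mean=float(acc.mean()),
        accuracy_sd=float(acc.std(ddof=ddof)),
        class_order=classes,
        sensitivity_mean={c: float(v) for c, v in zip(classes, np.nanmean(sens, axis=0))},
        sensitivity_sd={c: float(v) for c, v in zip(classes, np.nanstd(sens, axis=0, ddof=ddof))},
        specificity_mean={c: float(v) for c, v in zip(classes, spec.mean(axis=0))},
        specificity_sd={c: float(v) for c, v in zip(classes, spec.std(axis=0, ddof=ddof))},
        misclassification_matrix=pd.DataFrame(mis, index=classes, columns=classes),
        vip_frequency=vip_hits / max(n_models, 1),
        chosen_A_distribution=dict(sorted(chosen.items())),
        repeats=repeats,
        seed=seed,
        per_repetition_accuracy=acc,
    )


@dataclass
class PermutationResult:
    n_permutations: int
    null_metrics: np.ndarray
    observed_metric: float
    p_value: float


def permutation_test(
    X,
    y,
    n_permutations: int = 1000,
    seed: int = 0,
    metric: str = "accuracy",
    outer: int = 10,
    inner: int = 10,
    max_A: int = 5,
) -> PermutationResult:
    """Label-permutation null for the cross-validated accuracy.

    The observed metric is a single-repetition rDCV accuracy; each
    permutation reruns the identical procedure on shuffled labels.  The
    empirical p-value uses the +1 correction, p = (#{null >= obs} + 1)/(B + 1),
    so it is never zero.
    """
    if n_permutations < 1:
        raise PLSDAError("n_permutations must be >= 1")
    if metric != "accuracy":
        raise PLSDAError(f"unknown metric {metric!r}")
    y = np.asarray(y)
    observed = rdcv(X, y, outer=outer, inner=inner, repeats=1, max_A=max_A, seed=seed).accuracy_mean
    rng = rng_for(seed, "permutation")
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        y_perm = rng.permutation(y)
        null[b] = rdcv(
            X, y_perm, outer=outer, inner=inner, repeats=1, max_A=max_A, seed=seed + b + 1
        ).accuracy_mean
    p = (np.sum(null >= observed) + 1) / (n_permutations + 1)
    return PermutationResult(
        n_permutations=n_permutations,
        null_metrics=null,
        observed_metric=float(observed),
        p_value=float(p),
    )
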