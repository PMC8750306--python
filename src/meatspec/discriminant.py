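"""Four-class speciation: PCA exploration, PLS-DA, kernel SVM and validation.

PLS-DA regresses a one-indicator-column-per-species response on the spectra
(PLS2, NIPALS as implemented in scikit-learn) and assigns each scan to the
class with the largest predicted indicator value.  The latent-variable count
is chosen by group-aware Venetian-blinds cross-validation (ties favour fewer
components).  Variable importance in projection (VIP) scores support the
"greater than one" selection rule, and Q-residual / Hotelling T² statistics
flag training outliers.  The SVM route tunes kernel (RBF, quadratic, cubic),
cost and width on cross-validated accuracy.

All cross-validation operates on samples, never on scans, so replicate
spectra of one sample are always on the same side of every fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError, DimensionError, FitError, ValidationError
from .splitting import CVFolds, cv_folds

# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Mean-centred SVD decomposition of a training matrix."""

    mean: np.ndarray
    loadings: np.ndarray  # A × p, orthonormal
    scores: np.ndarray  # n × A (training scores)
    explained_variance_fraction: np.ndarray
    score_var: np.ndarray  # per-component score variance (ddof=1)
    residual_eigvals: np.ndarray  # eigenvalues beyond the retained components
    n_train: int

    @property
    def n_components(self) -> int:
        return int(self.loadings.shape[0])

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.mean) @ self.loadings.T

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.loadings + self.mean


def fit_pca(X_train: np.ndarray, n_components: int) -> PCAModel:
    """Principal component analysis by SVD of the mean-centred matrix."""
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise FitError("pca needs at least 2 rows")
    mean = X.mean(axis=0)
    _, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        raise FitError(f"n_components={n_components} exceeds rank {rank}")
    eig = s**2 / (n - 1)
    total = eig.sum()
    scores = (X - mean) @ Vt[:n_components].T
    return PCAModel(
        mean=mean,
        loadings=Vt[:n_components],
        scores=scores,
        explained_variance_fraction=eig[:n_components] / total,
        score_var=eig[:n_components],
        residual_eigvals=eig[n_components:],
        n_train=n,
    )


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


def indicator_matrix(labels: Sequence[str], classes: Sequence[str]) -> np.ndarray:
    classes = list(classes)
    idx = {c: j for j, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        if lab not in idx:
            raise ValidationError(f"label {lab!r} not among classes {classes}")
        Y[i, idx[lab]] = 1.0
    return Y


@dataclass
class PLSDAModel:
    """PLS2 decomposition with class encoding and the CV error curve."""

    classes: tuple[str, ...]
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_weights: np.ndarray  # p × A   (W)
    x_loadings: np.ndarray  # p × A  (P)
    y_loadings: np.ndarray  # c × A  (q)
    x_scores: np.ndarray  # n × A   (T, training scores)
    coef: np.ndarray  # p × c, at the selected LV count
    n_lv: int
    cv_error_curve: np.ndarray  # misclassification rate per LV count (index 0 → 1 LV)
    residual_eigvals: np.ndarray
    score_var: np.ndarray
    n_train: int

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.x_mean) @ self.coef + self.y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class with the largest predicted indicator (ties → first
        alphabetically; classes are stored sorted)."""
        Yhat = self.decision_values(X)
        return np.asarray([self.classes[j] for j in np.argmax(Yhat, axis=1)], dtype=object)

    def predict_shares(self, X: np.ndarray) -> np.ndarray:
        """Non-negative, row-normalised indicator predictions (probability-like
        shares used for the leave-class-out cutoff)."""
        Yhat = np.clip(self.decision_values(X), 0.0, None)
        total = Yhat.sum(axis=1, keepdims=True)
        flat = total[:, 0] == 0
        Yhat[flat] = 1.0 / len(self.classes)
        total[flat] = 1.0
        return Yhat / total


def _coef_for_lv(W: np.ndarray, P: np.ndarray, Q: np.ndarray, a: int) -> np.ndarray:
    """Regression coefficients using the first ``a`` latent variables."""
    Wa, Pa, Qa = W[:, :a], P[:, :a], Q[:, :a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T)


def _fit_pls_core(Xc: np.ndarray, Yc: np.ndarray, n_components: int) -> PLSRegression:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns when Y residual vanishes
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(Xc, Yc)
    return pls


def _group_folds_to_rows(
    groups: Sequence[str], folds: CVFolds
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Translate folds over group units into folds over row indices."""
    unique = list(dict.fromkeys(groups))
    rows_of = {g: [] for g in unique}
    for i, g in enumerate(groups):
        rows_of[g].append(i)
    out = []
    for tr_units, val_units in folds.folds:
        tr = np.concatenate([rows_of[unique[u]] for u in tr_units])
        val = np.concatenate([rows_of[unique[u]] for u in val_units])
        out.append((np.sort(tr), np.sort(val)))
    return out


def fit_plsda(
    X_train: np.ndarray,
    labels: Sequence[str],
    max_lv: int = 10,
    groups: Sequence[str] | None = None,
    cv_scheme: str = "venetian_blinds",
    cv_params: Mapping | None = None,
    seed: int = 0,
) -> PLSDAModel:
    """Fit a PLS-DA model, selecting the LV count by group-aware CV.

    ``groups`` carries one sample id per row (defaults to one group per row);
    folds are built over groups so replicates never validate a model trained
    on their siblings.  The misclassification error per LV count is computed
    once per fold from a single maximal-rank fit (coefficients for any smaller
    LV count follow algebraically), and the final model is refit on all rows
    at the selected count (ties toward fewer LVs).
    """
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    labels = list(labels)
    if X.shape[0] != len(labels):
        raise DimensionError("labels length must match row count")
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValidationError("plsda needs at least 2 classes")
    if max_lv >= X.shape[0]:
        raise ConfigError(f"max_lv={max_lv} must be < n_train={X.shape[0]}")
    max_lv = min(max_lv, np.linalg.matrix_rank(X - X.mean(axis=0)))
    Y = indicator_matrix(labels, classes)
    groups = list(groups) if groups is not None else [str(i) for i in range(len(labels))]

    unique_groups = list(dict.fromkeys(groups))
    folds = cv_folds(cv_scheme, len(unique_groups), cv_params, seed=seed)
    row_folds = _group_folds_to_rows(groups, folds)

    errors = np.zeros(max_lv)
    counts = np.zeros(max_lv)
    labels_arr = np.asarray(labels, dtype=object)
    for tr, val in row_folds:
        x_mean, y_mean = X[tr].mean(axis=0), Y[tr].mean(axis=0)
        Xc, Yc = X[tr] - x_mean, Y[tr] - y_mean
        lv_fold = min(max_lv, np.linalg.matrix_rank(Xc))
        pls = _fit_pls_core(Xc, Yc, lv_fold)
        W, P, Q = pls.x_weights_, pls.x_loadings_, pls.y_loadings_
        for a in range(1, max_lv + 1):
            B = _coef_for_lv(W, P, Q, min(a, lv_fold))
            pred = np.argmax((X[val] - x_mean) @ B + y_mean, axis=1)
            pred_labels = np.asarray([classes[j] for j in pred], dtype=object)
            errors[a - 1] += np.sum(pred_labels != labels_arr[val])
            counts[a - 1] += len(val)
    cv_curve = errors / counts
    n_lv = int(np.argmin(cv_curve)) + 1  # argmin takes the first (fewest LVs) on ties

    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - x_mean, Y - y_mean
    pls = _fit_pls_core(Xc, Yc, max_lv)
    W, P, Q = pls.x_weights_, pls.x_loadings_, pls.y_loadings_
    T = pls.x_scores_
    coef = _coef_for_lv(W, P, Q, n_lv)

    resid = Xc - T[:, :n_lv] @ P[:, :n_lv].T
    eig = np.linalg.svd(resid, compute_uv=False) ** 2 / (X.shape[0] - 1)
    score_var = T[:, :n_lv].var(axis=0, ddof=1)
    return PLSDAModel(
        classes=classes,
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=W,
        x_loadings=P,
        y_loadings=Q,
        x_scores=T,
        coef=coef,
        n_lv=n_lv,
        cv_error_curve=cv_curve,
        residual_eigvals=eig,
        score_var=score_var,
        n_train=X.shape[0],
    )


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection over the selected LV count.

    ``VIP_j = sqrt(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)`` with ``SSY_a``
    the Y-variance explained by component ``a``.  The squares average to 1,
    so the ">1" rule marks above-average contributors.
    """
    A = model.n_lv
    W = model.x_weights[:, :A]
    T = model.x_scores[:, :A]
    Q = model.y_loadings[:, :A]
    p = W.shape[0]
    ssy = np.einsum("ia,ia->a", T, T) * np.einsum("ca,ca->a", Q, Q)
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(p * (wn**2 @ ssy) / ssy.sum())


# ---------------------------------------------------------------------------
# outlier detection
# ---------------------------------------------------------------------------


@dataclass
class OutlierFlags:
    q: np.ndarray
    t2: np.ndarray
    q_limit: float
    t2_limit: float
    rule: str
    flags: np.ndarray


def _jackson_mudholkar_limit(residual_eigvals: np.ndarray, alpha: float) -> float:
    lam = np.asarray(residual_eigvals, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        return 0.0
    th1, th2, th3 = (float(np.sum(lam**i)) for i in (1, 2, 3))
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    if h0 <= 0:
        h0 = 1e-6
    c = stats.norm.ppf(1.0 - alpha)
    inner = (
        c * np.sqrt(2.0 * th2 * h0**2) / th1 + 1.0 + th2 * h0 * (h0 - 1.0) / th1**2
    )
    if inner <= 0:
        return 0.0
    return float(th1 * inner ** (1.0 / h0))


def outlier_flags(
    model: PCAModel | PLSDAModel,
    X: np.ndarray,
    alpha: float = 0.05,
    rule: str = "both",
) -> OutlierFlags:
    """Q-residual / Hotelling-T² outlier flags against a latent-variable model.

    The T² limit uses the F-distribution scaling ``A(n−1)/(n−A)·F₁₋α(A, n−A)``
    and the Q limit the Jackson–Mudholkar approximation from the residual
    eigenvalues.  ``rule='both'`` (default, conservative) flags rows exceeding
    both limits; ``rule='either'`` flags rows exceeding at least one.
    """
    if rule not in ("both", "either"):
        raise ConfigError(f"rule must be 'both' or 'either', got {rule!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if isinstance(model, PCAModel):
        A, n = model.n_components, model.n_train
        mean, load, svar = model.mean, model.loadings, model.score_var
        resid_eig = model.residual_eigvals
    else:
        A, n = model.n_lv, model.n_train
        mean = model.x_mean
        load = model.x_loadings[:, :A].T
        svar = model.score_var
        resid_eig = model.residual_eigvals
    if A < 1:
        raise ConfigError("outlier detection needs at least 1 component")
    Xc = X - mean
    if isinstance(model, PCAModel):
        T = Xc @ load.T
    else:
        Wa, Pa = model.x_weights[:, :A], model.x_loadings[:, :A]
        T = Xc @ Wa @ np.linalg.inv(Pa.T @ Wa)
    resid = Xc - T @ load
    q = np.einsum("ij,ij->i", resid, resid)
    t2 = np.einsum("ij,ij->i", T / svar, T)
    if n <= A:
        raise FitError("T² limit needs more training rows than components")
    t2_limit = float(A * (n - 1) / (n - A) * stats.f.ppf(1.0 - alpha, A, n - A))
    q_limit = _jackson_mudholkar_limit(resid_eig, alpha)
    over_q, over_t2 = q > q_limit, t2 > t2_limit
    flags = (over_q & over_t2) if rule == "both" else (over_q | over_t2)
    return OutlierFlags(q, t2, q_limit, t2_limit, rule, flags)


# ---------------------------------------------------------------------------
# SVM tuning
# ---------------------------------------------------------------------------

_KERNEL_ORDER = ("quadratic", "cubic", "rbf")


@dataclass(frozen=True)
class SVMSpec:
    kernel: str
    C: float
    gamma: float | str = "scale"

    def make_estimator(self, seed: int = 0) -> Pipeline:
        if self.kernel == "rbf":
            svc = SVC(kernel="rbf", C=self.C, gamma=self.gamma, random_state=seed)
        elif self.kernel in ("quadratic", "cubic"):
            svc = SVC(kernel="poly", degree=2 if self.kernel == "quadratic" else 3,
                      coef0=1.0, gamma="scale", C=self.C, random_state=seed)
        else:
            raise ConfigError(f"unknown kernel {self.kernel!r}")
        return Pipeline([("scale", StandardScaler()), ("svc", svc)])


def tune_svm(
    X_train: np.ndarray,
    labels: Sequence[str],
    kernels: Sequence[str] = _KERNEL_ORDER,
    groups: Sequence[str] | None = None,
    cv_scheme: str = "venetian_blinds",
    cv_params: Mapping | None = None,
    Cs: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
    gammas: Sequence[float] | None = None,
    seed: int = 0,
) -> tuple[SVMSpec, float]:
    """Grid-search kernel/C(/γ) by group-aware CV accuracy.

    Ties prefer the simpler kernel (quadratic < cubic < RBF), then smaller C,
    then smaller γ.  Features are standardised inside each fold.
    """
    X = np.atleast_2d(np.asarray(X_train, dtype=float))
    labels_arr = np.asarray(list(labels), dtype=object)
    if len(set(labels_arr)) < 2:
        raise ValidationError("svm tuning needs at least 2 classes")
    groups = list(groups) if groups is not None else [str(i) for i in range(len(labels_arr))]
    unique_groups = list(dict.fromkeys(groups))
    folds = cv_folds(cv_scheme, len(unique_groups), cv_params, seed=seed)
    row_folds = _group_folds_to_rows(groups, folds)
    if gammas is None:
        gammas = np.logspace(-3, 1, 5)

    candidates: list[SVMSpec] = []
    for kernel in kernels:
        if kernel == "rbf":
            candidates.extend(SVMSpec("rbf", C, float(g)) for C in Cs for g in gammas)
        else:
            candidates.extend(SVMSpec(kernel, C) for C in Cs)

    def sort_key(item: tuple[SVMSpec, float]):
        spec, acc = item
        g = spec.gamma if isinstance(spec.gamma, float) else 0.0
        return (-acc, _KERNEL_ORDER.index(spec.kernel), spec.C, g)

    results = []
    for spec in candidates:
        correct = total = 0
        for tr, val in row_folds:
            est = spec.make_estimator(seed=seed)
            est.fit(X[tr], labels_arr[tr])
            correct += int(np.sum(est.predict(X[val]) == labels_arr[val]))
            total += len(val)
        results.append((spec, correct / total))
    best, best_acc = sorted(results, key=sort_key)[0]
    return best, float(best_acc)


# ---------------------------------------------------------------------------
# confusion matrices and metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """Class-labelled count table (rows = truth, columns = prediction)."""

    classes: tuple[str, ...]
    table: np.ndarray

    @classmethod
    def from_labels(
        cls,
        y_true: Sequence[str],
        y_pred: Sequence[str],
        classes: Sequence[str] | None = None,
    ) -> "ConfusionMatrix":
        y_true = list(y_true)
        y_pred = list(y_pred)
        if len(y_true) != len(y_pred):
            raise DimensionError("y_true and y_pred lengths differ")
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        idx = {c: i for i, c in enumerate(classes)}
        table = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            table[idx[t], idx[p]] += 1
        return cls(tuple(classes), table)

    def per_class_counts(self) -> dict[str, dict[str, int]]:
        """One-vs-rest TP/TN/FP/FN per class."""
        total = int(self.table.sum())
        out = {}
        for i, c in enumerate(self.classes):
            tp = int(self.table[i, i])
            fn = int(self.table[i].sum() - tp)
            fp = int(self.table[:, i].sum() - tp)
            tn = total - tp - fn - fp
            out[c] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.table, index=list(self.classes), columns=list(self.classes))


def metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class sensitivity, specificity, accuracy and error rate.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/total, error = 1 − accuracy.  Degenerate denominators
    yield NaN with a warning.
    """
    rows = {}
    for c, k in cm.per_class_counts().items():
        tp, tn, fp, fn = k["TP"], k["TN"], k["FP"], k["FN"]
        total = tp + tn + fp + fn
        if tp + fn == 0:
            warnings.warn(f"class {c!r}: no positive truths; sensitivity undefined")
            sens = np.nan
        else:
            sens = tp / (tp + fn)
        if tn + fp == 0:
            warnings.warn(f"class {c!r}: no negative truths; specificity undefined")
            spec = np.nan
        else:
            spec = tn / (tn + fp)
        acc = (tp + tn) / total if total else np.nan
        rows[c] = {
            "sensitivity": sens,
            "specificity": spec,
            "accuracy": acc,
            "error": 1.0 - acc if total else np.nan,
        }
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# leave-class-out validation
# ---------------------------------------------------------------------------


class _SoftmaxSVM:
    """SVM wrapper exposing probability-like shares via a softmax over the
    one-vs-rest aggregated decision values (deterministic approximation to
    pairwise-coupling calibration)."""

    def __init__(self, spec: SVMSpec, seed: int = 0):
        self._est = spec.make_estimator(seed=seed)

    def fit(self, X, y):
        self._est.fit(X, y)
        self.classes_ = self._est.named_steps["svc"].classes_
        return self

    def predict(self, X):
        return self._est.predict(X)

    def predict_proba(self, X):
        f = np.atleast_2d(self._est.decision_function(X))
        if f.shape[1] != len(self.classes_):  # binary: expand the single margin
            f = np.column_stack([-f.ravel(), f.ravel()])
        e = np.exp(f - f.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)


def leave_class_out(
    X: np.ndarray,
    labels: Sequence[str],
    groups: Sequence[str] | None = None,
    svm_spec: SVMSpec | None = None,
    cutoff: float = 0.5,
    cv_scheme: str = "venetian_blinds",
    cv_params: Mapping | None = None,
    seed: int = 0,
    model_factory: Callable | None = None,
) -> pd.DataFrame:
    """Hold out each class entirely; observe where its spectra are allocated.

    For every class, a 3-class model (default: SVM) is trained and
    cross-validated on the remaining classes, then the held-out spectra are
    predicted.  A prediction is accepted only when its class probability
    share exceeds ``cutoff``, otherwise the spectrum is counted as
    unassigned.  For the SVM, shares are a softmax over the one-vs-rest
    aggregated decision values — an approximation to full pairwise-coupling
    calibration, but deterministic.  Returns one row per held-out class: CV
    accuracy of the 3-class model, spectrum count, and counts plus
    percentages per destination class.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels_arr = np.asarray(list(labels), dtype=object)
    groups = list(groups) if groups is not None else [str(i) for i in range(len(labels_arr))]
    groups_arr = np.asarray(groups, dtype=object)
    classes = sorted(set(labels_arr))
    spec = svm_spec or SVMSpec("rbf", C=10.0, gamma="scale")

    records = []
    for held in classes:
        out_rows = np.flatnonzero(labels_arr == held)
        in_rows = np.flatnonzero(labels_arr != held)
        Xin, yin, gin = X[in_rows], labels_arr[in_rows], groups_arr[in_rows]
        if model_factory is not None:
            fit = model_factory
        else:
            def fit(Xa, ya, _spec=spec):
                est = _SoftmaxSVM(_spec, seed)
                est.fit(Xa, ya)
                return est
        # group-aware CV accuracy of the 3-class model
        unique_groups = list(dict.fromkeys(gin))
        folds = cv_folds(cv_scheme, len(unique_groups), cv_params, seed=seed)
        row_folds = _group_folds_to_rows(list(gin), folds)
        correct = total = 0
        for tr, val in row_folds:
            est = fit(Xin[tr], yin[tr])
            correct += int(np.sum(np.asarray(est.predict(Xin[val])) == yin[val]))
            total += len(val)
        est = fit(Xin, yin)
        proba = np.asarray(est.predict_proba(X[out_rows]))
        est_classes = list(est.classes_)
        best = np.argmax(proba, axis=1)
        accepted = proba[np.arange(len(best)), best] > cutoff
        record = {
            "left_out": held,
            "cv_accuracy_pct": 100.0 * correct / total,
            "n_spectra": int(len(out_rows)),
        }
        for c in classes:
            if c == held:
                record[f"to_{c}"] = 0
                continue
            j = est_classes.index(c)
            record[f"to_{c}"] = int(np.sum(accepted & (best == j)))
        record["unassigned"] = int(np.sum(~accepted))
        for c in classes:
            if c != held:
                record[f"pct_{c}"] = 100.0 * record[f"to_{c}"] / len(out_rows)
        records.append(record)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# end-to-end evaluation on a train/test split
# ---------------------------------------------------------------------------


@dataclass
class EvaluationBlock:
    confusion: ConfusionMatrix
    metrics: pd.DataFrame


def evaluate_on_split(
    X: np.ndarray,
    labels: Sequence[str],
    groups: Sequence[str],
    train_rows: np.ndarray,
    test_rows: np.ndarray,
    method: str = "plsda",
    max_lv: int = 10,
    svm_spec: SVMSpec | None = None,
    cv_scheme: str = "venetian_blinds",
    cv_params: Mapping | None = None,
    seed: int = 0,
) -> dict[str, EvaluationBlock]:
    """Train / cross-validation / test metric blocks for one split.

    ``X`` must already be pre-processed leak-free (chain fitted on the
    training rows).  The CV block gathers group-aware out-of-fold predictions
    on the training partition at the selected model complexity; the test block
    never touches training rows.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels_arr = np.asarray(list(labels), dtype=object)
    groups_arr = np.asarray(list(groups), dtype=object)
    tr, te = np.asarray(train_rows, dtype=int), np.asarray(test_rows, dtype=int)
    classes = sorted(set(labels_arr))
    gtr = list(groups_arr[tr])

    if method == "plsda":
        model = fit_plsda(
            X[tr], list(labels_arr[tr]), max_lv=max_lv, groups=gtr,
            cv_scheme=cv_scheme, cv_params=cv_params, seed=seed,
        )
        predict = model.predict
        def fold_fit_predict(tr_idx, val_idx):
            sub = fit_plsda(
                X[tr][tr_idx], list(labels_arr[tr][tr_idx]), max_lv=model.n_lv,
                groups=[gtr[i] for i in tr_idx], cv_scheme=cv_scheme,
                cv_params=cv_params, seed=seed,
            )
            return sub.predict(X[tr][val_idx])
    elif method == "svm":
        spec = svm_spec
        if spec is None:
            spec, _ = tune_svm(
                X[tr], list(labels_arr[tr]), groups=gtr,
                cv_scheme=cv_scheme, cv_params=cv_params, seed=seed,
            )
        est = spec.make_estimator(seed=seed)
        est.fit(X[tr], labels_arr[tr])
        predict = est.predict
        def fold_fit_predict(tr_idx, val_idx, _spec=spec):
            sub = _spec.make_estimator(seed=seed)
            sub.fit(X[tr][tr_idx], labels_arr[tr][tr_idx])
            return sub.predict(X[tr][val_idx])
    else:
        raise ConfigError(f"unknown method {method!r}")

    unique_groups = list(dict.fromkeys(gtr))
    folds = cv_folds(cv_scheme, len(unique_groups), cv_params, seed=seed)
    row_folds = _group_folds_to_rows(gtr, folds)
    cv_true: list[str] = []
    cv_pred: list[str] = []
    for tr_idx, val_idx in row_folds:
        cv_pred.extend(np.asarray(fold_fit_predict(tr_idx, val_idx)))
        cv_true.extend(labels_arr[tr][val_idx])

    blocks = {}
    for name, (yt, yp) in {
        "train": (labels_arr[tr], np.asarray(predict(X[tr]))),
        "cv": (np.asarray(cv_true, dtype=object), np.asarray(cv_pred, dtype=object)),
        "test": (labels_arr[te], np.asarray(predict(X[te]))),
    }.items():
        cm = ConfusionMatrix.from_labels(list(yt), list(yp), classes)
        blocks[name] = EvaluationBlock(cm, metrics(cm))
    return blocks
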