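"""One-class screening for "not pork meat" flagging.

The screening approach models a single *target* class (pork, the non-halal
species) and asks of every sample whether its spectra are compatible with
that class.  Five one-class algorithms are available, all exposing a
*class distance* that is ≥ 0 and smaller for more target-like spectra:

``simca``
    PCA of the target class; distance is the geometric mean of the
    training-mean-normalised orthogonal residual (Q) and score distance (T²):
    ``sqrt((Q/Q̄)(T²/T̄²))``.
``knn_dist``
    mean Euclidean distance to the k nearest target training points in
    PCA-score space (default 2 components, k = 1).
``pca_residual``
    the Q statistic (squared orthogonal residual) alone, default 3 PCs.
``mahalanobis``
    Mahalanobis distance to the target mean in PCA-score space.
``ocsvm``
    one-class SVM with RBF kernel; decision values are reversed and shifted
    (``max(0, m − f(x))`` with ``m`` the training maximum) so that smaller
    still means more in-class.

Screening evaluates every (pre-processing chain × algorithm) combination by
repeated random resampling of the target class (default 80 repeats of a
70/30 sample-level split), scoring each with the AUROC of held-out pork
against each other species and against all of them pooled.  Three
complementary combinations are then selected, per-model class limits are
calibrated under two scenarios, and samples are flagged ``not_pork_meat``
when at least 2 of the 3 models place their median replicate distance
outside the limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.svm import OneClassSVM

from .dataset import SPECIES, SpectralDataset, group_by_sample
from .errors import ConfigError, FitError, MeatspecError, ValidationError
from .preprocess import FittedChain, PreprocessSpec, fit_chain
from .splitting import repeated_random_cv, rows_for_groups

# ---------------------------------------------------------------------------
# PCA basis shared by the latent-space algorithms
# ---------------------------------------------------------------------------


@dataclass
class _PCABasis:
    mean: np.ndarray
    components: np.ndarray  # A × p, orthonormal rows
    score_var: np.ndarray  # per-component score variance (ddof=1)

    def scores(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) @ self.components.T

    def q_statistic(self, X: np.ndarray) -> np.ndarray:
        Xc = X - self.mean
        resid = Xc - self.scores(X) @ self.components
        return np.einsum("ij,ij->i", resid, resid)

    def t2_statistic(self, X: np.ndarray) -> np.ndarray:
        T = self.scores(X)
        return np.einsum("ij,ij->i", T / self.score_var, T)


def _fit_pca_basis(X: np.ndarray, n_components: int) -> _PCABasis:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < n_components + 1:
        raise FitError(
            f"need at least n_components+1={n_components + 1} target rows, got {n}"
        )
    mean = X.mean(axis=0)
    _, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        raise FitError(f"n_components={n_components} exceeds rank {rank}")
    var = (s[:n_components] ** 2) / (n - 1)
    return _PCABasis(mean, Vt[:n_components], var)


# ---------------------------------------------------------------------------
# algorithms
# ---------------------------------------------------------------------------


class _BaseOCC:
    def fit(self, X: np.ndarray) -> "_BaseOCC":
        raise NotImplementedError

    def distance(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class SimcaOCC(_BaseOCC):
    """SIMCA-style combined distance sqrt((Q/Q̄)·(T²/T̄²)), default 3 PCs."""

    def __init__(self, n_components: int = 3):
        self.n_components = int(n_components)
        self.basis_: _PCABasis | None = None
        self.q_mean_: float = np.nan
        self.t2_mean_: float = np.nan

    def fit(self, X):
        self.basis_ = _fit_pca_basis(X, self.n_components)
        q = self.basis_.q_statistic(X)
        t2 = self.basis_.t2_statistic(X)
        self.q_mean_ = float(q.mean())
        self.t2_mean_ = float(t2.mean())
        if self.q_mean_ <= 0:
            # target data lie exactly in the PC span; fall back to unit scale
            self.q_mean_ = 1.0
        return self

    def distance(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        q = self.basis_.q_statistic(X) / self.q_mean_
        t2 = self.basis_.t2_statistic(X) / self.t2_mean_
        return np.sqrt(q * t2)


class PcaResidualOCC(_BaseOCC):
    """Orthogonal residual (Q statistic) to the target PCA subspace."""

    def __init__(self, n_components: int = 3):
        self.n_components = int(n_components)
        self.basis_: _PCABasis | None = None

    def fit(self, X):
        self.basis_ = _fit_pca_basis(X, self.n_components)
        return self

    def distance(self, X):
        return self.basis_.q_statistic(np.atleast_2d(np.asarray(X, dtype=float)))


class KnnDistOCC(_BaseOCC):
    """Mean distance to the k nearest target training points in score space."""

    def __init__(self, n_components: int = 2, k: int = 1):
        self.n_components = int(n_components)
        self.k = int(k)
        self.basis_: _PCABasis | None = None
        self.train_scores_: np.ndarray | None = None

    def fit(self, X):
        if self.k < 1:
            raise ConfigError("knn_dist requires k >= 1")
        self.basis_ = _fit_pca_basis(X, self.n_components)
        self.train_scores_ = self.basis_.scores(np.atleast_2d(np.asarray(X, dtype=float)))
        if self.k > self.train_scores_.shape[0]:
            raise FitError(f"k={self.k} exceeds number of target rows")
        return self

    def distance(self, X):
        S = self.basis_.scores(np.atleast_2d(np.asarray(X, dtype=float)))
        D = cdist(S, self.train_scores_)
        D.sort(axis=1)
        return D[:, : self.k].mean(axis=1)


class MahalanobisOCC(_BaseOCC):
    """Mahalanobis distance to the target mean in PCA-score space."""

    def __init__(self, n_components: int = 3):
        self.n_components = int(n_components)
        self.basis_: _PCABasis | None = None
        self.cov_inv_: np.ndarray | None = None

    def fit(self, X):
        self.basis_ = _fit_pca_basis(X, self.n_components)
        S = self.basis_.scores(np.atleast_2d(np.asarray(X, dtype=float)))
        cov = np.atleast_2d(np.cov(S, rowvar=False, ddof=1))
        self.cov_inv_ = np.linalg.pinv(cov)
        return self

    def distance(self, X):
        S = self.basis_.scores(np.atleast_2d(np.asarray(X, dtype=float)))
        # scores are centred on the training mean by construction
        return np.sqrt(np.einsum("ij,jk,ik->i", S, self.cov_inv_, S))


class OcsvmOCC(_BaseOCC):
    """One-class SVM (RBF); distance = max(0, m − f(x)), m = train maximum.

    After fitting, the decision function is kept as explicit kernel state
    (support vectors, dual coefficients, intercept, γ) so fitted models are
    serialisable without the libsvm object.
    """

    def __init__(self, nu: float = 0.05, gamma: float | str = "scale"):
        self.nu = float(nu)
        self.gamma = gamma
        self.support_vectors_: np.ndarray | None = None
        self.dual_coef_: np.ndarray | None = None
        self.intercept_: float = np.nan
        self.gamma_value_: float = np.nan
        self.offset_: float = np.nan

    def fit(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] < 2:
            raise FitError("ocsvm needs at least 2 target rows")
        svm = OneClassSVM(kernel="rbf", nu=self.nu, gamma=self.gamma)
        svm.fit(X)
        self.support_vectors_ = svm.support_vectors_
        self.dual_coef_ = svm.dual_coef_[0]
        self.intercept_ = float(svm.intercept_[0])
        self.gamma_value_ = float(svm._gamma)
        self.offset_ = float(self._decision(X).max())
        return self

    def _decision(self, X: np.ndarray) -> np.ndarray:
        K = np.exp(-self.gamma_value_ * cdist(X, self.support_vectors_) ** 2)
        return K @ self.dual_coef_ + self.intercept_

    def distance(self, X):
        f = self._decision(np.atleast_2d(np.asarray(X, dtype=float)))
        return np.maximum(0.0, self.offset_ - f)


_ALGORITHMS: dict[str, type[_BaseOCC]] = {
    "simca": SimcaOCC,
    "knn_dist": KnnDistOCC,
    "pca_residual": PcaResidualOCC,
    "mahalanobis": MahalanobisOCC,
    "ocsvm": OcsvmOCC,
}


@dataclass
class OCCModel:
    """A fitted one-class model bound to its pre-processing chain."""

    algorithm: str
    spec: PreprocessSpec
    params: dict[str, Any]
    estimator: _BaseOCC
    chain: FittedChain | None = None
    class_limits: dict[int, float] = field(default_factory=dict)

    @property
    def combo_id(self) -> str:
        return f"{self.spec.canonical()}+{self.algorithm}"


def fit_occ(
    algorithm: str, X_target_train: np.ndarray, params: Mapping[str, Any] | None = None
) -> OCCModel:
    """Fit one algorithm on (already pre-processed) target-class rows."""
    if algorithm not in _ALGORITHMS:
        raise ConfigError(
            f"unknown OCC algorithm {algorithm!r}; known: {sorted(_ALGORITHMS)}"
        )
    params = dict(params or {})
    est = _ALGORITHMS[algorithm](**params)
    est.fit(X_target_train)
    return OCCModel(algorithm, PreprocessSpec([]), params, est)


def class_distance(model: OCCModel, X: np.ndarray) -> np.ndarray:
    """Class distance of rows pre-processed identically to training."""
    return model.estimator.distance(X)


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------


def auroc(target_distances: np.ndarray, other_distances: np.ndarray) -> float:
    """Probability that a target distance is smaller than a non-target one.

    Mann–Whitney formulation over all (target, other) pairs, ties counting ½;
    1.0 means perfect separation, 0.5 chance.  Rank-based, hence invariant
    under strictly monotone transforms of the distances.
    """
    t = np.asarray(target_distances, dtype=float).ravel()
    o = np.asarray(other_distances, dtype=float).ravel()
    if t.size == 0 or o.size == 0:
        raise ValidationError("auroc requires nonempty distance vectors")
    ranks = rankdata(np.concatenate([t, o]))
    r_other = ranks[t.size :].sum()
    u_other = r_other - o.size * (o.size + 1) / 2.0
    return float(u_other / (t.size * o.size))


# ---------------------------------------------------------------------------
# grid screening
# ---------------------------------------------------------------------------


@dataclass
class ScreeningRecord:
    """Mean AUROCs of one (chain × algorithm) combination over the CV repeats."""

    combo_id: str
    spec: PreprocessSpec
    algorithm: str
    params: dict[str, Any]
    auroc_vs: dict[str, float] = field(default_factory=dict)
    failed: bool = False
    error: str = ""


def default_grid() -> list[tuple[PreprocessSpec, str, dict]]:
    """A compact screening grid covering the catalogue's main families."""
    chains = [
        PreprocessSpec([("snv", {})]),
        PreprocessSpec([("snv", {}), ("detrend", {"deg": 2})]),
        PreprocessSpec([("savgol", {"w": 11, "p": 2, "d": 1})]),
        PreprocessSpec([("savgol", {"w": 11, "p": 2, "d": 2})]),
        PreprocessSpec([("snv", {}), ("dwt", {"family": "la8", "lo": 3, "hi": 5})]),
        PreprocessSpec([("savgol", {"w": 11, "p": 2, "d": 1}), ("quarter", {"q": 2})]),
    ]
    algos: list[tuple[str, dict]] = [
        ("simca", {"n_components": 3}),
        ("knn_dist", {"n_components": 2, "k": 1}),
        ("pca_residual", {"n_components": 3}),
        ("mahalanobis", {"n_components": 3}),
        ("ocsvm", {}),
    ]
    return [(spec, a, p) for spec in chains for a, p in algos]


def screen_grid(
    ds: SpectralDataset,
    grid: Sequence[tuple[PreprocessSpec, str, Mapping[str, Any]]],
    n_repeats: int = 80,
    train_fraction: float = 0.7,
    seed: int = 0,
    target: str = "pork",
) -> list[ScreeningRecord]:
    """Screen a (chain × algorithm) grid by repeated random target-class CV.

    Every combination sees the same ``n_repeats`` random 70/30 sample-level
    splits of the target class.  Per repeat the chain and the model are fitted
    on the target training rows only; distances are computed for the held-out
    target rows and for all non-target rows, and AUROCs are recorded per
    contrast (each other species, and all of them pooled).  A combination
    whose pre-processing or fit fails is marked failed rather than aborting
    the screen.
    """
    present = set(ds.species)
    if target not in present:
        raise ValidationError(f"dataset contains no {target!r} rows")
    others = [s for s in SPECIES if s in present and s != target]
    groups = group_by_sample(ds)
    target_groups = [g for g, rows in groups.items() if ds.meta[rows[0]].species == target]
    splits = repeated_random_cv(target_groups, n_repeats, train_fraction, seed)
    other_rows = {s: np.flatnonzero(ds.species == s) for s in others}
    all_other = np.flatnonzero(ds.species != target)

    records: list[ScreeningRecord] = []
    for spec, algorithm, params in grid:
        combo = f"{spec.canonical()}+{algorithm}"
        try:
            stateless_X = None
            if spec.is_stateless:
                chain, _ = fit_chain(spec, ds.X[:2])
                stateless_X = chain.transform(ds.X)
            sums = {key: 0.0 for key in (*others, "all")}
            for split in splits:
                tr_rows = rows_for_groups(ds, split.train_groups)
                ho_rows = rows_for_groups(ds, split.test_groups)
                if stateless_X is not None:
                    Xall = stateless_X
                else:
                    chain, _ = fit_chain(spec, ds.X[tr_rows])
                    Xall = chain.transform(ds.X)
                model = fit_occ(algorithm, Xall[tr_rows], params)
                d_target = class_distance(model, Xall[ho_rows])
                for s in others:
                    sums[s] += auroc(d_target, class_distance(model, Xall[other_rows[s]]))
                sums["all"] += auroc(d_target, class_distance(model, Xall[all_other]))
            records.append(
                ScreeningRecord(
                    combo,
                    spec,
                    algorithm,
                    dict(params),
                    {k: v / len(splits) for k, v in sums.items()},
                )
            )
        except MeatspecError as exc:
            records.append(
                ScreeningRecord(combo, spec, algorithm, dict(params), {}, True, str(exc))
            )
    return records


def screening_table(records: Sequence[ScreeningRecord]) -> pd.DataFrame:
    """Screening records as a table shaped like the published AUROC summaries."""
    rows = []
    for r in records:
        row = {"combo_id": r.combo_id, "algorithm": r.algorithm, "failed": r.failed}
        for key, val in r.auroc_vs.items():
            row[f"auroc_vs_{key}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def select_triplet(
    records: Sequence[ScreeningRecord],
    override: Sequence[str] | None = None,
    classes: Sequence[str] = ("lamb", "beef", "chicken"),
) -> list[str]:
    """Choose 3 combinations jointly covering the per-class AUROCs.

    Automatic rule (a stand-in for expert manual choice): first take the
    combination with the best worst-class AUROC; then twice more add the
    combination that maximises the ensemble objective
    ``min over classes of (best AUROC among selected)``.  Ties break by
    pooled AUROC, then combo id.  ``override`` returns the given ids verbatim.
    """
    ok = [r for r in records if not r.failed]
    by_id = {r.combo_id: r for r in ok}
    if override is not None:
        if len(override) != 3:
            raise ConfigError("override must name exactly 3 combinations")
        missing = [c for c in override if c not in by_id]
        if missing:
            raise ConfigError(f"override ids not in records: {missing}")
        return list(override)
    if len(ok) < 3:
        raise ConfigError(f"need at least 3 successful records, got {len(ok)}")

    def ensemble_value(selected: list[str]) -> float:
        return min(
            max(by_id[c].auroc_vs.get(cls, 0.0) for c in selected) for cls in classes
        )

    first = max(
        ok,
        key=lambda r: (
            min(r.auroc_vs.get(c, 0.0) for c in classes),
            r.auroc_vs.get("all", 0.0),
            # lexicographically smallest id wins ties → negate via sort below
        ),
    )
    # resolve id ties deterministically
    best_key = (
        min(first.auroc_vs.get(c, 0.0) for c in classes),
        first.auroc_vs.get("all", 0.0),
    )
    tied = sorted(
        r.combo_id
        for r in ok
        if (
            min(r.auroc_vs.get(c, 0.0) for c in classes),
            r.auroc_vs.get("all", 0.0),
        )
        == best_key
    )
    selected = [tied[0]]
    while len(selected) < 3:
        candidates = [r for r in ok if r.combo_id not in selected]
        scored = sorted(
            candidates,
            key=lambda r: (
                -ensemble_value(selected + [r.combo_id]),
                -r.auroc_vs.get("all", 0.0),
                r.combo_id,
            ),
        )
        selected.append(scored[0].combo_id)
    return selected


# ---------------------------------------------------------------------------
# class limits, median-replicate aggregation, ensemble vote
# ---------------------------------------------------------------------------


def set_class_limit(
    model: OCCModel,
    target_train_distances: np.ndarray,
    scenario: int,
    q: float = 0.95,
) -> float:
    """Calibrate the class limit from target training median distances.

    Scenario 1 sets the limit just above the maximum, so 100 % of target
    training samples fall in-class (absence of the target must never be
    asserted for a true target sample).  Scenario 2 sets the limit at the
    ``q``-th quantile (default 0.95), sacrificing some target samples for a
    tighter class space and better rejection of non-target species.
    """
    d = np.asarray(target_train_distances, dtype=float).ravel()
    if d.size == 0:
        raise ValidationError("cannot set a class limit from empty distances")
    if scenario == 1:
        limit = float(d.max()) * (1.0 + 1e-9)
    elif scenario == 2:
        if not 0.0 < q <= 1.0:
            raise ConfigError(f"quantile must be in (0, 1], got {q}")
        limit = float(np.quantile(d, q))
    else:
        raise ConfigError(f"scenario must be 1 or 2, got {scenario}")
    model.class_limits[int(scenario)] = limit
    return limit


def median_sample_distances(
    model: OCCModel, ds: SpectralDataset, rows: np.ndarray | None = None
) -> dict[str, float]:
    """Median replicate class distance per sample (the decision statistic)."""
    if model.chain is None:
        raise FitError("model has no fitted pre-processing chain attached")
    rows = np.arange(ds.n_scans) if rows is None else np.asarray(rows, dtype=int)
    X = model.chain.transform(ds.X[rows])
    d = class_distance(model, X)
    out: dict[str, list[float]] = {}
    for val, idx in zip(d, rows):
        out.setdefault(ds.meta[idx].sample_id, []).append(float(val))
    return {sid: float(np.median(v)) for sid, v in out.items()}


@dataclass
class EnsembleDecision:
    """Per-sample verdicts of the 3 models and the resulting flag."""

    sample_id: str
    per_model_in_class: tuple[bool, bool, bool]
    flag: str  # "pork_in_class" | "not_pork_meat"


def classify_samples(
    models: Sequence[OCCModel],
    ds: SpectralDataset,
    scenario: int,
    rows: np.ndarray | None = None,
) -> list[EnsembleDecision]:
    """Flag each sample by the 2-of-3 out-of-class vote.

    Per model, the median of the sample's replicate distances is compared to
    that model's class limit for the scenario; a sample is flagged
    ``not_pork_meat`` iff at least 2 of the 3 models call it out-of-class.
    """
    if len(models) != 3:
        raise ConfigError(f"the ensemble vote requires exactly 3 models, got {len(models)}")
    for m in models:
        if int(scenario) not in m.class_limits:
            raise ConfigError(
                f"model {m.combo_id} has no class limit for scenario {scenario}"
            )
    per_model = [median_sample_distances(m, ds, rows) for m in models]
    sample_ids = list(per_model[0])
    decisions = []
    for sid in sample_ids:
        verdicts = tuple(
            per_model[k][sid] <= models[k].class_limits[int(scenario)] for k in range(3)
        )
        n_out = sum(not v for v in verdicts)
        flag = "not_pork_meat" if n_out >= 2 else "pork_in_class"
        decisions.append(EnsembleDecision(sid, verdicts, flag))
    return decisions


def correct_classification_rate(
    decisions: Sequence[EnsembleDecision],
    truth: Mapping[str, str],
    target: str = "pork",
) -> dict[str, float]:
    """Per-species correct-classification rate (%) of the ensemble flags.

    A target (pork) sample is correct when flagged in-class; any other
    species is correct when flagged ``not_pork_meat``.
    """
    counts: dict[str, list[int]] = {}
    for dec in decisions:
        species = truth[dec.sample_id]
        correct = (
            dec.flag == "pork_in_class" if species == target else dec.flag == "not_pork_meat"
        )
        counts.setdefault(species, []).append(int(correct))
    return {s: 100.0 * float(np.mean(v)) for s, v in counts.items()}


def fit_screening_ensemble(
    ds: SpectralDataset,
    records: Sequence[ScreeningRecord],
    combo_ids: Sequence[str],
    train_groups: Sequence[str],
    scenarios: Sequence[int] = (1, 2),
    q: float = 0.95,
    target: str = "pork",
) -> list[OCCModel]:
    """Fit the selected triplet on the target training samples and calibrate
    class limits for the requested scenarios."""
    by_id = {r.combo_id: r for r in records}
    missing = [c for c in combo_ids if c not in by_id]
    if missing:
        raise ConfigError(f"unknown combo ids: {missing}")
    groups = group_by_sample(ds)
    target_train = [
        g for g in train_groups if ds.meta[groups[g][0]].species == target
    ]
    if not target_train:
        raise ValidationError("no target-class samples among the training groups")
    tr_rows = rows_for_groups(ds, target_train)
    models = []
    for cid in combo_ids:
        rec = by_id[cid]
        chain, Xtr = fit_chain(rec.spec, ds.X[tr_rows])
        model = fit_occ(rec.algorithm, Xtr, rec.params)
        model.spec = rec.spec
        model.chain = chain
        med = median_sample_distances(model, ds, tr_rows)
        train_d = np.array([med[g] for g in target_train])
        for sc in scenarios:
            set_class_limit(model, train_d, sc, q=q)
        models.append(model)
    return models
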