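"""Group-aware train/test partitioning and cross-validation schemes.

Replicate scans of one physical sample must never straddle a partition —
otherwise near-duplicate spectra leak between training and test sets and
validation figures become meaningless.  All functions here therefore operate
on *samples* (groups of rows sharing a sample id) and expand to row indices
only at the end.

Deterministic sample-set partitioning (duplex, Kennard–Stone) works on one
representative vector per sample; by default the pipeline uses the SNV-
corrected mean spectrum of the sample's replicates, computed by
:func:`sample_representatives`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .dataset import SpectralDataset, group_by_sample
from .errors import ConfigError, ValidationError
from .preprocess import snv


@dataclass
class SplitResult:
    """A group-level train/test partition with the expanded row indices."""

    train_groups: list[str]
    test_groups: list[str]
    train_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    test_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def validate_partition(self, all_groups: Iterable[str]) -> None:
        train, test = set(self.train_groups), set(self.test_groups)
        if train & test:
            raise ValidationError(f"groups on both sides: {sorted(train & test)}")
        if train | test != set(all_groups):
            raise ValidationError("train/test groups do not cover all groups")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.train_groups + self.test_groups,
                "partition": ["train"] * len(self.train_groups)
                + ["test"] * len(self.test_groups),
            }
        )


@dataclass
class CVFolds:
    """Cross-validation folds expressed as (train_units, validation_units)."""

    scheme: str
    folds: list[tuple[np.ndarray, np.ndarray]]
    params: dict = field(default_factory=dict)


def _n_train(n_groups: int, train_fraction: float) -> int:
    if not 0.0 < train_fraction < 1.0:
        raise ConfigError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n_train = int(round(n_groups * train_fraction))
    return min(max(n_train, 1), n_groups - 1)


def duplex_split(
    representatives: np.ndarray, train_fraction: float = 0.7
) -> SplitResult:
    """Classic duplex partitioning of groups by alternating max–min selection.

    The two mutually farthest groups (Euclidean) seed the training set; the
    next farthest pair among the rest seeds the test set; thereafter the group
    farthest (max of minimum distance) from the growing set is assigned to
    train and test alternately, test assignment stopping at its quota.  Ties
    break to the lowest group index.  Group identity is positional — callers
    map indices back to sample ids.
    """
    R = np.atleast_2d(np.asarray(representatives, dtype=float))
    n = R.shape[0]
    if n < 4:
        raise ConfigError(f"duplex needs at least 4 groups, got {n}")
    n_train = _n_train(n, train_fraction)
    n_test = n - n_train
    D = cdist(R, R)

    def farthest_pair(pool: list[int]) -> tuple[int, int]:
        best, best_d = (pool[0], pool[1]), -1.0
        for ai, a in enumerate(pool):
            for b in pool[ai + 1 :]:
                if D[a, b] > best_d:
                    best, best_d = (a, b), D[a, b]
        return best

    def farthest_from(pool: list[int], chosen: list[int]) -> int:
        dmin = D[np.ix_(pool, chosen)].min(axis=1)
        return pool[int(np.argmax(dmin))]  # argmax takes first on ties → lowest index

    remaining = list(range(n))
    a, b = farthest_pair(remaining)
    train = [a, b]
    remaining = [i for i in remaining if i not in (a, b)]
    test: list[int] = []
    if n_test >= 2:
        c, d = farthest_pair(remaining)
        test = [c, d]
        remaining = [i for i in remaining if i not in (c, d)]
    elif n_test == 1:
        test = [farthest_from(remaining, train)]
        remaining = [i for i in remaining if i not in test]

    turn_train = True
    while remaining:
        if turn_train or len(test) >= n_test:
            pick = farthest_from(remaining, train)
            train.append(pick)
        else:
            pick = farthest_from(remaining, test)
            test.append(pick)
        remaining.remove(pick)
        turn_train = not turn_train
    return SplitResult([str(i) for i in sorted(train)], [str(i) for i in sorted(test)])


def kennard_stone_split(
    representatives: np.ndarray, train_fraction: float = 0.7
) -> SplitResult:
    """Kennard–Stone: max–min selection fills the training set, rest is test.

    ``train_fraction=1.0`` selects every group (empty test set, with a
    warning); useful when the ranking itself is wanted.
    """
    R = np.atleast_2d(np.asarray(representatives, dtype=float))
    n = R.shape[0]
    if n < 2:
        raise ConfigError("kennard-stone needs at least 2 groups")
    if train_fraction == 1.0:
        warnings.warn("kennard-stone selecting all groups; test set is empty")
        n_train = n
    else:
        n_train = _n_train(n, train_fraction)
    D = cdist(R, R)
    iu = np.triu_indices(n, 1)
    flat = int(np.argmax(D[iu]))
    train = [int(iu[0][flat]), int(iu[1][flat])]
    pool = [i for i in range(n) if i not in train]
    while len(train) < n_train and pool:
        dmin = D[np.ix_(pool, train)].min(axis=1)
        pick = pool[int(np.argmax(dmin))]
        train.append(pick)
        pool.remove(pick)
    return SplitResult([str(i) for i in sorted(train)], [str(i) for i in sorted(pool)])


def sample_representatives(
    ds: SpectralDataset, standardize: bool = True
) -> tuple[list[str], np.ndarray]:
    """One representative vector per sample: the (optionally SNV-corrected)
    mean of its replicate spectra.  Returns (sample ids, matrix)."""
    X = snv(ds.X) if standardize else ds.X
    groups = group_by_sample(ds)
    ids = list(groups)
    R = np.vstack([X[rows].mean(axis=0) for rows in groups.values()])
    return ids, R


def _expand_rows(
    groups: Mapping[str, np.ndarray], ids: Sequence[str]
) -> np.ndarray:
    if not ids:
        return np.empty(0, dtype=int)
    return np.concatenate([groups[g] for g in ids])


def stratified_sample_split(
    ds: SpectralDataset,
    method: str = "duplex",
    train_fraction: float = 0.7,
    seed: int | None = None,
    standardize: bool = True,
) -> SplitResult:
    """Species-stratified group-level split of a dataset.

    The chosen method (``duplex``, ``kennard_stone`` or ``random``) runs
    within each species stratum on per-sample mean spectra, so every species
    is represented on both sides; row indices are expanded at the end.
    """
    groups = group_by_sample(ds)
    ids, R = sample_representatives(ds, standardize=standardize)
    species_of = ds.sample_species()
    train_ids: list[str] = []
    test_ids: list[str] = []
    for species in dict.fromkeys(species_of.values()):
        stratum = [i for i, sid in enumerate(ids) if species_of[sid] == species]
        sub = R[stratum]
        if method == "duplex":
            res = duplex_split(sub, train_fraction)
        elif method == "kennard_stone":
            res = kennard_stone_split(sub, train_fraction)
        elif method == "random":
            if seed is None:
                raise ConfigError("random split requires a seed")
            rng = np.random.default_rng(seed)
            order = rng.permutation(len(stratum))
            k = _n_train(len(stratum), train_fraction)
            res = SplitResult(
                [str(i) for i in sorted(order[:k])], [str(i) for i in sorted(order[k:])]
            )
        else:
            raise ConfigError(f"unknown split method {method!r}")
        train_ids.extend(ids[stratum[int(i)]] for i in res.train_groups)
        test_ids.extend(ids[stratum[int(i)]] for i in res.test_groups)
    return SplitResult(
        train_ids,
        test_ids,
        _expand_rows(groups, train_ids),
        _expand_rows(groups, test_ids),
    )


def random_split(
    groups: Sequence[str],
    train_fraction: float,
    seed: int,
    species_of: Mapping[str, str] | None = None,
) -> SplitResult:
    """Uniform group-level split, optionally stratified by species; seeded."""
    rng = np.random.default_rng(seed)
    groups = list(groups)
    strata: dict[str, list[str]]
    if species_of is None:
        strata = {"all": groups}
    else:
        strata = {}
        for g in groups:
            strata.setdefault(species_of[g], []).append(g)
    train: list[str] = []
    test: list[str] = []
    for members in strata.values():
        order = rng.permutation(len(members))
        k = _n_train(len(members), train_fraction)
        train.extend(members[i] for i in order[:k])
        test.extend(members[i] for i in order[k:])
    return SplitResult(train, test)


def venetian_blinds(
    n_units: int, n_splits: int = 10, thickness: int = 1
) -> CVFolds:
    """Venetian-blinds folds: unit ``i`` validates in fold
    ``floor(i/thickness) mod n_splits``."""
    if n_units < n_splits:
        raise ConfigError(f"need at least n_splits={n_splits} units, got {n_units}")
    idx = np.arange(n_units)
    assignment = (idx // thickness) % n_splits
    folds = []
    for f in range(n_splits):
        val = idx[assignment == f]
        folds.append((idx[assignment != f], val))
    return CVFolds("venetian_blinds", folds, {"n_splits": n_splits, "thickness": thickness})


def cv_folds(
    scheme: str,
    n_units: int,
    params: Mapping | None = None,
    seed: int | None = None,
) -> CVFolds:
    """Build CV folds over ``n_units`` units (samples, not scans).

    Schemes: ``venetian_blinds``, ``loo``, ``kfold`` (shuffled contiguous),
    ``random_subsets`` (repeated random s-fold partitions).
    """
    params = dict(params or {})
    idx = np.arange(n_units)
    if scheme == "venetian_blinds":
        return venetian_blinds(
            n_units, params.get("n_splits", 10), params.get("thickness", 1)
        )
    if scheme == "loo":
        folds = [(np.delete(idx, i), np.array([i])) for i in range(n_units)]
        return CVFolds("loo", folds, {})
    if scheme == "kfold":
        k = int(params.get("k", 5))
        if not 2 <= k <= n_units:
            raise ConfigError(f"kfold needs 2 <= k <= n_units, got k={k}")
        rng = np.random.default_rng(seed)
        order = rng.permutation(n_units)
        folds = [
            (np.sort(np.setdiff1d(idx, val)), np.sort(val))
            for val in np.array_split(order, k)
        ]
        return CVFolds("kfold", folds, {"k": k})
    if scheme == "random_subsets":
        k = int(params.get("k", 5))
        repeats = int(params.get("repeats", 5))
        rng = np.random.default_rng(seed)
        folds = []
        for _ in range(repeats):
            order = rng.permutation(n_units)
            folds.extend(
                (np.sort(np.setdiff1d(idx, val)), np.sort(val))
                for val in np.array_split(order, k)
            )
        return CVFolds("random_subsets", folds, {"k": k, "repeats": repeats})
    raise ConfigError(f"unknown CV scheme {scheme!r}")


def repeated_random_cv(
    groups: Sequence[str],
    n_repeats: int = 80,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> list[SplitResult]:
    """Repeated random group-level splits of the target class.

    Default 80 repetitions of a 70/30 split with replicates kept together —
    the resampling protocol behind one-class screening AUROCs.
    """
    rng = np.random.default_rng(seed)
    groups = list(groups)
    k = _n_train(len(groups), train_fraction)
    out = []
    for _ in range(n_repeats):
        order = rng.permutation(len(groups))
        out.append(
            SplitResult(
                [groups[i] for i in order[:k]], [groups[i] for i in order[k:]]
            )
        )
    return out


def rows_for_groups(ds: SpectralDataset, ids: Sequence[str]) -> np.ndarray:
    """Row indices of the given sample ids, in group order."""
    groups = group_by_sample(ds)
    return _expand_rows(groups, list(ids))
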