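"""One-class models, AUROC screening, class limits and the ensemble vote."""

import numpy as np
import pytest

from meatspec.dataset import ScanMeta, SpectralDataset, nir_grid
from meatspec.errors import ConfigError, FitError, ValidationError
from meatspec.occ import (
    OCCModel,
    ScreeningRecord,
    _BaseOCC,
    auroc,
    class_distance,
    classify_samples,
    correct_classification_rate,
    fit_occ,
    fit_screening_ensemble,
    screen_grid,
    select_triplet,
    set_class_limit,
)
from meatspec.preprocess import PreprocessSpec, fit_chain
from meatspec.serialize import occ_models_from_dict, occ_models_to_dict
from meatspec.splitting import stratified_sample_split


class TestClassDistances:
    def test_mahalanobis_identity_covariance(self, rng):
        # whiten scores exactly: unit covariance plane embedded in 6-D
        S0 = rng.normal(size=(50, 2))
        S0 -= S0.mean(axis=0)
        L = np.linalg.cholesky(np.cov(S0, rowvar=False, ddof=1))
        S = S0 @ np.linalg.inv(L).T  # sample covariance exactly identity
        V, _ = np.linalg.qr(rng.normal(size=(6, 2)))
        mean = rng.normal(size=6)
        X = S @ V.T + mean
        model = fit_occ("mahalanobis", X, {"n_components": 2})
        query = mean + np.array([3.0, 4.0]) @ V.T  # in-plane point at radius 5
        np.testing.assert_allclose(class_distance(model, query[None, :]), 5.0, atol=1e-7)

    def test_knn_distance_on_line(self):
        model = fit_occ("knn_dist", np.array([[0.0], [1.0], [2.0]]), {"n_components": 1, "k": 1})
        np.testing.assert_allclose(class_distance(model, np.array([[5.0]])), 3.0)
        np.testing.assert_allclose(class_distance(model, np.array([[1.0]])), 0.0, atol=1e-12)

    def test_pca_residual_zero_in_span(self, rng):
        X = rng.normal(size=(20, 6))
        model = fit_occ("pca_residual", X, {"n_components": 3})
        basis = model.estimator.basis_
        q = basis.mean + basis.scores(X[:1]) @ basis.components
        np.testing.assert_allclose(class_distance(model, q), 0.0, atol=1e-12)

    def test_pca_residual_quadratic_scaling(self, rng):
        X = rng.normal(size=(20, 6))
        model = fit_occ("pca_residual", X, {"n_components": 2})
        basis = model.estimator.basis_
        row = X[:1]
        in_span = basis.mean + basis.scores(row) @ basis.components
        resid = row - in_span
        d1 = class_distance(model, in_span + resid)
        d2 = class_distance(model, in_span + 2 * resid)
        np.testing.assert_allclose(d2, 4 * d1, rtol=1e-9)

    def test_simca_self_normalisation(self, rng):
        X = rng.normal(size=(30, 8))
        model = fit_occ("simca", X, {"n_components": 3})
        est = model.estimator
        np.testing.assert_allclose(est.basis_.q_statistic(X).mean() / est.q_mean_, 1.0)
        np.testing.assert_allclose(est.basis_.t2_statistic(X).mean() / est.t2_mean_, 1.0)

    def test_ocsvm_training_rows_nonnegative_with_zero_min(self, rng):
        X = rng.normal(size=(40, 5))
        model = fit_occ("ocsvm", X)
        d = class_distance(model, X)
        assert np.all(d >= 0)
        assert np.isclose(d.min(), 0.0, atol=1e-9)

    def test_too_few_rows_errors(self, rng):
        with pytest.raises(FitError):
            fit_occ("simca", rng.normal(size=(3, 8)), {"n_components": 3})

    def test_unknown_algorithm(self):
        with pytest.raises(ConfigError):
            fit_occ("isolation_forest", np.zeros((5, 3)))


class TestAuroc:
    def test_known_values(self):
        assert auroc([1, 2], [3, 4]) == 1.0
        assert auroc([1, 1, 1], [1, 1]) == 0.5
        assert auroc([1, 3], [2, 4]) == 0.75

    def test_equals_brute_force_pairwise_counting(self, rng):
        # ties included via discretisation
        t = np.round(rng.normal(size=150), 1)
        o = np.round(rng.normal(0.3, 1.0, size=200), 1)
        brute = np.mean([(a < b) + 0.5 * (a == b) for a in t for b in o])
        np.testing.assert_allclose(auroc(t, o), brute, atol=1e-12)

    def test_monotone_transform_invariance(self, rng):
        t = rng.exponential(size=60)
        o = rng.exponential(2.0, size=80)
        base = auroc(t, o)
        assert auroc(np.exp(t), np.exp(o)) == base
        assert auroc(t**3, o**3) == base

    def test_empty_inputs_error(self):
        with pytest.raises(ValidationError):
            auroc([], [1.0])


class TestClassLimits:
    def test_scenario_one_keeps_all_training_samples(self):
        model = fit_occ("knn_dist", np.arange(10.0)[:, None], {"n_components": 1})
        d = np.array([0.1, 0.5, 0.9])
        limit = set_class_limit(model, d, 1)
        assert limit >= 0.9
        assert np.all(d <= limit)

    def test_scenario_two_percentile(self, rng):
        model = fit_occ("knn_dist", np.arange(10.0)[:, None], {"n_components": 1})
        d = rng.uniform(size=100)
        limit = set_class_limit(model, d, 2)
        out = np.sum(d > limit)
        assert 3 <= out <= 7  # ~5 of 100 beyond the 95th percentile

    def test_scenario_two_not_above_scenario_one(self, rng):
        model = fit_occ("knn_dist", np.arange(10.0)[:, None], {"n_components": 1})
        d = rng.uniform(size=50)
        assert set_class_limit(model, d, 2) <= set_class_limit(model, d, 1)

    def test_empty_distances_error(self):
        model = fit_occ("knn_dist", np.arange(10.0)[:, None], {"n_components": 1})
        with pytest.raises(ValidationError):
            set_class_limit(model, np.array([]), 1)


class _ColumnDistance(_BaseOCC):
    """Test stub: the class distance is simply the first channel value."""

    def fit(self, X):
        return self

    def distance(self, X):
        return np.asarray(X, dtype=float)[:, 0]


def _stub_model(limit: float) -> OCCModel:
    spec = PreprocessSpec([])
    chain, _ = fit_chain(spec, np.zeros((1, 252)))
    return OCCModel("stub", spec, {}, _ColumnDistance(), chain, {1: limit})


def _vote_dataset(values_by_sample: dict[str, list[float]]) -> SpectralDataset:
    rows, meta = [], []
    for sid, vals in values_by_sample.items():
        for r, v in enumerate(vals, start=1):
            row = np.zeros(252)
            row[0] = v
            rows.append(row)
            meta.append(ScanMeta(sid, "pork", "intact", r))
    return SpectralDataset(np.vstack(rows), nir_grid(), meta)


class TestEnsembleVote:
    def test_two_of_three_out_flags_not_pork(self):
        ds = _vote_dataset({"A": [1.0] * 6})
        models = [_stub_model(0.5), _stub_model(0.5), _stub_model(2.0)]  # out, out, in
        (dec,) = classify_samples(models, ds, 1)
        assert dec.flag == "not_pork_meat"
        assert dec.per_model_in_class == (False, False, True)

    def test_single_out_vote_stays_in_class(self):
        ds = _vote_dataset({"A": [1.0] * 6})
        models = [_stub_model(2.0), _stub_model(2.0), _stub_model(0.5)]  # in, in, out
        (dec,) = classify_samples(models, ds, 1)
        assert dec.flag == "pork_in_class"

    def test_median_of_even_replicate_count(self):
        # median of {1,1,1,9,9,9} = 5 > limit 2 → out for every model
        ds = _vote_dataset({"A": [1, 1, 1, 9, 9, 9]})
        models = [_stub_model(2.0)] * 3
        (dec,) = classify_samples(models, ds, 1)
        assert dec.flag == "not_pork_meat"

    def test_requires_three_models(self):
        ds = _vote_dataset({"A": [1.0] * 6})
        with pytest.raises(ConfigError):
            classify_samples([_stub_model(1.0)] * 2, ds, 1)

    def test_rates_arithmetic(self):
        from meatspec.occ import EnsembleDecision

        decisions = [
            EnsembleDecision("p1", (True, True, True), "pork_in_class"),
            EnsembleDecision("p2", (False, False, True), "not_pork_meat"),
            EnsembleDecision("l1", (False, False, False), "not_pork_meat"),
            EnsembleDecision("l2", (True, True, False), "pork_in_class"),
        ]
        truth = {"p1": "pork", "p2": "pork", "l1": "lamb", "l2": "lamb"}
        rates = correct_classification_rate(decisions, truth)
        assert rates == {"pork": 50.0, "lamb": 50.0}


def _record(combo_id, lamb, beef, chicken):
    vals = {"lamb": lamb, "beef": beef, "chicken": chicken}
    vals["all"] = float(np.mean([lamb, beef, chicken]))
    return ScreeningRecord(combo_id, PreprocessSpec([]), "simca", {}, vals)


class TestSelectTriplet:
    def test_dominant_combo_selected_first(self):
        records = [
            _record("weak1", 0.6, 0.6, 0.6),
            _record("dominant", 0.99, 0.99, 0.99),
            _record("weak2", 0.7, 0.5, 0.6),
            _record("weak3", 0.55, 0.65, 0.6),
        ]
        assert select_triplet(records)[0] == "dominant"

    def test_orthogonal_specialists_jointly_selected(self):
        records = [
            _record("lamb-expert", 0.95, 0.55, 0.55),
            _record("beef-expert", 0.55, 0.95, 0.55),
            _record("chicken-expert", 0.55, 0.55, 0.95),
            _record("mediocre", 0.50, 0.52, 0.51),
        ]
        chosen = set(select_triplet(records))
        assert chosen == {"lamb-expert", "beef-expert", "chicken-expert"}

    def test_manual_override_verbatim(self):
        records = [_record(f"c{i}", 0.5 + i / 100, 0.5, 0.5) for i in range(5)]
        assert select_triplet(records, override=["c0", "c3", "c1"]) == ["c0", "c3", "c1"]

    def test_too_few_records(self):
        with pytest.raises(ConfigError):
            select_triplet([_record("a", 0.9, 0.9, 0.9)])


class TestScreening:
    def test_record_shape_and_failure_isolation(self, nir_campaign):
        grid = [
            (PreprocessSpec([("snv", {})]), "simca", {"n_components": 2}),
            # stencil wider than the 252-channel row → combination must fail
            (PreprocessSpec([("gapseg", {"gap": 200, "seg": 200, "order": 2})]), "simca", {}),
        ]
        records = screen_grid(nir_campaign, grid, n_repeats=3, seed=0)
        assert len(records) == 2
        ok, failed = records
        assert set(ok.auroc_vs) == {"lamb", "beef", "chicken", "all"}
        assert all(0.0 <= v <= 1.0 for v in ok.auroc_vs.values())
        assert failed.failed and failed.error

    def test_deterministic_given_seed(self, nir_campaign):
        grid = [(PreprocessSpec([("snv", {})]), "pca_residual", {"n_components": 2})]
        a = screen_grid(nir_campaign, grid, n_repeats=4, seed=9)
        b = screen_grid(nir_campaign, grid, n_repeats=4, seed=9)
        assert a[0].auroc_vs == b[0].auroc_vs


class TestEnsembleEndToEnd:
    def test_separable_campaign_flags_only_non_pork(self, visnir_campaign):
        ds = visnir_campaign
        grid = [
            (PreprocessSpec([("snv", {})]), "simca", {"n_components": 3}),
            (PreprocessSpec([("snv", {})]), "pca_residual", {"n_components": 3}),
            (PreprocessSpec([("savgol", {"w": 11, "p": 2, "d": 1})]), "ocsvm", {}),
        ]
        records = screen_grid(ds, grid, n_repeats=10, seed=1)
        combos = select_triplet(records)
        split = stratified_sample_split(ds, "duplex", 0.7)
        models = fit_screening_ensemble(ds, records, combos, split.train_groups)
        decisions = classify_samples(models, ds, 1)
        rates = correct_classification_rate(decisions, ds.sample_species())
        assert rates["pork"] >= 95.0
        assert min(rates[s] for s in ("lamb", "beef", "chicken")) >= 90.0

    def test_json_round_trip_preserves_decisions(self, visnir_campaign):
        ds = visnir_campaign
        grid = [
            (PreprocessSpec([("snv", {})]), "simca", {"n_components": 3}),
            (PreprocessSpec([("msc", {"mode": "mean"})]), "mahalanobis", {"n_components": 3}),
            (PreprocessSpec([("savgol", {"w": 11, "p": 2, "d": 1})]), "ocsvm", {}),
        ]
        records = screen_grid(ds, grid, n_repeats=4, seed=2)
        split = stratified_sample_split(ds, "duplex", 0.7)
        models = fit_screening_ensemble(
            ds, records, [r.combo_id for r in records], split.train_groups
        )
        restored = occ_models_from_dict(occ_models_to_dict(models))
        for orig, back in zip(models, restored):
            assert back.class_limits == orig.class_limits
            np.testing.assert_allclose(
                class_distance(back, back.chain.transform(ds.X[:12])),
                class_distance(orig, orig.chain.transform(ds.X[:12])),
                rtol=1e-10,
            )
        a = classify_samples(models, ds, 2)
        b = classify_samples(restored, ds, 2)
        assert [d.flag for d in a] == [d.flag for d in b]
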