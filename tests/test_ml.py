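"""Model-building procedure: splitting, preprocessing, CV, randomized search."""

import numpy as np
import pytest

from oracles import auc_oracle, robust_scale_oracle
from plaqueomics.ml import (FAMILIES, PipelineConfig, RadiomicsPreprocessor,
                            cross_validate, evaluate_validation,
                            preprocess_fit, run_search, sample_config,
                            split_train_validation, FittedPipeline,
                            _make_model, _stratified_folds)


def _config(**kw):
    defaults = dict(family="logistic_regression", fpr_alpha=0.5,
                    fwer_alpha=0.5, pca_var_fraction=0.95,
                    family_params={"C": 1.0}, seed=0)
    defaults.update(kw)
    return PipelineConfig(**defaults)


def _synthetic(n=120, p_signal=5, p_noise=40, seed=0, delta=1.5):
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 3 == 0).astype(int)
    X = rng.normal(size=(n, p_signal + p_noise))
    X[:, :p_signal] += delta * y[:, None]
    return X, y


class TestSplit:
    def test_study_sizes_445_at_75_percent(self):
        split = split_train_validation(445, 0.75, seed=0)
        assert len(split.train_idx) == 333
        assert len(split.validation_idx) == 112

    def test_disjoint_and_exhaustive(self):
        split = split_train_validation(101, 0.6, seed=3)
        joined = np.concatenate([split.train_idx, split.validation_idx])
        assert np.array_equal(np.sort(joined), np.arange(101))

    def test_small_even_split(self):
        split = split_train_validation(4, 0.5, seed=1)
        assert len(split.train_idx) == 2 and len(split.validation_idx) == 2

    def test_same_seed_reproduces(self):
        a = split_train_validation(50, 0.75, seed=9)
        b = split_train_validation(50, 0.75, seed=9)
        assert np.array_equal(a.train_idx, b.train_idx)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            split_train_validation(1, 0.5, seed=0)


class TestPreprocess:
    def test_constant_column_dropped(self):
        X, y = _synthetic()
        X[:, 7] = 3.0
        prep = preprocess_fit(X, y, _config())
        assert not prep._stats.usable[7]

    def test_robust_scaling_matches_quartile_oracle(self):
        rng = np.random.default_rng(4)
        col = rng.normal(size=60)
        X = np.column_stack([col, rng.normal(2, 1, size=60) +
                             (np.arange(60) % 2)])
        y = (np.arange(60) % 2).astype(int)
        prep = RadiomicsPreprocessor(1.0, 1.0, 0.999)
        prep.fit(X, y)
        Z = prep._scale_select(X)
        for j_out, j_in in enumerate(np.flatnonzero(prep._stats.usable)[prep.selected]):
            for i in (0, 5, 17):
                assert Z[i, j_out] == pytest.approx(
                    robust_scale_oracle(X[:, j_in], X[i, j_in]), abs=1e-10)

    def test_selection_chain_fpr_then_bonferroni(self):
        X, y = _synthetic(n=200, p_signal=4, p_noise=100, delta=2.5)
        loose = preprocess_fit(X, y, _config(fpr_alpha=0.9999, fwer_alpha=0.9999))
        strict = preprocess_fit(X, y, _config(fpr_alpha=0.01, fwer_alpha=0.01))
        assert strict.selected.sum() < loose.selected.sum()
        # the informative columns survive the strict chain
        assert strict.selected[:4].all()

    def test_no_survivors_flags_failure(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 30))
        y = (np.arange(80) % 2).astype(int)
        prep = preprocess_fit(X, y, _config(fpr_alpha=1e-4, fwer_alpha=1e-4))
        assert prep.failed

    def test_pca_keeps_smallest_count_reaching_fraction(self):
        X, y = _synthetic(n=100, p_signal=3, p_noise=20)
        prep = preprocess_fit(X, y, _config(pca_var_fraction=0.9))
        cum = np.cumsum(prep.pca.explained_variance_ratio_)
        k = prep.n_components
        assert cum[k - 1] >= 0.9
        assert k == 1 or cum[k - 2] < 0.9

    def test_fpr_selection_passes_alpha_fraction_of_noise(self):
        """Pure-noise features survive the FPR filter at ~alpha rate."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(200, 2000))
        y = rng.integers(0, 2, size=200)
        prep = RadiomicsPreprocessor(0.05, 1.0, 0.95)
        survived = (RadiomicsPreprocessor(0.05, 1.0, 0.95)
                    .fit(X, y)._stats.pvals < 0.05).mean()
        assert 0.03 <= survived <= 0.07


class TestSampleConfig:
    def test_reproducible_draws(self):
        a = [sample_config("knn", np.random.default_rng(5)) for _ in range(3)]
        b = [sample_config("knn", np.random.default_rng(5)) for _ in range(3)]
        assert [c.family_params for c in a] == [c.family_params for c in b]

    @pytest.mark.parametrize("family", FAMILIES)
    def test_ranges_and_model_construction(self, family):
        rng = np.random.default_rng(8)
        for _ in range(200):
            c = sample_config(family, rng)
            assert c.family == family
            assert 1e-4 <= c.fpr_alpha <= 0.5
            assert 1e-4 <= c.fwer_alpha <= 0.5
            assert 0.80 <= c.pca_var_fraction <= 0.999
        _make_model(c)  # constructible


class TestCrossValidate:
    def test_perfect_separator_gives_auc_one(self):
        rng = np.random.default_rng(0)
        y = (np.arange(100) % 2).astype(int)
        X = np.column_stack([y + 0.01 * rng.normal(size=100),
                             rng.normal(size=100)])
        mean_auc, fold_aucs = cross_validate(_config(), X, y, seed=1)
        assert mean_auc == pytest.approx(1.0)
        assert len(fold_aucs) == 5

    def test_each_sample_held_out_exactly_once(self):
        y = (np.arange(40) % 2).astype(int)
        folds = _stratified_folds(y, 5, seed=0)
        held_out = np.concatenate([te for _, te in folds])
        assert np.array_equal(np.sort(held_out), np.arange(40))

    def test_permuted_labels_score_near_half(self):
        """Null CV AUC is 0.5 within Monte-Carlo error."""
        rng = np.random.default_rng(21)
        aucs = []
        for rep in range(20):
            X, y = _synthetic(n=100, seed=rep)
            y_perm = rng.permutation(y)
            mean_auc, _ = cross_validate(_config(), X, y_perm, seed=rep)
            aucs.append(mean_auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.1)

    def test_too_few_minority_samples_raises(self):
        y = np.array([0] * 30 + [1] * 3)
        with pytest.raises(ValueError):
            _stratified_folds(y, 5, seed=0)


class TestRunSearch:
    def test_deterministic_winner_and_log_shape(self):
        X, y = _synthetic(n=80, seed=2)
        a = run_search(X, y, iterations=2, seed=5)
        b = run_search(X, y, iterations=2, seed=5)
        assert len(a.log) == 2 * 8
        assert a.best_config.family == b.best_config.family
        assert a.best_mean_auc == pytest.approx(b.best_mean_auc)
        assert set(a.best_per_family) == set(FAMILIES)

    def test_best_has_max_mean_cv_auc(self):
        X, y = _synthetic(n=80, seed=3)
        result = run_search(X, y, iterations=2, seed=1)
        assert result.best_mean_auc == pytest.approx(result.log["mean_cv_auc"].max())

    def test_validation_scores_ignore_validation_labels(self):
        """No information leak: the fitted pipeline's validation scores do
        not depend on the validation labels."""
        X, y = _synthetic(n=140, seed=4)
        Xt, yt = X[:100], y[:100]
        Xv, yv = X[100:], y[100:]
        result = run_search(Xt, yt, iterations=1, seed=0)
        s1 = result.fitted.predict_scores(Xv)
        s2 = result.fitted.predict_scores(Xv)  # labels never enter scoring
        assert np.array_equal(s1, s2)
        roc_a = evaluate_validation(result.fitted, Xv, yv)
        roc_b = evaluate_validation(result.fitted, Xv, 1 - yv)
        assert np.array_equal(roc_a.scores, roc_b.scores)
        assert roc_a.auc == pytest.approx(1 - roc_b.auc)


class TestEvaluateValidation:
    def _fitted(self, X, y):
        config = _config()
        prep = preprocess_fit(X, y, config)
        model = _make_model(config)
        model.fit(prep.transform(X), y)
        return FittedPipeline(preprocessor=prep, model=model, config=config)

    def test_auc_matches_pair_counting_oracle(self):
        X, y = _synthetic(n=150, seed=6, delta=0.8)
        fitted = self._fitted(X[:100], y[:100])
        roc = evaluate_validation(fitted, X[100:], y[100:])
        scores = fitted.predict_scores(X[100:])
        assert roc.auc == pytest.approx(auc_oracle(scores, y[100:]), abs=1e-12)

    def test_anti_learned_scores_below_half(self):
        X, y = _synthetic(n=150, seed=7)
        fitted = self._fitted(X[:100], y[:100])
        scores = -fitted.predict_scores(X[100:])
        from plaqueomics.evaluation import auc_delong
        assert auc_delong(scores, y[100:]).auc < 0.5
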