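"""Randomized model search over eight classifier families.

The model-building procedure mirrors common radiomics practice: features are
(a) stripped of zero-variance columns, (b) robust-scaled by median and
interquartile range, (c) filtered by univariate ANOVA F-tests at a sampled
false-positive-rate threshold and then a sampled Bonferroni family-wise
threshold, and (d) projected onto the fewest principal components explaining
a sampled fraction of variance, before (e) a classifier with sampled
hyperparameters is fitted.  Every preprocessing statistic is estimated on
training folds only and applied unchanged to held-out data.

Each sampled configuration is scored by the mean AUC of stratified five-fold
cross-validation on the training set; the search draws a fixed number of
configurations per family (logistic regression, K-nearest neighbors, random
forest, least angle regression, naive Bayes, Gaussian process, decision
tree, neural network), selects the best by mean CV AUC (ties broken by
evaluation order), and refits it on the full training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.linear_model import Lars, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.tree import DecisionTreeClassifier

from .evaluation import ROCResult, auc_delong

__all__ = [
    "FAMILIES",
    "SplitSpec",
    "PipelineConfig",
    "SearchResult",
    "FittedPipeline",
    "RadiomicsPreprocessor",
    "split_train_validation",
    "sample_config",
    "cross_validate",
    "run_search",
    "evaluate_validation",
]

FAMILIES: tuple[str, ...] = (
    "logistic_regression", "knn", "random_forest", "least_angle_regression",
    "naive_bayes", "gaussian_process", "decision_tree", "neural_network",
)


@dataclass(frozen=True)
class SplitSpec:
    """Random train/validation split: first floor(n * fraction) of a seeded
    uniform permutation go to training."""

    train_idx: np.ndarray
    validation_idx: np.ndarray
    train_fraction: float
    seed: int


def split_train_validation(n: int, train_fraction: float, seed: int) -> SplitSpec:
    if n < 2:
        raise ValueError("need at least two samples to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * train_fraction))
    return SplitSpec(train_idx=np.sort(perm[:n_train]),
                     validation_idx=np.sort(perm[n_train:]),
                     train_fraction=train_fraction, seed=seed)


@dataclass(frozen=True)
class PipelineConfig:
    """One sampled preprocessing + model configuration."""

    family: str
    fpr_alpha: float
    fwer_alpha: float
    pca_var_fraction: float
    family_params: dict
    seed: int

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if not (0.0 < self.fpr_alpha <= 1.0 and 0.0 < self.fwer_alpha <= 1.0):
            raise ValueError("selection alphas must be in (0, 1]")
        if not 0.0 < self.pca_var_fraction < 1.0:
            raise ValueError("pca_var_fraction must be in (0, 1)")


def sample_config(family: str, rng: np.random.Generator) -> PipelineConfig:
    """Draw one random configuration for a family.

    Selection thresholds are log-uniform on [1e-4, 0.5], the PCA variance
    fraction uniform on [0.80, 0.999]; family grids are documented below.
    """

    def log_uniform(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    fpr_alpha = log_uniform(1e-4, 0.5)
    fwer_alpha = log_uniform(1e-4, 0.5)
    pca = float(rng.uniform(0.80, 0.999))
    if family == "logistic_regression":
        params = {"C": log_uniform(1e-3, 1e3)}
    elif family == "knn":
        params = {"n_neighbors": int(rng.integers(1, 51))}
    elif family == "random_forest":
        params = {"n_estimators": int(rng.integers(50, 501)),
                  "max_depth": int(rng.integers(2, 21))}
    elif family == "least_angle_regression":
        params = {"n_nonzero_coefs": int(rng.integers(1, 51))}
    elif family == "naive_bayes":
        params = {"var_smoothing": log_uniform(1e-12, 1e-6)}
    elif family == "gaussian_process":
        params = {"length_scale": log_uniform(0.1, 100.0)}
    elif family == "decision_tree":
        params = {"max_depth": int(rng.integers(1, 21)),
                  "min_samples_leaf": int(rng.integers(1, 21))}
    elif family == "neural_network":
        n_layers = int(rng.integers(1, 4))
        units = tuple(int(rng.choice([8, 16, 32, 64])) for _ in range(n_layers))
        params = {"hidden_layer_sizes": units,
                  "alpha": log_uniform(1e-6, 1e-1)}
    else:
        raise ValueError(f"unknown model family {family!r}")
    return PipelineConfig(family=family, fpr_alpha=fpr_alpha,
                          fwer_alpha=fwer_alpha, pca_var_fraction=pca,
                          family_params=params,
                          seed=int(rng.integers(0, 2 ** 31)))


def _make_model(config: PipelineConfig, n_train: int | None = None):
    p = config.family_params
    family = config.family
    if family == "logistic_regression":
        return LogisticRegression(C=p["C"], solver="lbfgs", max_iter=2000)
    if family == "knn":
        k = p["n_neighbors"]
        if n_train is not None:  # k cannot exceed the fitted sample count
            k = min(k, n_train)
        return KNeighborsClassifier(n_neighbors=k)
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=p["n_estimators"],
                                      max_depth=p["max_depth"],
                                      random_state=config.seed, n_jobs=1)
    if family == "least_angle_regression":
        return Lars(n_nonzero_coefs=p["n_nonzero_coefs"])
    if family == "naive_bayes":
        return GaussianNB(var_smoothing=p["var_smoothing"])
    if family == "gaussian_process":
        # optimizer=None keeps the sampled length-scale as the hyperparameter
        # actually used, as randomized search intends.
        return GaussianProcessClassifier(kernel=RBF(length_scale=p["length_scale"]),
                                         optimizer=None)
    if family == "decision_tree":
        return DecisionTreeClassifier(max_depth=p["max_depth"],
                                      min_samples_leaf=p["min_samples_leaf"],
                                      random_state=config.seed)
    if family == "neural_network":
        return MLPClassifier(hidden_layer_sizes=p["hidden_layer_sizes"],
                             alpha=p["alpha"], solver="lbfgs", max_iter=400,
                             random_state=config.seed)
    raise ValueError(f"unknown model family {family!r}")


def _model_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    if hasattr(model, "decision_function"):
        return model.decision_function(X)
    return model.predict(X)  # regressors (least angle regression)


class _ColumnStats:
    """Per-column training statistics that do not depend on the sampled
    hyperparameters: usable-column mask, medians, IQRs, F-test p-values."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        variances = X.var(axis=0)
        q1, med, q3 = np.percentile(X, (25, 50, 75), axis=0)
        iqr = q3 - q1
        self.usable = (variances > 0) & (iqr > 0)
        self.median = med[self.usable]
        self.iqr = iqr[self.usable]
        with np.errstate(divide="ignore", invalid="ignore"):
            _, pvals = f_classif(X[:, self.usable], y)
        self.pvals = np.nan_to_num(pvals, nan=1.0)


class RadiomicsPreprocessor:
    """Fitted preprocessing chain: zero-variance drop, robust scaling,
    FPR-then-FWER univariate selection, PCA.

    ``failed`` is set when no feature survives selection; the caller scores
    such configurations with AUC 0.5.
    """

    def __init__(self, fpr_alpha: float, fwer_alpha: float,
                 pca_var_fraction: float):
        self.fpr_alpha = fpr_alpha
        self.fwer_alpha = fwer_alpha
        self.pca_var_fraction = pca_var_fraction
        self.failed = False

    def fit(self, X: np.ndarray, y: np.ndarray,
            _stats: _ColumnStats | None = None) -> "RadiomicsPreprocessor":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).astype(int)
        if min(np.bincount(y, minlength=2)) < 2:
            raise ValueError("need >= 2 samples per class")
        stats = _stats if _stats is not None else _ColumnStats(X, y)
        self._stats = stats
        survived_fpr = stats.pvals < self.fpr_alpha
        m = int(survived_fpr.sum())
        selected = survived_fpr.copy()
        if m > 0:
            selected &= stats.pvals < self.fwer_alpha / m
        self.selected = selected
        if not selected.any():
            self.failed = True
            return self
        Z = self._scale_select(X)
        n_comp_max = min(Z.shape[0], Z.shape[1])
        pca = PCA(n_components=n_comp_max, svd_solver="full")
        pca.fit(Z)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, self.pca_var_fraction) + 1)
        k = min(k, n_comp_max)
        self.pca = pca
        self.n_components = k
        return self

    def _scale_select(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        Z = (X[:, self._stats.usable] - self._stats.median) / self._stats.iqr
        return Z[:, self.selected]

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.failed:
            raise RuntimeError("preprocessor failed: no features survived selection")
        return self.pca.transform(self._scale_select(X))[:, :self.n_components]


def preprocess_fit(X, y, config: PipelineConfig) -> RadiomicsPreprocessor:
    """Fit the preprocessing chain of one configuration on training data."""
    return RadiomicsPreprocessor(config.fpr_alpha, config.fwer_alpha,
                                 config.pca_var_fraction).fit(X, y)


@dataclass
class FittedPipeline:
    """A preprocessor + model pair fitted on one training set."""

    preprocessor: RadiomicsPreprocessor
    model: object
    config: PipelineConfig

    def predict_scores(self, X) -> np.ndarray:
        return _model_scores(self.model, self.preprocessor.transform(np.asarray(X)))


def _stratified_folds(y: np.ndarray, k: int, seed: int):
    counts = np.bincount(np.asarray(y).astype(int), minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"cannot stratify {k} folds with class counts {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cross_validate(config: PipelineConfig, X, y, k: int = 5, seed: int = 0,
                   _folds=None, _fold_stats=None):
    """Stratified k-fold CV of one configuration; returns (mean AUC,
    fold AUCs).  Preprocessing is refitted inside every fold; a fold whose
    selection leaves no features scores 0.5.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    folds = _folds if _folds is not None else _stratified_folds(y, k, seed)
    aucs = []
    for f, (tr, te) in enumerate(folds):
        stats = _fold_stats[f] if _fold_stats is not None else None
        prep = RadiomicsPreprocessor(config.fpr_alpha, config.fwer_alpha,
                                     config.pca_var_fraction)
        prep.fit(X[tr], y[tr], _stats=stats)
        if prep.failed:
            aucs.append(0.5)
            continue
        model = _make_model(config, n_train=len(tr))
        with warnings.catch_warnings():
            # the iteration cap is part of the sampled configuration
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(prep.transform(X[tr]), y[tr])
        scores = _model_scores(model, prep.transform(X[te]))
        aucs.append(float(roc_auc_score(y[te], scores)))
    return float(np.mean(aucs)), aucs


@dataclass
class SearchResult:
    """Outcome of the randomized search."""

    log: pd.DataFrame
    best_per_family: dict
    best_config: PipelineConfig
    best_mean_auc: float
    fitted: FittedPipeline
    configs: list = field(default_factory=list)


def run_search(X, y, iterations: int, seed: int, k: int = 5) -> SearchResult:
    """Randomized search: ``iterations`` configurations per family, each
    scored by mean stratified 5-fold CV AUC on the training set; the overall
    best (ties broken by evaluation order) is refitted on the full training
    set.

    One fold partition, derived from ``seed``, is shared by all
    configurations so their CV scores are directly comparable; the per-fold
    column statistics (which do not depend on sampled hyperparameters) are
    computed once.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    ss = np.random.SeedSequence(seed)
    fold_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
    folds = _stratified_folds(y, k, fold_seed)
    fold_stats = [_ColumnStats(X[tr], y[tr]) for tr, _ in folds]

    rows = []
    configs = []
    best_per_family: dict[str, dict] = {}
    best_config = None
    best_auc = -np.inf
    family_rngs = {fam: np.random.default_rng(s)
                   for fam, s in zip(FAMILIES, ss.spawn(len(FAMILIES)))}
    for iteration in range(iterations):
        for family in FAMILIES:
            config = sample_config(family, family_rngs[family])
            mean_auc, fold_aucs = cross_validate(
                config, X, y, k=k, _folds=folds, _fold_stats=fold_stats)
            row = {"family": family, "iteration": iteration,
                   "mean_cv_auc": mean_auc,
                   **{f"fold{j}_auc": a for j, a in enumerate(fold_aucs)},
                   "fpr_alpha": config.fpr_alpha,
                   "fwer_alpha": config.fwer_alpha,
                   "pca_var_fraction": config.pca_var_fraction,
                   "family_params": repr(config.family_params)}
            rows.append(row)
            configs.append(config)
            fam_best = best_per_family.get(family)
            if fam_best is None or mean_auc > fam_best["mean_cv_auc"]:
                best_per_family[family] = {"config": config,
                                           "mean_cv_auc": mean_auc}
            if mean_auc > best_auc:
                best_auc = mean_auc
                best_config = config
    prep = preprocess_fit(X, y, best_config)
    if prep.failed:
        raise RuntimeError("best configuration failed preprocessing on the "
                           "full training set")
    model = _make_model(best_config, n_train=len(y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(prep.transform(X), y)
    fitted = FittedPipeline(preprocessor=prep, model=model, config=best_config)
    return SearchResult(log=pd.DataFrame(rows), best_per_family=best_per_family,
                        best_config=best_config, best_mean_auc=float(best_auc),
                        fitted=fitted, configs=configs)


def evaluate_validation(fitted: FittedPipeline, X_validation, y_validation,
                        ) -> ROCResult:
    """Score held-out rows with the fitted pipeline and return the AUC with
    DeLong variance and 95% CI."""
    scores = fitted.predict_scores(X_validation)
    return auc_delong(scores, y_validation)
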