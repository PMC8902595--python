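"""Region-wise "virtual lesion" evaluation and biomarker selection.

Each candidate region identified by the searchlight is evaluated on its
own: its voxels form the feature matrix for three classifier families
(PCA+Ridge, PCA+SVM, Bagging of decision trees), with hyperparameters
tuned by randomized search on inner cross-validation folds, performance
estimated by repeated nested cross-validation (and optionally by
training on one site and testing on held-out sites), significance
assessed by a label-permutation test, and a final stability ruling:
a region is kept as a biomarker only if its sensitivity/specificity gap
is within 20 percentage points AND its permutation p is below 0.05.

ASD is the positive class everywhere: sensitivity = ASD detection rate,
specificity = TDC rejection rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import RidgeClassifier
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from ._utils import derive_seed
from .exceptions import (DegenerateTrainingError, InvalidDesignError,
                         MetricError)
from .searchlight import (RegionFeatureSet, pca_fit_transform, svm_decision,
                          svm_fit)
from .volio import Cohort

FAMILIES = ("pca_ridge", "pca_svm", "bagging")


@dataclass(frozen=True)
class ModelConfig:
    """One concrete classifier configuration."""

    family: str
    variance_frac: float = 0.8      # PCA families
    C: float = 1.0                  # pca_svm
    alpha: float = 1.0              # pca_ridge
    n_estimators: int = 10          # bagging
    max_samples_frac: float = 1.0
    max_features_frac: float = 1.0
    bootstrap: bool = True          # rows with replacement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.C <= 0 or self.alpha <= 0:
            raise ValueError("C and alpha must be positive")
        if not (0 < self.variance_frac <= 1):
            raise ValueError("variance_frac must be in (0, 1]")
        if not (0 < self.max_samples_frac <= 1 and 0 < self.max_features_frac <= 1):
            raise ValueError("sampling fractions must be in (0, 1]")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")


@dataclass(frozen=True)
class SearchSpace:
    """Hyperparameter search space.

    The PCA variance grid is enumerated; C/alpha are log-uniform over
    [1e-10, 1e10]; the bagging estimator count is an integer in [3, 30]
    and both sampling fractions uniform on [0.5, 1].
    """

    variance_grid: tuple[float, ...] = (0.6, 0.7, 0.8, 0.9, 0.99)
    log_penalty_bounds: tuple[float, float] = (1e-10, 1e10)
    n_estimators_bounds: tuple[int, int] = (3, 30)
    frac_bounds: tuple[float, float] = (0.5, 1.0)

    def sample(self, family: str, rng: np.random.Generator,
               model_seed: int) -> ModelConfig:
        if family in ("pca_ridge", "pca_svm"):
            vf = float(rng.choice(self.variance_grid))
            lo, hi = np.log10(self.log_penalty_bounds)
            penalty = float(10.0 ** rng.uniform(lo, hi))
            if family == "pca_svm":
                return ModelConfig(family=family, variance_frac=vf, C=penalty,
                                   seed=model_seed)
            return ModelConfig(family=family, variance_frac=vf, alpha=penalty,
                               seed=model_seed)
        if family == "bagging":
            lo_n, hi_n = self.n_estimators_bounds
            lo_f, hi_f = self.frac_bounds
            return ModelConfig(
                family=family,
                n_estimators=int(rng.integers(lo_n, hi_n + 1)),
                max_samples_frac=float(rng.uniform(lo_f, hi_f)),
                max_features_frac=float(rng.uniform(lo_f, hi_f)),
                seed=model_seed)
        raise ValueError(f"unknown family {family!r}")


@dataclass
class Metrics:
    acc: float                  # percent
    sen: float                  # percent, ASD positive
    spe: float                  # percent
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray


@dataclass
class EvalResult:
    region: str
    family: str
    setting: str                # "nested_cv" | "multisite" | ...
    acc: float
    sen: float
    spe: float
    auc: float
    per_repeat: list[Metrics] = field(default_factory=list)
    chosen_configs: list[ModelConfig] = field(default_factory=list)
    extras: dict = field(default_factory=dict)


@dataclass
class PermutationResult:
    region: str
    family: str
    observed: float
    null: np.ndarray
    n_perm: int

    @property
    def p(self) -> float:
        """Exceedance fraction: share of null accuracies >= observed."""
        return float((self.null >= self.observed).sum()) / self.n_perm

    def p_text(self) -> str:
        return f"< {1.0 / self.n_perm:g}" if self.p == 0 else f"{self.p:g}"


@dataclass
class BiomarkerDecision:
    region: str
    family: str
    balanced: bool
    significant: bool
    included: bool
    max_gap: float
    p: float


# ---------------------------------------------------------------------------
# Features and models


def extract_region_features(cohort: Cohort, region_set: RegionFeatureSet,
                            region: str) -> tuple[np.ndarray, np.ndarray]:
    """(subjects x region-voxels) matrix and ±1 labels, cohort order."""
    if region not in region_set.regions:
        raise InvalidDesignError(f"unknown region {region!r}")
    idx = np.asarray(region_set.regions[region])
    if idx.size == 0:
        raise InvalidDesignError(f"region {region!r} has no voxels")
    X = cohort.volumes.reshape(cohort.n_subjects, -1)[:, idx]
    return X, cohort.labels()


def fit_predict(config: ModelConfig, X_train: np.ndarray, y_train: np.ndarray,
                X_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fit one configured model and predict the test set.

    Returns (labels in {-1,+1}, decision scores).  Scores: signed
    distance for the linear families, mean positive-class vote for
    bagging (centered at 0 by subtracting 0.5 so >0 means ASD).
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise DegenerateTrainingError("training labels contain a single class")
    if X_test.shape[1] != X_train.shape[1]:
        raise InvalidDesignError(
            f"test features {X_test.shape[1]} != train features {X_train.shape[1]}")

    if config.family in ("pca_ridge", "pca_svm"):
        F_tr, F_te, _ = pca_fit_transform(X_train, X_test, config.variance_frac)
        if config.family == "pca_svm":
            model = svm_fit(F_tr, y_train, C=config.C)
            scores = svm_decision(model, F_te)
        else:
            ridge = RidgeClassifier(alpha=config.alpha)
            ridge.fit(F_tr, y_train)
            scores = ridge.decision_function(F_te)
        return np.where(scores > 0, 1, -1).astype(np.int64), scores

    bag = BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=config.seed),
        n_estimators=config.n_estimators,
        max_samples=config.max_samples_frac,
        max_features=config.max_features_frac,
        bootstrap=config.bootstrap,
        bootstrap_features=False,
        random_state=config.seed)
    bag.fit(X_train, y_train)
    pos = list(bag.classes_).index(1)
    vote = bag.predict_proba(X_test)[:, pos]     # mean estimator vote
    scores = vote - 0.5
    return np.where(scores > 0, 1, -1).astype(np.int64), scores


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    scores: np.ndarray) -> Metrics:
    """ACC/SEN/SPE (percent, ASD=+1 positive), ROC and trapezoid AUC."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(np.unique(y_true)) < 2:
        raise MetricError("metrics undefined: true labels contain one class")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == -1)).sum())
    tn = int(((y_true == -1) & (y_pred == -1)).sum())
    fp = int(((y_true == -1) & (y_pred == 1)).sum())
    acc = 100.0 * (tp + tn) / len(y_true)
    sen = 100.0 * tp / (tp + fn)
    spe = 100.0 * tn / (tn + fp)
    fpr, tpr, _ = roc_curve(y_true, scores, pos_label=1)
    return Metrics(acc=acc, sen=sen, spe=spe, auc=float(_auc(fpr, tpr)),
                   roc_fpr=fpr, roc_tpr=tpr)


# ---------------------------------------------------------------------------
# Hyperparameter tuning and nested CV


def _cv_accuracy(X: np.ndarray, y: np.ndarray, config: ModelConfig,
                 n_folds: int, seed: int) -> float:
    """Pooled stratified k-fold CV accuracy for one config."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    correct = 0
    for tr, te in skf.split(X, y):
        pred, _ = fit_predict(config, X[tr], y[tr], X[te])
        correct += int((pred == y[te]).sum())
    return correct / len(y)


def tune_hyperparameters(X: np.ndarray, y: np.ndarray, family: str,
                         space: SearchSpace | None = None, budget: int = 30,
                         inner_folds: int = 5, seed: int = 0) -> ModelConfig:
    """Randomized search: best inner-CV accuracy wins, ties -> first tried."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    space = space or SearchSpace()
    rng = np.random.default_rng(seed)
    best_config, best_score = None, -np.inf
    for trial in range(budget):
        config = space.sample(family, rng, model_seed=derive_seed(seed, "model", trial))
        score = _cv_accuracy(X, y, config, inner_folds, derive_seed(seed, "inner"))
        if score > best_score:
            best_config, best_score = config, score
    return best_config


def nested_cv_evaluate(X: np.ndarray, y: np.ndarray, family: str,
                       space: SearchSpace | None = None, outer_folds: int = 5,
                       n_repeats: int = 10, budget: int = 30,
                       inner_folds: int = 5, seed: int = 0,
                       region: str = "", ) -> EvalResult:
    """Repeated stratified nested cross-validation.

    Outer folds estimate generalization; the hyperparameter search runs
    on each outer-training portion only and never sees held-out data.
    Predictions are pooled over outer folds within a repeat; metrics are
    averaged over repeats.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    for cls in (-1, 1):
        if (y == cls).sum() < outer_folds:
            raise DegenerateTrainingError(
                f"class {cls} has fewer than outer_folds={outer_folds} members")
    space = space or SearchSpace()

    per_repeat: list[Metrics] = []
    chosen: list[ModelConfig] = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=outer_folds, shuffle=True,
                              random_state=derive_seed(seed, "outer", rep))
        y_true = np.empty_like(y)
        y_pred = np.empty_like(y)
        y_score = np.empty(len(y), dtype=np.float64)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            config = tune_hyperparameters(
                X[tr], y[tr], family, space, budget=budget,
                inner_folds=inner_folds, seed=derive_seed(seed, "tune", rep, fold))
            pred, scores = fit_predict(config, X[tr], y[tr], X[te])
            y_true[te] = y[te]
            y_pred[te] = pred
            y_score[te] = scores
            chosen.append(config)
        per_repeat.append(compute_metrics(y_true, y_pred, y_score))

    return EvalResult(
        region=region, family=family, setting="nested_cv",
        acc=float(np.mean([m.acc for m in per_repeat])),
        sen=float(np.mean([m.sen for m in per_repeat])),
        spe=float(np.mean([m.spe for m in per_repeat])),
        auc=float(np.mean([m.auc for m in per_repeat])),
        per_repeat=per_repeat, chosen_configs=chosen)


def multisite_evaluate(train_cohort: Cohort, test_cohorts: Sequence[Cohort],
                       region_set: RegionFeatureSet, region: str, family: str,
                       space: SearchSpace | None = None, budget: int = 30,
                       inner_folds: int = 5, seed: int = 0) -> EvalResult:
    """Train (with inner-CV tuning) on one site, test on held-out sites.

    Test cohorts are pooled for the headline metrics; per-site metrics
    are kept in ``extras["per_site"]`` where each site has both classes.
    """
    if not test_cohorts:
        raise InvalidDesignError("no test cohorts provided")
    for tc in test_cohorts:
        if tc.grid_shape != train_cohort.grid_shape:
            raise InvalidDesignError("test cohort grid does not match training grid")

    X_tr, y_tr = extract_region_features(train_cohort, region_set, region)
    config = tune_hyperparameters(X_tr, y_tr, family, space, budget=budget,
                                  inner_folds=inner_folds,
                                  seed=derive_seed(seed, "tune", region, family))

    tests = [extract_region_features(tc, region_set, region) for tc in test_cohorts]
    X_te = np.vstack([t[0] for t in tests])
    y_te = np.concatenate([t[1] for t in tests])
    pred, scores = fit_predict(config, X_tr, y_tr, X_te)
    pooled = compute_metrics(y_te, pred, scores)

    per_site = {}
    start = 0
    for tc, (Xs, ys) in zip(test_cohorts, tests):
        stop = start + len(ys)
        if len(np.unique(ys)) == 2:
            site = str(tc.phenotype["site"].iloc[0])
            per_site[site] = compute_metrics(ys, pred[start:stop], scores[start:stop])
        start = stop

    return EvalResult(region=region, family=family, setting="multisite",
                      acc=pooled.acc, sen=pooled.sen, spe=pooled.spe,
                      auc=pooled.auc, per_repeat=[pooled],
                      chosen_configs=[config],
                      extras={"per_site": per_site})


# ---------------------------------------------------------------------------
# Permutation test and stability selection


def permutation_test(X: np.ndarray, y: np.ndarray, family: str,
                     config: ModelConfig, n_perm: int = 5000,
                     cv_folds: int = 5, seed: int = 0,
                     region: str = "") -> PermutationResult:
    """Label-permutation significance of the CV accuracy.

    The observed accuracy is the stratified ``cv_folds``-fold CV
    accuracy on the true labels with the given (frozen) configuration;
    each permutation redraws the labels and repeats the identical fold
    procedure.  p is the fraction of null accuracies >= observed
    (an exceedance count, so p = 0 is possible and is reported in text
    as "< 1/n_perm").
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    observed = _cv_accuracy(X, y, config, cv_folds, derive_seed(seed, "obs"))
    rng = np.random.default_rng(derive_seed(seed, "perm"))
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        null[i] = _cv_accuracy(X, y_perm, config, cv_folds,
                               derive_seed(seed, "perm-fold", i))
    return PermutationResult(region=region, family=family,
                             observed=float(observed), null=null, n_perm=n_perm)


def select_biomarkers(evals: Sequence[EvalResult],
                      perms: Sequence[PermutationResult],
                      gap_threshold: float = 20.0,
                      alpha: float = 0.05) -> list[BiomarkerDecision]:
    """Stability ruling per region.

    For each region the best family is the one with the highest
    nested-CV accuracy (highest accuracy overall if no nested-CV entry
    exists).  The region is included iff, for that family, every
    provided evaluation setting has |SEN - SPE| <= gap_threshold
    percentage points AND the permutation p is < alpha.
    """
    perm_by_key = {(p.region, p.family): p for p in perms}
    by_region: dict[str, list[EvalResult]] = {}
    for ev in evals:
        by_region.setdefault(ev.region, []).append(ev)

    decisions = []
    for region, region_evals in by_region.items():
        primary = [e for e in region_evals if e.setting == "nested_cv"] or region_evals
        best = max(primary, key=lambda e: e.acc)
        family_evals = [e for e in region_evals if e.family == best.family]
        gaps = [abs(e.sen - e.spe) for e in family_evals]
        balanced = all(g <= gap_threshold for g in gaps)
        key = (region, best.family)
        if key not in perm_by_key:
            raise InvalidDesignError(
                f"missing permutation result for region {region!r} "
                f"family {best.family!r}")
        p = perm_by_key[key].p
        significant = p < alpha
        decisions.append(BiomarkerDecision(
            region=region, family=best.family, balanced=balanced,
            significant=significant, included=balanced and significant,
            max_gap=float(max(gaps)), p=p))
    return decisions
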