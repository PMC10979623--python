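"""Validation protocol: tuned gradient-boosted classifiers on repeatedly
re-balanced training data, scored by auroc on a held-out validation set.

For each balancing method the training set is regenerated ``n_iterations``
times (fresh randomness each time), a histogram gradient-boosted classifier
is fitted with hyperparameters tuned once by stratified 5-fold CV, and the
validation auroc recorded.  Methods are compared pairwise with Welch's
unequal-variance t-test, adjusting across the pair family by
Benjamini-Hochberg.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .balancing import BalancePlan, apply_balancing
from .simulate import LabeledMatrix

__all__ = [
    "ClassifierGrid", "ValidationReport", "MethodComparison",
    "tune_classifier", "evaluate_balancing", "compare_methods",
    "select_alpha_combination",
]


@dataclass
class ClassifierGrid:
    """Hyperparameter grid for the gradient-boosted classifier."""

    learning_rates: tuple = (1e-4, 1e-3, 1e-2, 1.0, 10.0)
    min_samples_leaf: tuple = (1, 10, 25, 50, 75)
    folds: int = 5

    def __post_init__(self):
        if not self.learning_rates or not self.min_samples_leaf:
            raise ValueError("grids must be non-empty")

    def cells(self):
        return [{"learning_rate": lr, "min_samples_leaf": msl}
                for lr, msl in itertools.product(self.learning_rates,
                                                 self.min_samples_leaf)]


def tune_classifier(train: LabeledMatrix, grid: ClassifierGrid = None,
                    seed: int = 0) -> dict:
    """Grid search by stratified CV auroc; ties keep the first grid cell.

    Folds are reduced (with a warning) when the rarer class cannot fill them.
    """
    grid = grid or ClassifierGrid()
    if train.labels is None:
        raise ValueError("training data must be labeled")
    y = train.labels
    min_class = np.bincount(y).min()
    folds = grid.folds
    if min_class < folds:
        if min_class < 2:
            raise ValueError("each class needs at least 2 samples to stratify")
        folds = min_class
        warnings.warn(f"reducing CV folds to {folds} (small class)")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(train.values, y))
    best_params, best_score = None, -np.inf
    for params in grid.cells():
        scores = []
        for tr, te in splits:
            clf = HistGradientBoostingClassifier(random_state=seed, **params)
            clf.fit(train.values[tr], y[tr])
            scores.append(roc_auc_score(y[te], clf.predict_proba(train.values[te])[:, 1]))
        mean = float(np.mean(scores))
        if mean > best_score:  # strict: ties keep the earlier cell
            best_params, best_score = params, mean
    return {**best_params, "cv_auroc": best_score}


@dataclass
class ValidationReport:
    """Per-method auroc summary over the balancing iterations."""

    method: str
    scores: np.ndarray
    alpha_combination: tuple | None = None
    n_failures: int = 0

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("auroc values must lie in [0, 1]")

    @property
    def mean_auroc(self) -> float:
        return float(self.scores.mean())

    @property
    def sd_auroc(self) -> float:
        return float(self.scores.std(ddof=1)) if len(self.scores) > 1 else 0.0

    @property
    def auc_diff(self) -> float:
        return self.mean_auroc - 0.5

    def summary(self) -> str:
        alpha = ("" if self.alpha_combination is None
                 else f"  alpha={self.alpha_combination}")
        return (f"{self.method}: mean auroc {self.mean_auroc:.3f} "
                f"(sd {self.sd_auroc:.3f}, AUC diff {self.auc_diff:+.3f}, "
                f"n={len(self.scores)}){alpha}")


def evaluate_balancing(real: LabeledMatrix, validation: LabeledMatrix,
                       method: str, gans=None, params: dict | None = None,
                       n_iterations: int = 100, seed: int = 0,
                       multiplier: float = 1.0,
                       max_failure_fraction: float = 0.1) -> ValidationReport:
    """Repeatedly re-balance, refit and score on the validation split."""
    if validation.labels is None:
        raise ValueError("validation data must be labeled")
    params = dict(params or {})
    params.pop("cv_auroc", None)
    ss = np.random.SeedSequence(seed)
    scores, failures = [], 0
    for i, child in enumerate(ss.spawn(n_iterations)):
        sub = child.generate_state(2)
        try:
            plan = BalancePlan(method, multiplier=multiplier,
                               seed=int(sub[0] % (2 ** 31 - 1)))
            balanced = apply_balancing(real, plan, gans)
            clf = HistGradientBoostingClassifier(
                random_state=int(sub[1] % (2 ** 31 - 1)), **params)
            clf.fit(balanced.values, balanced.labels)
            proba = clf.predict_proba(validation.values)[:, 1]
            scores.append(roc_auc_score(validation.labels, proba))
        except (ValueError, FloatingPointError) as err:
            failures += 1
            warnings.warn(f"iteration {i} failed: {err}")
    if failures > max_failure_fraction * n_iterations:
        raise RuntimeError(f"{failures}/{n_iterations} balancing iterations failed")
    return ValidationReport(method, np.array(scores), n_failures=failures)


@dataclass
class MethodComparison:
    """Pairwise Welch tests with Benjamini-Hochberg adjustment."""

    table: pd.DataFrame

    def __post_init__(self):
        raw = self.table["p_value"].to_numpy()
        adj = self.table["p_adjusted"].to_numpy()
        if np.any(adj + 1e-12 < raw):
            raise ValueError("adjusted p-values cannot undercut raw p-values")


def _welch(a: np.ndarray, b: np.ndarray):
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            warnings.warn("zero variance in both samples with equal means; p = 1")
            return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def compare_methods(reports: list) -> MethodComparison:
    """All pairwise Welch two-sided t-tests on per-iteration auroc vectors."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    rows = []
    for r1, r2 in itertools.combinations(reports, 2):
        t, p = _welch(r1.scores, r2.scores)
        rows.append({"method_a": r1.method, "method_b": r2.method,
                     "mean_a": r1.mean_auroc, "mean_b": r2.mean_auroc,
                     "t_statistic": t, "p_value": p})
    table = pd.DataFrame(rows)
    _, adj, _, _ = multipletests(table["p_value"], method="fdr_bh")
    table["p_adjusted"] = adj
    table["significant"] = table["p_adjusted"] < 0.05
    return MethodComparison(table)


def select_alpha_combination(reports: dict) -> ValidationReport:
    """Best report by mean auroc; ties prefer lower alpha values."""
    if not reports:
        raise ValueError("no reports given")
    best = max(sorted(reports), key=lambda k: (reports[k].mean_auroc,
                                               tuple(-a for a in k)))
    report = reports[best]
    report.alpha_combination = best
    return report
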