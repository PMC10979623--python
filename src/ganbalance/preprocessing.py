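"""Per-feature scaling, feature filtering and stability feature selection.

Each feature is assigned one of two scalers by a two-sided D'Agostino
skewness test against normality: significantly skewed features get a
Yeo-Johnson power transform (maximum-likelihood lambda, then standardise),
the rest a robust (median/IQR) scaling.  Two fitted transformers are used in
the pipeline: one fitted on a 200-row subsample of the external data (for
pre-training) and one fitted on all rows of the real data (for re-training).

Stability selection repeatedly refits L1 (LASSO) and elastic-net logistic
models on random 75% splits, tuning each penalty by inner cross-validation,
and keeps the features that land in the top quartile of the appearance
frequency ranking under *both* penalties.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.preprocessing import PowerTransformer, RobustScaler, StandardScaler

from .simulate import LabeledMatrix

__all__ = [
    "ScalerPlan", "FittedTransformer", "SelectionResult",
    "choose_feature_transforms", "fit_transformer",
    "filter_top_features", "stability_select",
]

POWER = "power_transform"
ROBUST = "robust_scale"
STANDARD = "standard_scale"

# Yeo-Johnson images are one-sided-bounded for lambda outside [0, 2]; inverse
# transforming arbitrary (e.g. GAN-generated) values needs the input pulled
# into the open domain.  The margin keeps the inverse finite and bounded.
_YJ_DOMAIN_MARGIN = 1e-3


def _yj_domain_clip(y: np.ndarray, lmbda: float) -> np.ndarray:
    """Clip values into the invertible image of the Yeo-Johnson transform.

    The image is [0, -1/lmbda) on the positive branch when lmbda < 0, and
    (1/(2-lmbda), 0] on the negative branch when lmbda > 2; otherwise each
    branch is unbounded.
    """
    lo, hi = -np.inf, np.inf
    if lmbda < 0:
        hi = -1.0 / lmbda - _YJ_DOMAIN_MARGIN
    if lmbda > 2:
        lo = 1.0 / (2.0 - lmbda) + _YJ_DOMAIN_MARGIN
    return np.clip(y, min(lo, 0.0), max(hi, 0.0))


@dataclass
class ScalerPlan:
    """Per-feature scaler assignment driven by the skewness test."""

    assignments: list
    p_values: np.ndarray
    alpha: float = 0.05
    constant_features: list = field(default_factory=list)

    def __post_init__(self):
        self.p_values = np.asarray(self.p_values, dtype=float)
        if len(self.assignments) != len(self.p_values):
            raise ValueError("one assignment per feature required")

    @property
    def n_features(self) -> int:
        return len(self.assignments)


def choose_feature_transforms(matrix, alpha: float = 0.05,
                              nonskew_scaler: str = ROBUST) -> ScalerPlan:
    """Assign a scaler to each feature: power transform iff the skewness test
    rejects normality at level ``alpha``.

    Constant features (skewness undefined) are assigned the non-skew scaler
    and flagged rather than dropped.
    """
    values = matrix.values if isinstance(matrix, LabeledMatrix) else np.asarray(matrix)
    if values.shape[0] < 8:
        raise ValueError("the skewness test needs at least 8 samples")
    if nonskew_scaler not in (ROBUST, STANDARD):
        raise ValueError(f"unknown nonskew_scaler {nonskew_scaler!r}")
    assignments, pvals, constant = [], [], []
    for j in range(values.shape[1]):
        col = values[:, j]
        if np.ptp(col) == 0.0:
            constant.append(j)
            pvals.append(np.nan)
            assignments.append(nonskew_scaler)
            continue
        p = float(stats.skewtest(col).pvalue)
        pvals.append(p)
        assignments.append(POWER if p < alpha else nonskew_scaler)
    if constant:
        warnings.warn(f"{len(constant)} constant feature(s); assigned {nonskew_scaler}")
    return ScalerPlan(assignments, np.array(pvals), alpha, constant)


class FittedTransformer:
    """Columnwise transformer realising a :class:`ScalerPlan`.

    Skewed columns go through a Yeo-Johnson power transform (with
    standardisation), the rest through the plan's non-skew scaler.  Column
    order is preserved on both transform and inverse transform.
    """

    def __init__(self, plan: ScalerPlan):
        self.plan = plan
        self._groups: dict = {}
        self.fingerprint: str | None = None

    def fit(self, values: np.ndarray, n_fit_samples: int | None = None,
            rng: np.random.Generator | None = None) -> "FittedTransformer":
        values = np.asarray(values, dtype=float)
        if values.shape[1] != self.plan.n_features:
            raise ValueError("plan does not cover this feature set")
        if n_fit_samples is not None:
            if n_fit_samples > values.shape[0]:
                raise ValueError("n_fit_samples exceeds the available rows")
            rng = rng or np.random.default_rng()
            idx = rng.choice(values.shape[0], size=n_fit_samples, replace=False)
            fit_values = values[idx]
        else:
            fit_values = values
        self.fingerprint = hashlib.sha256(
            np.ascontiguousarray(fit_values).tobytes()).hexdigest()

        assignments = np.array(self.plan.assignments)
        self._groups = {}
        for kind in (POWER, ROBUST, STANDARD):
            cols = np.where(assignments == kind)[0]
            if len(cols) == 0:
                continue
            if kind == POWER:
                # separate standardisation step so the inverse path can clip
                # into the Yeo-Johnson domain between the two stages
                pt = PowerTransformer(method="yeo-johnson", standardize=False)
                sc = StandardScaler()
                sc.fit(pt.fit_transform(fit_values[:, cols]))
                self._groups[kind] = (cols, (pt, sc))
                continue
            elif kind == ROBUST:
                sub = fit_values[:, cols]
                iqr = np.subtract(*np.percentile(sub, [75, 25], axis=0))
                if np.any(iqr == 0):
                    warnings.warn("zero IQR in robust-scaled feature(s); "
                                  "falling back to unit scale")
                est = RobustScaler()
            else:
                est = StandardScaler()
            est.fit(fit_values[:, cols])
            self._groups[kind] = (cols, est)
        return self

    def _check_fitted(self):
        if not self._groups:
            raise ValueError("transformer is not fitted")

    def transform(self, values: np.ndarray) -> np.ndarray:
        self._check_fitted()
        values = np.asarray(values, dtype=float)
        out = np.empty_like(values)
        for kind, (cols, est) in self._groups.items():
            if kind == POWER:
                pt, sc = est
                out[:, cols] = sc.transform(pt.transform(values[:, cols]))
            else:
                out[:, cols] = est.transform(values[:, cols])
        return out

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        self._check_fitted()
        values = np.asarray(values, dtype=float)
        out = np.empty_like(values)
        for kind, (cols, est) in self._groups.items():
            if kind == POWER:
                pt, sc = est
                y = sc.inverse_transform(values[:, cols])
                for j, lmbda in enumerate(pt.lambdas_):
                    y[:, j] = _yj_domain_clip(y[:, j], lmbda)
                out[:, cols] = pt.inverse_transform(y)
            else:
                out[:, cols] = est.inverse_transform(values[:, cols])
        return out

    def to_dict(self) -> dict:
        """JSON-serialisable parameters (for the sidecar file)."""
        self._check_fitted()
        payload = {"alpha": self.plan.alpha, "fingerprint": self.fingerprint,
                   "assignments": list(self.plan.assignments),
                   "p_values": [None if np.isnan(p) else float(p)
                                for p in self.plan.p_values],
                   "groups": {}}
        for kind, (cols, est) in self._groups.items():
            entry = {"columns": cols.tolist()}
            if kind == POWER:
                pt, sc = est
                entry.update(lambdas=pt.lambdas_.tolist(),
                             mean=sc.mean_.tolist(),
                             scale=sc.scale_.tolist())
            elif kind == ROBUST:
                entry.update(center=est.center_.tolist(), scale=est.scale_.tolist())
            else:
                entry.update(mean=est.mean_.tolist(), scale=est.scale_.tolist())
            payload["groups"][kind] = entry
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "FittedTransformer":
        """Rebuild a fitted transformer from :meth:`to_dict` output."""
        pvals = np.array([np.nan if p is None else p for p in payload["p_values"]])
        plan = ScalerPlan(list(payload["assignments"]), pvals, payload["alpha"])
        self = cls(plan)
        self.fingerprint = payload.get("fingerprint")
        for kind, entry in payload["groups"].items():
            cols = np.asarray(entry["columns"], dtype=int)
            p = len(cols)
            if kind == POWER:
                pt = PowerTransformer(method="yeo-johnson", standardize=False)
                pt.lambdas_ = np.asarray(entry["lambdas"], dtype=float)
                pt.n_features_in_ = p
                sc = StandardScaler()
                sc.mean_ = np.asarray(entry["mean"], dtype=float)
                sc.scale_ = np.asarray(entry["scale"], dtype=float)
                sc.var_ = sc.scale_ ** 2
                sc.n_features_in_ = p
                sc.n_samples_seen_ = p
                self._groups[kind] = (cols, (pt, sc))
            elif kind == ROBUST:
                est = RobustScaler()
                est.center_ = np.asarray(entry["center"], dtype=float)
                est.scale_ = np.asarray(entry["scale"], dtype=float)
                est.n_features_in_ = p
                self._groups[kind] = (cols, est)
            else:
                est = StandardScaler()
                est.mean_ = np.asarray(entry["mean"], dtype=float)
                est.scale_ = np.asarray(entry["scale"], dtype=float)
                est.var_ = est.scale_ ** 2
                est.n_features_in_ = p
                est.n_samples_seen_ = p
                self._groups[kind] = (cols, est)
        return self


def fit_transformer(matrix, plan: ScalerPlan, n_fit_samples: int | None = None,
                    rng: np.random.Generator | None = None) -> FittedTransformer:
    """Fit the columnwise transformer; the external transformer passes
    ``n_fit_samples=200``, the real transformer fits on all rows."""
    values = matrix.values if isinstance(matrix, LabeledMatrix) else np.asarray(matrix)
    return FittedTransformer(plan).fit(values, n_fit_samples, rng)


def filter_top_features(feature_table, k: int, missing_features=()) -> list:
    """Keep the ``k`` most significant features (smallest adjusted p), then
    drop any feature with a missing value in any of the provided datasets.

    ``feature_table`` is a DataFrame with columns ``feature`` and ``adj_p``;
    ties in ``adj_p`` break by feature name for determinism.
    """
    table = feature_table.sort_values(["adj_p", "feature"], kind="mergesort")
    if k > len(table):
        warnings.warn(f"k={k} exceeds the {len(table)} available features; taking all")
        k = len(table)
    top = table.head(k)["feature"].tolist()
    missing = set(missing_features)
    return [f for f in top if f not in missing]


@dataclass
class SelectionResult:
    selected: list
    lasso_frequency: dict
    en_frequency: dict
    top_fraction: float
    n_iterations: int


def _nonzero_features(model, names) -> set:
    coef = model.coef_.ravel()
    return {names[j] for j in np.where(np.abs(coef) > 1e-12)[0]}


def _top_by_frequency(freq: dict, k: int) -> set:
    ranked = sorted(freq, key=lambda f: (-freq[f], f))
    return set(ranked[:k])


def stability_select(matrix: LabeledMatrix, n_iterations: int = 10,
                     train_fraction: float = 0.75, inner_folds: int = 10,
                     top_fraction: float = 0.25, l1_ratio: float = 0.5,
                     seed: int = 0, max_retries: int = 10) -> SelectionResult:
    """LASSO / elastic-net stability selection.

    Per iteration: a random ``train_fraction`` split; each penalty tuned by
    ``inner_folds``-fold CV on the training part; features with nonzero
    coefficients recorded.  The result is the intersection of the top
    ``top_fraction`` (ceiling) of the two appearance-frequency rankings.
    """
    if matrix.labels is None or len(np.unique(matrix.labels)) != 2:
        raise ValueError("both classes must be present")
    X, y, names = matrix.values, matrix.labels, matrix.feature_names
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    rng = np.random.default_rng(seed)
    n = len(y)
    n_train = int(round(train_fraction * n))
    lasso_freq = {f: 0 for f in names}
    en_freq = {f: 0 for f in names}

    for _ in range(n_iterations):
        for attempt in range(max_retries + 1):
            idx = rng.permutation(n)[:n_train]
            if len(np.unique(y[idx])) == 2 and np.bincount(y[idx]).min() >= inner_folds:
                break
        else:
            raise ValueError("could not draw a training split containing "
                             "enough samples of both classes")
        inner_seed = int(rng.integers(2 ** 31 - 1))
        common = dict(cv=inner_folds, Cs=10, max_iter=5000, solver="saga",
                      scoring="roc_auc", random_state=inner_seed, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lasso = LogisticRegressionCV(penalty="l1", **common)
            lasso.fit(Xs[idx], y[idx])
            en = LogisticRegressionCV(penalty="elasticnet",
                                      l1_ratios=[l1_ratio], **common)
            en.fit(Xs[idx], y[idx])
        for f in _nonzero_features(lasso, names):
            lasso_freq[f] += 1
        for f in _nonzero_features(en, names):
            en_freq[f] += 1

    k = math.ceil(top_fraction * len(names))
    selected = sorted(_top_by_frequency(lasso_freq, k) & _top_by_frequency(en_freq, k))
    return SelectionResult(selected, lasso_freq, en_freq, top_fraction, n_iterations)
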