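"""PLS inference of gestational age with nested cross-validation.

Partial least squares (PLS1) regression projects a wide feature matrix
(e.g. 4,005 connectivity edges for 88 subjects) onto a few latent
components maximally covarying with the response, here GA at birth in
weeks (regression modality) or a 0/1 prematurity label (classification
modality; the model is still a PLS regression on the 0/1 target and ROC
analysis consumes its raw continuous scores — no threshold is applied).

A 10-fold nested cross-validation estimates generalization: the outer
folds produce out-of-fold predictions; within each outer training set an
inner 10-fold CV selects the number of components (1-20) minimizing
mean squared prediction error.  Feature standardization is always
learned on the training portion only.  The final model is a single
full-data fit at the rounded average of the per-fold optimal component
counts, and the statistical relevance of each of its beta-weights is a
bootstrap z-score (subjects resampled with replacement, model refit,
z = mean/SD of the resampled weights).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .panel import FeaturePanel

__all__ = [
    "PlsModel",
    "NcvResult",
    "RocResult",
    "SubgroupComparison",
    "PlsNestedCV",
    "pls_fit",
    "nested_cv",
    "roc_analysis",
    "binarize_ga",
    "bootstrap_beta_z",
    "fisher_z_compare",
    "equalized_subgroup_comparison",
    "shuffled_label_control",
]

logger = logging.getLogger(__name__)

K_HARD_MAX = 20  # hyperparameter search never exceeds 20 components


def _as_xy(X, y):
    if isinstance(X, FeaturePanel):
        x_arr = X.values
        y_arr = X.ga_values if y is None else np.asarray(y, dtype=float)
    else:
        x_arr = np.asarray(X, dtype=float)
        y_arr = np.asarray(y, dtype=float)
    if x_arr.ndim != 2 or y_arr.ndim != 1 or len(y_arr) != x_arr.shape[0]:
        raise ValueError("X must be (n_subjects, n_features) aligned with y")
    return x_arr, y_arr


class PlsModel:
    """Univariate-response PLS with explicit training-set standardization.

    Features are centered and scaled to unit sample SD (parameters
    stored from the training data); the response is centered.  The
    underlying NIPALS components are nested, so ``coef_at(k)`` for any
    k below the fitted order equals a fresh fit with k components —
    nested CV exploits this to score the whole component path from one
    fit per fold.

    Attributes (after fit): ``beta_per_sd_`` (weights per SD of
    feature, comparable across metrics), ``beta_raw_`` (original
    feature units), ``x_mean_``, ``x_std_``, ``y_mean_``.
    """

    def __init__(self, n_components: int):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.n_components = n_components

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PlsModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if np.ptp(y) == 0:
            raise ValueError("constant response: nothing to model")
        k_cap = min(K_HARD_MAX, n - 1, p)
        if self.n_components > k_cap:
            raise ValueError(
                f"n_components={self.n_components} exceeds min(20, n-1, p)={k_cap}")
        self.x_mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.x_std_ = np.where(sd > 0, sd, 1.0)
        self.y_mean_ = float(y.mean())
        xs = (X - self.x_mean_) / self.x_std_
        self._pls = PLSRegression(n_components=self.n_components, scale=False)
        self._pls.fit(xs, y - self.y_mean_)
        self.beta_per_sd_ = self._pls.coef_.reshape(-1)
        self.beta_raw_ = self.beta_per_sd_ / self.x_std_
        return self

    def coef_at(self, k: int) -> np.ndarray:
        """Standardized-space coefficients of the first-k-component submodel."""
        if not 1 <= k <= self.n_components:
            raise ValueError("k out of fitted range")
        w = self._pls.x_weights_[:, :k]
        p_load = self._pls.x_loadings_[:, :k]
        q = self._pls.y_loadings_[:, :k]
        rot = w @ np.linalg.pinv(p_load.T @ w)
        return (rot @ q.T).reshape(-1)

    def predict(self, X: np.ndarray, k: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        xs = (X - self.x_mean_) / self.x_std_
        beta = self.beta_per_sd_ if k is None else self.coef_at(k)
        return xs @ beta + self.y_mean_


def pls_fit(X, y, k: int) -> PlsModel:
    """Fit a k-component PLS model (training-data scaling included)."""
    x_arr, y_arr = _as_xy(X, y)
    return PlsModel(n_components=k).fit(x_arr, y_arr)


@dataclass
class RocResult:
    """ROC analysis of continuous scores against 0/1 labels.

    ``auc`` is the tie-corrected Mann-Whitney statistic / (n1*n2); ``z``
    uses the null normal approximation
    SE0 = sqrt((n1+n2+1)/(12*n1*n2)) and ``p_one_sided = 1 - Phi(z)``.
    """

    auc: float
    z: float
    p_one_sided: float
    fpr: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)


def roc_analysis(scores, labels) -> RocResult:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    y = (labels == classes.max()).astype(int)
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    auc = float(roc_auc_score(y, scores))
    se0 = np.sqrt((n0 + n1 + 1) / (12.0 * n0 * n1))
    z = (auc - 0.5) / se0
    p = float(sp_stats.norm.sf(z))
    fpr, tpr, _ = roc_curve(y, scores)
    return RocResult(auc=auc, z=float(z), p_one_sided=p, fpr=fpr, tpr=tpr)


def binarize_ga(ga_weeks, threshold: float = 32.0) -> np.ndarray:
    """Prematurity label: 0 for GA below threshold, 1 for GA at or above."""
    ga = np.asarray(ga_weeks, dtype=float)
    return (ga >= threshold).astype(int)


@dataclass
class NcvResult:
    """Outputs of one nested-cross-validation run."""

    mode: str
    oof_predictions: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    per_fold_optimal_k: list[int] = field(default_factory=list)
    final_k: int = 1
    performance: dict = field(default_factory=dict)
    roc: RocResult | None = None
    final_beta_per_sd: np.ndarray = field(repr=False, default=None)
    final_beta_raw: np.ndarray = field(repr=False, default=None)
    feature_ids: list[str] | None = None
    n_subjects: int = 0
    beta_z: np.ndarray = field(repr=False, default=None)

    @property
    def r(self) -> float | None:
        return self.performance.get("pearson_r")

    @property
    def auc(self) -> float | None:
        return None if self.roc is None else self.roc.auc

    def score(self) -> float:
        """Headline performance: oof r (regression) or AUC (classification)."""
        return self.r if self.mode == "regression" else self.auc


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


class PlsNestedCV(BaseEstimator):
    """Nested-CV PLS estimator (scikit-learn style).

    Parameters
    ----------
    mode : "regression" or "classification"
        Classification fits PLS regression on 0/1 labels and scores the
        continuous output with ROC analysis.
    k_min, k_max : component search range (capped at 20 and by fold size).
    outer_folds, inner_folds : CV structure (both default to 10).
    random_state : seeds the fold partitions.
    stratify : stratified outer folds (classification only).

    Fitted attributes: ``oof_predictions_``, ``per_fold_optimal_k_``,
    ``final_k_``, ``beta_per_sd_``, ``performance_``, ``roc_``,
    ``result_`` (the full :class:`NcvResult`).
    """

    def __init__(self, mode: str = "regression", k_min: int = 1, k_max: int = 20,
                 outer_folds: int = 10, inner_folds: int = 10,
                 random_state: int | None = None, stratify: bool = False):
        self.mode = mode
        self.k_min = k_min
        self.k_max = k_max
        self.outer_folds = outer_folds
        self.inner_folds = inner_folds
        self.random_state = random_state
        self.stratify = stratify

    def fit(self, X, y=None):
        x_arr, y_arr = _as_xy(X, y)
        n, p = x_arr.shape
        if n < 20:
            raise ValueError("nested CV needs at least 20 subjects")
        if self.mode not in ("regression", "classification"):
            raise ValueError("mode must be 'regression' or 'classification'")
        if self.mode == "classification":
            if not set(np.unique(y_arr)) <= {0.0, 1.0}:
                raise ValueError("classification mode needs 0/1 labels")

        rs = self.random_state
        if self.mode == "classification" and self.stratify:
            outer = StratifiedKFold(self.outer_folds, shuffle=True, random_state=rs)
            splits = list(outer.split(x_arr, y_arr))
        else:
            outer = KFold(self.outer_folds, shuffle=True, random_state=rs)
            splits = list(outer.split(x_arr))

        oof = np.empty(n)
        fold_ks: list[int] = []
        inner_seed = None if rs is None else rs + 1
        for train_idx, test_idx in splits:
            y_tr = y_arr[train_idx]
            if np.ptp(y_tr) == 0:
                raise ValueError("outer training fold has constant response")
            best_k = self._inner_select(x_arr[train_idx], y_tr, inner_seed)
            fold_ks.append(best_k)
            model = PlsModel(best_k).fit(x_arr[train_idx], y_tr)
            oof[test_idx] = model.predict(x_arr[test_idx])

        final_k = _round_half_up(float(np.mean(fold_ks)))
        final_k = max(1, min(final_k, min(K_HARD_MAX, n - 1, p)))
        final_model = PlsModel(final_k).fit(x_arr, y_arr)

        result = NcvResult(
            mode=self.mode, oof_predictions=oof, y=y_arr,
            per_fold_optimal_k=fold_ks, final_k=final_k,
            final_beta_per_sd=final_model.beta_per_sd_,
            final_beta_raw=final_model.beta_raw_,
            feature_ids=(X.feature_ids if isinstance(X, FeaturePanel) else None),
            n_subjects=n,
        )
        if self.mode == "regression":
            r, p_val = sp_stats.pearsonr(oof, y_arr)
            result.performance = {"pearson_r": float(r), "df": n - 2, "p": float(p_val)}
        else:
            result.roc = roc_analysis(oof, y_arr)
            result.performance = {"auc": result.roc.auc, "z": result.roc.z,
                                  "p": result.roc.p_one_sided}

        self.result_ = result
        self.oof_predictions_ = oof
        self.per_fold_optimal_k_ = fold_ks
        self.final_k_ = final_k
        self.final_model_ = final_model
        self.beta_per_sd_ = final_model.beta_per_sd_
        self.performance_ = result.performance
        self.roc_ = result.roc
        return self

    def predict(self, X):
        if isinstance(X, FeaturePanel):
            X = X.values
        return self.final_model_.predict(np.asarray(X, dtype=float))

    def _inner_select(self, x_tr: np.ndarray, y_tr: np.ndarray,
                      seed: int | None) -> int:
        """Inner CV: pick the component count minimizing mean squared error."""
        n_tr, p = x_tr.shape
        inner = KFold(self.inner_folds, shuffle=True, random_state=seed)
        k_caps = []
        sse = None
        for tr, va in inner.split(x_tr):
            if np.ptp(y_tr[tr]) == 0:
                raise ValueError("inner training fold has constant response")
            k_cap = min(K_HARD_MAX, self.k_max, len(tr) - 1, p)
            k_caps.append(k_cap)
            model = PlsModel(k_cap).fit(x_tr[tr], y_tr[tr])
            if sse is None:
                sse = np.zeros(k_cap)
            preds = np.stack([model.predict(x_tr[va], k=k)
                              for k in range(1, min(k_cap, len(sse)) + 1)])
            m = preds.shape[0]
            sse = sse[:m] + ((preds - y_tr[va][None, :]) ** 2).sum(axis=1)
        ks = np.arange(1, len(sse) + 1)
        valid = ks >= self.k_min
        best = ks[valid][int(np.argmin(sse[valid]))]
        return int(best)


def nested_cv(panel: FeaturePanel, mode: str = "regression",
              threshold: float = 32.0, k_min: int = 1, k_max: int = 20,
              outer_folds: int = 10, inner_folds: int = 10,
              seed: int | None = 0, stratify: bool = False) -> NcvResult:
    """Run nested-CV PLS on a feature panel against GA at birth.

    In classification mode the response is the prematurity label from
    :func:`binarize_ga` at ``threshold`` weeks.
    """
    y = panel.ga_values
    if mode == "classification":
        y = binarize_ga(y, threshold=threshold).astype(float)
    est = PlsNestedCV(mode=mode, k_min=k_min, k_max=k_max,
                      outer_folds=outer_folds, inner_folds=inner_folds,
                      random_state=seed, stratify=stratify)
    est.fit(panel, y)
    return est.result_


def bootstrap_beta_z(panel_or_x, y=None, k: int = 1, n_boot: int = 100_000,
                     seed: int = 0) -> np.ndarray:
    """Bootstrap z-scores of PLS beta-weights (per SD of feature).

    Subjects are resampled with replacement and the k-component model
    refit on each resample; z = mean / SD of the resampled weights.
    Resamples with a constant response are redrawn (and counted in the
    log).
    """
    x_arr, y_arr = _as_xy(panel_or_x, y)
    n = len(y_arr)
    rng = np.random.default_rng(seed)
    betas = np.empty((n_boot, x_arr.shape[1]))
    redrawn = 0
    for b in range(n_boot):
        idx = rng.integers(n, size=n)
        while np.ptp(y_arr[idx]) == 0:
            idx = rng.integers(n, size=n)
            redrawn += 1
        betas[b] = PlsModel(k).fit(x_arr[idx], y_arr[idx]).beta_per_sd_
    if redrawn:
        logger.info("bootstrap_beta_z: redrew %d constant-response resamples", redrawn)
    mean = betas.mean(axis=0)
    sd = betas.std(axis=0, ddof=1)
    return np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), 0.0)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sample comparison of correlations on the Fisher-z scale.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); the returned
    p is one-sided, 1 - Phi(|z|).
    """
    if min(n1, n2) <= 3:
        raise ValueError("need n > 3 in both samples")
    if max(abs(r1), abs(r2)) >= 1:
        raise ValueError("requires |r| < 1")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(z), float(sp_stats.norm.sf(abs(z)))


@dataclass
class SubgroupComparison:
    """Feature-subgroup contrast with numerosity equalization.

    The smaller feature group gets one full nested-CV run; the larger
    group is subsampled to the smaller size ``n_repeats`` times (one run
    each) and its performance averaged — correlations on the Fisher-z
    scale and back-transformed, AUCs arithmetically.
    """

    mode: str
    group_small: str
    group_large: str
    n_features_small: int
    n_features_large: int
    perf_small: float
    perf_large_avg: float
    n_repeats_used: int
    z: float
    p_one_sided: float


def equalized_subgroup_comparison(panel: FeaturePanel, partition: dict,
                                  mode: str = "regression", n_repeats: int = 100,
                                  seed: int = 0, n_boot_auc: int = 2000,
                                  **ncv_kwargs) -> SubgroupComparison:
    """Compare nested-CV performance between two feature subgroups.

    ``partition`` maps two group names to boolean masks over the
    panel's features.  Equal-size groups skip subsampling entirely.
    Regression performances are compared with the two-sample Fisher-z
    test; classification performances with a subject-level bootstrap of
    the AUC difference computed from out-of-fold scores (the larger
    group's scores averaged over repeats).
    """
    if len(partition) != 2:
        raise ValueError("partition must contain exactly two groups")
    (name_a, mask_a), (name_b, mask_b) = partition.items()
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each feature group needs at least 2 features")

    if mask_a.sum() <= mask_b.sum():
        small_name, small_mask, large_name, large_mask = name_a, mask_a, name_b, mask_b
    else:
        small_name, small_mask, large_name, large_mask = name_b, mask_b, name_a, mask_a
    n_small = int(small_mask.sum())
    n_large = int(large_mask.sum())

    rng = np.random.default_rng(seed)
    res_small = nested_cv(panel.subset(small_mask, small_name), mode=mode,
                          seed=seed, **ncv_kwargs)

    large_idx = np.flatnonzero(large_mask)
    repeats = 1 if n_large == n_small else n_repeats
    perfs = []
    oof_sum = np.zeros(panel.n_subjects)
    for rep in range(repeats):
        if n_large == n_small:
            sub_mask = large_mask
        else:
            pick = rng.choice(large_idx, size=n_small, replace=False)
            sub_mask = np.zeros(panel.n_features, dtype=bool)
            sub_mask[pick] = True
        res = nested_cv(panel.subset(sub_mask, f"{large_name}_rep{rep}"),
                        mode=mode, seed=seed + rep, **ncv_kwargs)
        perfs.append(res.score())
        oof_sum += res.oof_predictions
    oof_large = oof_sum / repeats

    n_sub = panel.n_subjects
    if mode == "regression":
        perf_large = float(np.tanh(np.mean(np.arctanh(np.clip(perfs, -0.999999, 0.999999)))))
        z, p = fisher_z_compare(res_small.r, n_sub, perf_large, n_sub)
    else:
        perf_large = float(np.mean(perfs))
        labels = res_small.y
        diffs = np.empty(n_boot_auc)
        scores_small = res_small.oof_predictions
        for b in range(n_boot_auc):
            idx = rng.integers(n_sub, size=n_sub)
            while len(np.unique(labels[idx])) < 2:
                idx = rng.integers(n_sub, size=n_sub)
            diffs[b] = (roc_auc_score(labels[idx], scores_small[idx])
                        - roc_auc_score(labels[idx], oof_large[idx]))
        sd = diffs.std(ddof=1)
        z = float(diffs.mean() / sd) if sd > 0 else 0.0
        p = float(sp_stats.norm.sf(abs(z)))

    return SubgroupComparison(
        mode=mode, group_small=small_name, group_large=large_name,
        n_features_small=n_small, n_features_large=n_large,
        perf_small=float(res_small.score()), perf_large_avg=perf_large,
        n_repeats_used=repeats, z=float(z), p_one_sided=float(p))


def shuffled_label_control(panel: FeaturePanel, mode: str = "regression",
                           n_shuffles: int = 20, seed: int = 0,
                           **ncv_kwargs) -> np.ndarray:
    """Null performance distribution from randomly permuted responses.

    Each shuffle permutes GA (or the prematurity labels) across subjects
    and reruns the full nested CV; returns the array of oof r (or AUC)
    values, usable for an empirical permutation p-value.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(panel.n_subjects)
        shuffled = FeaturePanel(
            x=panel.x,
            ga=panel.ga.iloc[perm].set_axis(panel.x.index),
            metric_name=f"{panel.metric_name}:shuffled",
        )
        res = nested_cv(shuffled, mode=mode, seed=seed + 1000 + s, **ncv_kwargs)
        out[s] = res.score()
    return out
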