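"""Mass-univariate association of brain metrics with gestational age.

Each feature (edge or ROI value) is correlated with GA at birth across
subjects: Pearson r, the correlation t-test (t = r * sqrt(df/(1-r^2)),
df = n-2, two-sided p), the least-squares slope in feature units per
week, Fisher-z transforms, and Benjamini-Hochberg FDR across features.
Group contrasts of mean edge-GA correlation (e.g. long- vs short-range
connections) use a subject-level bootstrap: subjects are resampled with
replacement, per-feature correlations recomputed, and the difference of
Fisher-z group means summarized as z = mean/SD over resamples with a
one-sided normal p-value — resampling subjects rather than features
preserves the dependence between edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .panel import FeaturePanel

__all__ = [
    "UnivariateResult",
    "GroupComparison",
    "MassUnivariateRegression",
    "feature_regression",
    "fisher_z",
    "fdr_correct",
    "pearson_r_matrix",
    "bootstrap_group_mean_diff",
    "cross_metric_concordance",
]


def fisher_z(r):
    """Variance-stabilizing transform z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fdr_correct(p_values: np.ndarray, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over a family of p-values.

    Returns (q_values, reject_mask).  NaN entries (undefined tests) are
    excluded from the family size m and come back as NaN / False.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    valid = ~np.isnan(p)
    if not valid.any():
        raise ValueError("no valid p-values")
    if np.any((p[valid] <= 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    q = np.full(p.shape, np.nan)
    mask = np.zeros(p.shape, dtype=bool)
    rej, qv, _, _ = multipletests(p[valid], alpha=q_level, method="fdr_bh")
    q[valid] = qv
    mask[valid] = rej
    return q, mask


def pearson_r_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of x against y, vectorized.

    Columns with zero variance yield NaN (no exception; callers decide).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    num = xc.T @ yc
    den = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return np.clip(r, -1.0, 1.0)


@dataclass
class UnivariateResult:
    """Per-feature association statistics with GA at birth.

    ``table`` columns: pearson_r, fisher_z, slope (feature units per
    week), t_stat, p (two-sided), q_fdr, significant_uncorrected,
    significant_fdr.  ``df = n_subjects - 2`` for every feature.
    """

    table: pd.DataFrame = field(repr=False)
    n_subjects: int = 0
    metric_name: str = "custom"

    @property
    def df(self) -> int:
        return self.n_subjects - 2

    @property
    def r(self) -> np.ndarray:
        return self.table["pearson_r"].to_numpy()

    @property
    def z(self) -> np.ndarray:
        return self.table["fisher_z"].to_numpy()


def feature_regression(panel: FeaturePanel, q_level: float = 0.05) -> UnivariateResult:
    """Correlate every feature with GA at birth.

    Constant features get NaN statistics, a warning, and are excluded
    from the FDR family.
    """
    x = panel.values
    ga = panel.ga_values
    n = len(ga)
    if n < 5:
        raise ValueError("need at least 5 subjects")
    if np.ptp(ga) == 0:
        raise ValueError("GA is constant across subjects")

    r = pearson_r_matrix(x, ga)
    n_const = int(np.isnan(r).sum())
    if n_const:
        warnings.warn(f"{n_const} constant feature(s): r undefined, excluded from FDR")

    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.clip(1.0 - r**2, 1e-300, None))
        p = 2.0 * sp_stats.t.sf(np.abs(t), df)
    p = np.clip(p, 1e-300, 1.0)  # |r| = 1 gives p = 0; keep it in (0, 1]
    ga_c = ga - ga.mean()
    slope = (x - x.mean(axis=0)).T @ ga_c / (ga_c**2).sum()
    rz = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    q, sig_fdr = fdr_correct(p, q_level=q_level)

    table = pd.DataFrame({
        "pearson_r": r,
        "fisher_z": rz,
        "slope": slope,
        "t_stat": t,
        "p": p,
        "q_fdr": q,
        "significant_uncorrected": p < 0.05,
        "significant_fdr": sig_fdr,
    }, index=pd.Index(panel.feature_ids, name="feature_id"))
    return UnivariateResult(table=table, n_subjects=n, metric_name=panel.metric_name)


class MassUnivariateRegression(BaseEstimator):
    """Feature-wise GA association as a scikit-learn style estimator.

    ``fit(X, y)`` computes, for every column of X, the Pearson
    correlation with y plus the correlation t-test and BH-FDR; fitted
    attributes mirror :class:`UnivariateResult` columns.
    """

    def __init__(self, q_level: float = 0.05):
        self.q_level = q_level

    def fit(self, X, y):
        if isinstance(X, FeaturePanel):
            panel = X
        else:
            X = np.asarray(X, dtype=float)
            y = np.asarray(y, dtype=float)
            panel = FeaturePanel.from_array(
                X, y, [f"s{i}" for i in range(len(y))],
                [f"f{j}" for j in range(X.shape[1])], "custom")
        res = feature_regression(panel, q_level=self.q_level)
        self.result_ = res
        self.r_ = res.r
        self.fisher_z_ = res.z
        self.slope_ = res.table["slope"].to_numpy()
        self.p_ = res.table["p"].to_numpy()
        self.q_ = res.table["q_fdr"].to_numpy()
        self.significant_fdr_ = res.table["significant_fdr"].to_numpy()
        self.n_subjects_ = res.n_subjects
        return self


@dataclass
class GroupComparison:
    """Bootstrap contrast of mean edge-GA correlation between two groups."""

    group_a: str
    group_b: str
    observed_diff: float      # mean Fisher-z(group a) - mean Fisher-z(group b)
    z: float
    p_one_sided: float
    n_boot: int


def bootstrap_group_mean_diff(panel: FeaturePanel, group_labels,
                              n_boot: int = 100_000, seed: int = 0,
                              resample: str = "subjects") -> GroupComparison:
    """Compare average feature-GA correlation between two feature groups.

    ``group_labels`` assigns each feature to one of exactly two groups.
    The default resampling unit is subjects (preserving inter-feature
    dependence); ``resample="features"`` is available for sensitivity
    analysis.  z is the bootstrap mean over SD of the Fisher-z group
    mean difference, with one-sided p = 1 - Phi(|z|) reported in the
    direction of the observed difference.
    """
    labels = np.asarray(group_labels)
    names = pd.unique(labels)
    if len(names) != 2:
        raise ValueError("group_labels must define exactly two groups")
    mask_a = labels == names[0]
    mask_b = labels == names[1]
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs at least 2 features")

    x = panel.values
    ga = panel.ga_values
    n = len(ga)
    rng = np.random.default_rng(seed)

    def zdiff(xb, gab, ma, mb):
        r = pearson_r_matrix(xb, gab)
        z = np.arctanh(np.clip(r, -0.999999, 0.999999))
        return np.nanmean(z[ma]) - np.nanmean(z[mb])

    observed = zdiff(x, ga, mask_a, mask_b)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        if resample == "subjects":
            idx = rng.integers(n, size=n)
            while np.ptp(ga[idx]) == 0:
                idx = rng.integers(n, size=n)
            diffs[b] = zdiff(x[idx], ga[idx], mask_a, mask_b)
        elif resample == "features":
            ia = rng.choice(np.flatnonzero(mask_a), size=mask_a.sum(), replace=True)
            ib = rng.choice(np.flatnonzero(mask_b), size=mask_b.sum(), replace=True)
            r = pearson_r_matrix(x, ga)
            z = np.arctanh(np.clip(r, -0.999999, 0.999999))
            diffs[b] = np.nanmean(z[ia]) - np.nanmean(z[ib])
        else:
            raise ValueError("resample must be 'subjects' or 'features'")
    sd = diffs.std(ddof=1)
    # identical groups give diffs at float-noise level; report exact null
    z_stat = float(diffs.mean() / sd) if sd > 1e-10 else 0.0
    p = float(sp_stats.norm.sf(abs(z_stat)))
    return GroupComparison(group_a=str(names[0]), group_b=str(names[1]),
                           observed_diff=float(observed), z=z_stat,
                           p_one_sided=p, n_boot=n_boot)


def cross_metric_concordance(weights_a: np.ndarray, weights_b: np.ndarray) -> tuple[float, float]:
    """Spatial agreement of two aligned weight maps: Pearson r and
    two-sided p across features (df = n_features - 2)."""
    a = np.asarray(weights_a, dtype=float)
    b = np.asarray(weights_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("weight vectors must be 1-D and equal length")
    r, p = sp_stats.pearsonr(a, b)
    return float(r), float(p)
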