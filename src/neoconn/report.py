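"""Univariate/multivariate weight concordance and study orchestration.

``weight_concordance`` quantifies the spatial agreement between the
feature map found by the mass-univariate analysis (Fisher-z transforms
of per-feature correlations with GA) and the one found by the
multivariate model (bootstrap z-scores of PLS beta-weights, or raw
beta-weights).  ``run_full_study`` executes the whole pipeline on a
synthetic cohort — simulation, metric extraction, univariate statistics
with grouped contrasts, nested-CV PLS in both modalities, combined
feature spaces, positive-connectivity and shuffled-label controls, and
concordance — and writes a structured report bundle.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RoiAtlas, classify_edges
from .connectivity import connectivity_panel, nodal_strength_panel
from .panel import FeaturePanel, combine_feature_spaces
from .pls import NcvResult, bootstrap_beta_z, nested_cv, shuffled_label_control
from .simulate import CohortConfig, SyntheticDataset, simulate_dataset
from .spectral import SpectralConfig, falff_panel
from .univariate import (UnivariateResult, bootstrap_group_mean_diff,
                         cross_metric_concordance, feature_regression)

__all__ = ["WeightConcordance", "StudyConfig", "weight_concordance",
           "extract_panels", "run_full_study"]

logger = logging.getLogger(__name__)


@dataclass
class WeightConcordance:
    """Spatial correlation between univariate and multivariate weights."""

    metric_name: str
    scale: str  # "fisher_z_vs_beta_z" or "beta_vs_beta"
    r: float
    p: float
    n_features: int


def weight_concordance(univariate: UnivariateResult, ncv: NcvResult,
                       scale: str = "fisher_z_vs_beta_z") -> WeightConcordance:
    """Correlate univariate and multivariate feature weights.

    Default scale pairs the univariate Fisher-z values with the
    multivariate bootstrap beta z-scores; ``beta_vs_beta`` pairs the raw
    univariate slopes with the raw PLS beta-weights.
    """
    n = len(univariate.table)
    if ncv.final_beta_per_sd is None or len(ncv.final_beta_per_sd) != n:
        raise ValueError("univariate and multivariate feature sets are misaligned")
    if ncv.feature_ids is not None and list(univariate.table.index) != ncv.feature_ids:
        raise ValueError("feature ids differ between the two analyses")
    if scale == "fisher_z_vs_beta_z":
        if ncv.beta_z is None:
            raise ValueError("NcvResult lacks bootstrap beta z-scores")
        a, b = univariate.z, ncv.beta_z
    elif scale == "beta_vs_beta":
        a, b = univariate.table["slope"].to_numpy(), ncv.final_beta_per_sd
    else:
        raise ValueError("unknown scale")
    r, p = cross_metric_concordance(a, b)
    return WeightConcordance(metric_name=univariate.metric_name, scale=scale,
                             r=r, p=p, n_features=n)


@dataclass
class StudyConfig:
    """End-to-end study settings (synthetic cohort plus analysis knobs).

    ``n_boot_group`` and ``n_boot_beta`` default far below the
    100,000-iteration analysis standard so that a desk-scale run
    finishes in minutes; raise them for publication-grade z-scores.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    k_max: int = 20
    outer_folds: int = 10
    inner_folds: int = 10
    n_boot_group: int = 2000
    n_boot_beta: int = 500
    n_shuffles: int = 5
    modes: tuple[str, ...] = ("regression", "classification")
    include_group_contrasts: bool = True
    include_positive_only: bool = True
    include_combined: bool = True
    include_shuffled: bool = True
    include_concordance: bool = True


def extract_panels(dataset: SyntheticDataset,
                   positive_only: bool = False) -> dict[str, FeaturePanel]:
    """Compute the four per-subject feature panels from a dataset."""
    ts = dataset.timeseries
    atlas = dataset.atlas
    ga = dataset.phenotypes["ga_weeks"].to_numpy()
    sids = list(dataset.phenotypes["subject_id"])
    ids = atlas.roi_ids

    edge_ids = [f"rsfc:{ids[i]}-{ids[j]}"
                for i in range(len(ids)) for j in range(i + 1, len(ids))]
    rsfc = connectivity_panel(ts, positive_only=positive_only)
    rsfcns = nodal_strength_panel(ts, positive_only=positive_only)
    falff = falff_panel(ts, SpectralConfig(tr_seconds=ts.tr_seconds))
    vols = dataset.volumes.to_numpy(dtype=float)

    tag = "+" if positive_only else ""
    return {
        "rsFC" + tag: FeaturePanel.from_array(rsfc, ga, sids, edge_ids, "rsFC" + tag),
        "rsFCNS" + tag: FeaturePanel.from_array(
            rsfcns, ga, sids, [f"rsfcns:{r}" for r in ids], "rsFCNS" + tag),
        "fALFF": FeaturePanel.from_array(
            falff, ga, sids, [f"falff:{r}" for r in ids], "fALFF"),
        "Volume": FeaturePanel.from_array(
            vols, ga, sids, [f"vol:{r}" for r in ids], "Volume"),
    }


def _ncv_summary(res: NcvResult) -> dict:
    out = {
        "mode": res.mode,
        "per_fold_optimal_k": res.per_fold_optimal_k,
        "final_k": res.final_k,
        "performance": res.performance,
    }
    return out


def run_full_study(config: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the complete synthetic-cohort analysis and report it.

    Returns a nested report dict; when ``out_dir`` is given the bundle
    is also written to disk (report.json, univariate and beta-weight
    CSVs, out-of-fold prediction CSVs and the simulated data layout).
    """
    t0 = time.time()
    report: dict = {"config": {"seed": config.seed,
                               "cohort": asdict(config.cohort)},
                    "timing_s": {}}

    dataset = simulate_dataset(config.cohort)
    atlas = dataset.atlas
    taxonomy = classify_edges(atlas)
    report["timing_s"]["simulate"] = round(time.time() - t0, 2)

    t1 = time.time()
    panels = extract_panels(dataset)
    report["timing_s"]["extract"] = round(time.time() - t1, 2)

    # ---- univariate ----
    t1 = time.time()
    uni: dict[str, UnivariateResult] = {}
    report["univariate"] = {}
    for name, panel in panels.items():
        res = feature_regression(panel)
        uni[name] = res
        report["univariate"][name] = {
            "n_features": len(res.table),
            "n_significant_uncorrected": int(res.table["significant_uncorrected"].sum()),
            "n_significant_fdr": int(res.table["significant_fdr"].sum()),
        }
    if config.include_group_contrasts:
        contrasts = {}
        for col in ("cortico_class", "range_class", "homotopy_class"):
            gc = bootstrap_group_mean_diff(
                panels["rsFC"], taxonomy.table[col].to_numpy(),
                n_boot=config.n_boot_group, seed=config.seed)
            contrasts[col] = asdict(gc)
        sub = atlas.lobes == "subcortical"
        for name in ("rsFCNS", "fALFF", "Volume"):
            gc = bootstrap_group_mean_diff(
                panels[name], np.where(sub, "subcortical", "cortical"),
                n_boot=config.n_boot_group, seed=config.seed)
            contrasts[f"{name}:subcortical_vs_cortical"] = asdict(gc)
        report["group_contrasts"] = contrasts
    report["timing_s"]["univariate"] = round(time.time() - t1, 2)

    # ---- multivariate ----
    t1 = time.time()
    ncv_results: dict[str, NcvResult] = {}
    report["multivariate"] = {}
    metric_list = list(panels)
    if config.include_combined:
        panels["combined"] = combine_feature_spaces(
            panels["rsFC"], panels["fALFF"], panels["Volume"])
        metric_list.append("combined")
    if config.include_positive_only:
        pos = extract_panels(dataset, positive_only=True)
        panels["rsFC+"] = pos["rsFC+"]
        metric_list.append("rsFC+")
    for name in metric_list:
        report["multivariate"][name] = {}
        for mode in config.modes:
            res = nested_cv(panels[name], mode=mode, k_max=config.k_max,
                            outer_folds=config.outer_folds,
                            inner_folds=config.inner_folds, seed=config.seed)
            ncv_results[f"{name}:{mode}"] = res
            report["multivariate"][name][mode] = _ncv_summary(res)
            logger.info("nCV %s/%s: score=%.3f k=%d", name, mode,
                        res.score(), res.final_k)
    if config.include_shuffled:
        null_scores = {}
        for mode in config.modes:
            dist = shuffled_label_control(
                panels["Volume"], mode=mode, n_shuffles=config.n_shuffles,
                seed=config.seed, k_max=config.k_max,
                outer_folds=config.outer_folds, inner_folds=config.inner_folds)
            null_scores[mode] = [float(v) for v in dist]
        report["shuffled_label_null"] = null_scores
    report["timing_s"]["multivariate"] = round(time.time() - t1, 2)

    # ---- concordance ----
    if config.include_concordance and "regression" in config.modes:
        t1 = time.time()
        report["concordance"] = {}
        for name in [m for m in metric_list if m not in ("combined", "rsFC+")]:
            res = ncv_results[f"{name}:regression"]
            res.beta_z = bootstrap_beta_z(panels[name], k=res.final_k,
                                          n_boot=config.n_boot_beta,
                                          seed=config.seed)
            wc = weight_concordance(uni[name], res)
            report["concordance"][name] = asdict(wc)
        report["timing_s"]["concordance"] = round(time.time() - t1, 2)

    report["timing_s"]["total"] = round(time.time() - t0, 2)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        dataset.write(out / "data")
        for name, res in uni.items():
            res.table.to_csv(out / f"univariate_{name.replace('+', '_pos')}.csv")
        for key, res in ncv_results.items():
            safe = key.replace("+", "_pos").replace(":", "_")
            pd.DataFrame({
                "subject_id": list(dataset.phenotypes["subject_id"]),
                "y_true": res.y,
                "oof_prediction": res.oof_predictions,
            }).to_csv(out / f"oof_{safe}.csv", index=False)
            beta = pd.DataFrame({"beta_per_sd": res.final_beta_per_sd},
                                index=res.feature_ids)
            if res.beta_z is not None:
                beta["beta_z"] = res.beta_z
            beta.to_csv(out / f"beta_{safe}.csv", index_label="feature_id")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
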