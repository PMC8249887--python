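"""Synthetic neonatal cohort generator.

Generates a fully synthetic resting-state cohort — phenotypes, ROI-averaged
BOLD time series and regional volumes — carrying the statistical structure
that the downstream analyses exploit:

* gestational age (GA) at birth drawn from a truncated normal
  (mean 33, SD 3.75, range 25-40 weeks), with every scan at a
  postmenstrual age of 40 weeks;
* per-subject inter-regional correlation structure with a block baseline
  (within-lobe, homotopic bonus) plus signed GA-dependent slopes on a
  random subset of edges, repaired to the nearest positive-semidefinite
  correlation matrix;
* an AR(1) temporal kernel and a shared global signal component;
* GA-dependent low-frequency (0.01-0.1 Hz) spectral power fractions in a
  subset of regions, so fALFF carries signal;
* regional volumes with positive GA slopes in subcortical and medial
  temporal regions and negative slopes in medial frontal regions.

``null_mode`` zeroes every GA slope, producing a cohort in which any
detected association is a false positive — the calibration condition for
downstream type-I-error checks.

All randomness flows from a single master seed through named
``numpy.random.SeedSequence`` child streams (atlas, cohort, timeseries,
volumes), so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .atlas import RoiAtlas, edge_pairs, generate_atlas

__all__ = [
    "CohortConfig",
    "RoiTimeSeriesSet",
    "SyntheticDataset",
    "generate_cohort",
    "generate_timeseries",
    "generate_volumes",
    "simulate_dataset",
    "nearest_correlation",
]

_STREAMS = ("atlas", "cohort", "timeseries", "volumes", "maturation")

# Per-lobe mean ROI volumes (mm^3) at the cohort-mean GA, neonatal scale.
_VOLUME_BASELINES = {
    "subcortical": 2500.0,
    "frontal": 5200.0,
    "temporal": 4600.0,
    "parietal": 4800.0,
    "occipital": 4200.0,
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    GA-effect parameters are per-week slopes around the cohort mean GA;
    ``null_mode=True`` forces all of them to zero.
    """

    n_subjects: int = 88
    maturation_sd: float = 2.5            # weeks; latent brain-maturity scatter around GA
    ga_mean: float = 33.0
    ga_sd: float = 3.75
    ga_range: tuple[float, float] = (25.0, 40.0)
    pma_weeks: float = 40.0
    n_timepoints: int = 164
    tr_seconds: float = 1.555
    # connectivity effects
    edge_effect_fraction: float = 0.10
    edge_slope_min: float = 0.01          # |correlation units| per week
    edge_slope_max: float = 0.04
    base_within_lobe_r: float = 0.30
    base_homotopic_bonus: float = 0.20
    base_floor_r: float = 0.05
    edge_noise_sd: float = 0.08           # per-subject idiosyncratic edge variability
    global_signal_weight: float = 0.5
    ar1_coefficient: float = 0.3
    # spectral effects
    falff_effect_rois: tuple[int, ...] | None = None   # 1-based roi_ids; None -> random pick
    n_falff_effect_rois: int = 10
    falff_slope_per_week: float = 0.012   # low-band mixing fraction per week
    falff_baseline: float = 0.5
    # volume effects
    volume_slope_rate: float = 0.015      # fraction of baseline per week (+, subcortical/medial temporal)
    volume_slope_rate_frontal: float = -0.010  # fraction per week (medial frontal)
    volume_cv: float = 0.05
    volume_subject_cv: float = 0.10       # per-subject global (head-size) scale factor
    seed: int = 0
    null_mode: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10 (cross-validation infeasible below)")
        if self.ga_sd < 0:
            raise ValueError("ga_sd must be >= 0")
        lo, hi = self.ga_range
        if not lo < hi:
            raise ValueError("ga_range must be increasing")
        if not 0.0 <= self.edge_effect_fraction <= 1.0:
            raise ValueError("edge_effect_fraction must lie in [0, 1]")
        if self.n_timepoints < 32:
            raise ValueError("n_timepoints must be >= 32 (spectral bands need resolution)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0.0 < self.falff_baseline < 1.0:
            raise ValueError("falff_baseline must lie in (0, 1)")
        if self.volume_cv < 0:
            raise ValueError("volume_cv must be >= 0")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must lie in [0, 1)")

    def streams(self) -> dict[str, np.random.Generator]:
        """Named child generators spawned from the master seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass
class RoiTimeSeriesSet:
    """ROI-averaged BOLD series for a cohort: (subjects, timepoints, rois)."""

    data: np.ndarray = field(repr=False)
    tr_seconds: float = 1.555
    subject_ids: list[str] = field(default_factory=list)
    roi_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (subjects, timepoints, rois)")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contain non-finite values")
        if self.data.shape[1] < 32:
            raise ValueError("need >= 32 timepoints")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def n_rois(self) -> int:
        return self.data.shape[2]


def truncnorm_parameters(config: CohortConfig) -> tuple[float, float]:
    """Location and scale of the underlying normal whose truncation to
    ``ga_range`` has mean ``ga_mean`` and SD ``ga_sd``.

    Truncation shrinks the SD (and can shift the mean), so using the
    target moments directly as the parent parameters would understate
    the cohort spread; the two parent parameters are solved so the
    truncated distribution itself reproduces the printed cohort moments.
    """
    lo, hi = config.ga_range

    def eqs(p):
        loc, scale = p[0], abs(p[1])
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = sp_stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - config.ga_mean, np.sqrt(v) - config.ga_sd]

    sol = sp_optimize.fsolve(eqs, [config.ga_mean, config.ga_sd * 1.3])
    resid = eqs(sol)
    if max(abs(resid[0]), abs(resid[1])) > 1e-6:
        raise ValueError(
            f"cannot calibrate truncated normal to mean {config.ga_mean}, "
            f"SD {config.ga_sd} on range {config.ga_range}")
    return float(sol[0]), float(abs(sol[1]))


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw subject phenotypes: GA at birth (weeks) and PMA at scan.

    GA follows a truncated normal on ``ga_range`` calibrated (see
    :func:`truncnorm_parameters`) so the truncated distribution has mean
    ``ga_mean`` and SD ``ga_sd``; with ``ga_sd == 0`` every subject sits
    at ``ga_mean``.
    """
    rng = config.streams()["cohort"]
    n = config.n_subjects
    if config.ga_sd == 0:
        ga = np.full(n, config.ga_mean)
    else:
        lo, hi = config.ga_range
        loc, scale = truncnorm_parameters(config)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        ga = sp_stats.truncnorm.rvs(a, b, loc=loc, scale=scale,
                                    size=n, random_state=rng)
    return pd.DataFrame({
        "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
        "ga_weeks": ga,
        "pma_weeks": np.full(n, config.pma_weeks),
    })


def maturation_deltas(cohort: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    """Per-subject effective maturity deviation from the cohort mean (weeks).

    All GA-dependent brain effects are driven by a latent maturational
    age — chronological GA plus Gaussian scatter of SD
    ``maturation_sd`` — so inference from brain features against
    recorded GA cannot be perfect, mimicking biological variability.
    The scatter comes from its own seed stream and is identical across
    the time-series and volume generators for a given master seed.
    """
    rng = config.streams()["maturation"]
    noise = rng.normal(0.0, config.maturation_sd, size=len(cohort))
    return cohort["ga_weeks"].to_numpy() + noise - config.ga_mean


def nearest_correlation(r: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a nearby valid correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the reconstruction is
    re-normalized to unit diagonal; the result is exactly symmetric with
    an exactly unit diagonal.
    """
    sym = 0.5 * (r + r.T)
    vals, vecs = np.linalg.eigh(sym)
    if not np.all(np.isfinite(vals)):
        raise ValueError("PSD projection failed: non-finite eigenvalues")
    vals = np.clip(vals, eig_floor, None)
    a = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(a))
    a = a / np.outer(d, d)
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 1.0)
    return a


def _base_correlation(atlas: RoiAtlas, config: CohortConfig) -> np.ndarray:
    n = atlas.n_rois
    lobes = atlas.lobes
    r = np.full((n, n), config.base_floor_r)
    same_lobe = lobes[:, None] == lobes[None, :]
    r[same_lobe] = config.base_within_lobe_r
    if atlas.has_partners:
        ids = atlas.roi_ids
        pos = {rid: k for k, rid in enumerate(ids)}
        for k, rid in enumerate(ids):
            p = pos[atlas.table["homotopic_partner"].iloc[k]]
            r[k, p] = r[p, k] = config.base_within_lobe_r + config.base_homotopic_bonus
    np.fill_diagonal(r, 1.0)
    return r


def draw_edge_effects(atlas: RoiAtlas, config: CohortConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Signed per-week correlation slopes on a random edge subset (N x N)."""
    n = atlas.n_rois
    pairs = edge_pairs(n)
    m = len(pairs)
    e = np.zeros((n, n))
    if config.null_mode or config.edge_effect_fraction == 0.0:
        return e
    k = int(round(config.edge_effect_fraction * m))
    chosen = rng.choice(m, size=k, replace=False)
    mags = rng.uniform(config.edge_slope_min, config.edge_slope_max, size=k)
    signs = rng.choice([-1.0, 1.0], size=k)
    for idx, mag, s in zip(chosen, mags, signs):
        i, j = pairs[idx]
        e[i, j] = e[j, i] = s * mag
    return e


def _band_masks(t: int, tr: float) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.fft.rfftfreq(t, d=tr)
    low = (freqs > 0) & (freqs <= 0.1)
    high = freqs > 0.1
    return low, high


def _band_mix(x: np.ndarray, mix: np.ndarray, t: int, tr: float) -> np.ndarray:
    """Re-weight low/high frequency content per column.

    ``mix[j]`` is the target low-band variance fraction of column j; both
    band carriers are standardized before mixing, so the column variance
    stays near 1 while the spectral split follows ``mix``.
    """
    low, high = _band_masks(t, tr)
    f = np.fft.rfft(x - x.mean(axis=0), axis=0)
    lo = np.fft.irfft(f * low[:, None], n=t, axis=0)
    hi = np.fft.irfft(f * high[:, None], n=t, axis=0)
    lo_sd = lo.std(axis=0)
    hi_sd = hi.std(axis=0)
    lo = np.divide(lo, lo_sd, out=lo, where=lo_sd > 0)
    hi = np.divide(hi, hi_sd, out=hi, where=hi_sd > 0)
    return np.sqrt(mix) * lo + np.sqrt(1.0 - mix) * hi


def resolve_falff_rois(atlas: RoiAtlas, config: CohortConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """0-based row positions of the ROIs carrying the fALFF-GA effect."""
    if config.falff_effect_rois is not None:
        pos = {rid: k for k, rid in enumerate(atlas.roi_ids)}
        return np.array([pos[r] for r in config.falff_effect_rois], dtype=int)
    k = min(config.n_falff_effect_rois, atlas.n_rois)
    return rng.choice(atlas.n_rois, size=k, replace=False)


def generate_timeseries(cohort: pd.DataFrame, atlas: RoiAtlas,
                        config: CohortConfig) -> RoiTimeSeriesSet:
    """Sample per-subject ROI BOLD series with the configured structure.

    For subject *s* with GA deviation ``d = ga_s - ga_mean`` (weeks) the
    target correlation matrix is ``R_base + d * E`` (block baseline plus
    signed per-week edge slopes), repaired to the nearest valid
    correlation matrix.  Correlated Gaussian series are drawn, smoothed
    with an AR(1) kernel, re-weighted in the frequency domain so that
    effect ROIs get a GA-dependent low-band power fraction, and a shared
    AR(1) global component is added to every ROI.
    """
    rng = config.streams()["timeseries"]
    n_sub = len(cohort)
    t = config.n_timepoints
    tr = config.tr_seconds
    n = atlas.n_rois

    r_base = _base_correlation(atlas, config)
    effects = draw_edge_effects(atlas, config, rng)
    falff_pos = resolve_falff_rois(atlas, config, rng)
    falff_slope = 0.0 if config.null_mode else config.falff_slope_per_week

    burn = 24
    phi = config.ar1_coefficient
    deltas = maturation_deltas(cohort, config)
    out = np.empty((n_sub, t, n))
    iu = np.triu_indices(n, k=1)
    for s in range(n_sub):
        d = deltas[s]
        r_target = r_base + d * effects
        if config.edge_noise_sd > 0:
            # idiosyncratic per-subject connectivity (individual differences
            # unrelated to GA); keeps inference away from the noiseless limit
            noise = np.zeros((n, n))
            noise[iu] = rng.normal(0.0, config.edge_noise_sd, size=len(iu[0]))
            r_target = r_target + noise + noise.T
        np.fill_diagonal(r_target, 1.0)
        r_psd = nearest_correlation(r_target)
        chol = np.linalg.cholesky(r_psd)
        white = rng.standard_normal((t + burn, n))
        x = white @ chol.T
        if phi > 0:
            x = sp_signal.lfilter([1.0], [1.0, -phi], x, axis=0)
        x = x[burn:]
        mix = np.full(n, config.falff_baseline)
        if falff_slope != 0.0 and falff_pos.size:
            mix[falff_pos] = np.clip(config.falff_baseline + falff_slope * d, 0.05, 0.95)
        x = _band_mix(x, mix, t, tr)
        if config.global_signal_weight != 0.0:
            g = rng.standard_normal(t + burn)
            if phi > 0:
                g = sp_signal.lfilter([1.0], [1.0, -phi], g)
            g = g[burn:]
            g = (g - g.mean()) / g.std()
            x = x + config.global_signal_weight * g[:, None]
        out[s] = x

    return RoiTimeSeriesSet(
        data=out, tr_seconds=tr,
        subject_ids=list(cohort["subject_id"]),
        roi_ids=atlas.roi_ids.copy(),
    )


def generate_volumes(cohort: pd.DataFrame, atlas: RoiAtlas,
                     config: CohortConfig) -> pd.DataFrame:
    """Per-subject regional volumes (mm^3), subjects x ROIs.

    ``V[s, j] = (mu_j + b_j * (ga_s - ga_mean)) * (1 + cv * eps)`` with
    ``b_j > 0`` for subcortical and medial temporal ROIs, ``b_j < 0`` for
    medial frontal ROIs and 0 elsewhere.  Baselines are per-lobe means
    with ±30% per-ROI variation.  Raises if any volume comes out
    non-positive (a sign of an unphysical configuration).
    """
    rng = config.streams()["volumes"]
    n = atlas.n_rois
    lobes = atlas.lobes
    medial = atlas.table["medial"].to_numpy()

    mu = np.array([_VOLUME_BASELINES[lb] for lb in lobes]) * rng.uniform(0.7, 1.3, size=n)
    b = np.zeros(n)
    if not config.null_mode:
        pos_mask = (lobes == "subcortical") | ((lobes == "temporal") & medial)
        neg_mask = (lobes == "frontal") & medial
        b[pos_mask] = config.volume_slope_rate * mu[pos_mask]
        b[neg_mask] = config.volume_slope_rate_frontal * mu[neg_mask]

    delta = maturation_deltas(cohort, config)
    lin = mu[None, :] + delta[:, None] * b[None, :]
    noise = 1.0 + config.volume_cv * rng.standard_normal(lin.shape)
    # shared per-subject scale: head-size variability unrelated to GA
    subj_scale = np.exp(config.volume_subject_cv * rng.standard_normal(len(cohort)))
    vol = lin * noise * subj_scale[:, None]
    if np.any(vol <= 0):
        raise ValueError("configuration produced non-positive volumes")
    return pd.DataFrame(vol, index=list(cohort["subject_id"]),
                        columns=atlas.roi_ids)


def volume_slopes(atlas: RoiAtlas, config: CohortConfig) -> np.ndarray:
    """Implanted per-ROI volume slopes b_j (mm^3/week) for a given config.

    Recomputes the same baseline draw used by :func:`generate_volumes`
    (the volume stream is deterministic given the master seed), so tests
    can compare recovered against implanted slopes.
    """
    rng = config.streams()["volumes"]
    n = atlas.n_rois
    lobes = atlas.lobes
    medial = atlas.table["medial"].to_numpy()
    mu = np.array([_VOLUME_BASELINES[lb] for lb in lobes]) * rng.uniform(0.7, 1.3, size=n)
    b = np.zeros(n)
    if not config.null_mode:
        pos_mask = (lobes == "subcortical") | ((lobes == "temporal") & medial)
        neg_mask = (lobes == "frontal") & medial
        b[pos_mask] = config.volume_slope_rate * mu[pos_mask]
        b[neg_mask] = config.volume_slope_rate_frontal * mu[neg_mask]
    return b


@dataclass
class SyntheticDataset:
    """Bundle of everything one synthetic study run produces."""

    config: CohortConfig
    atlas: RoiAtlas
    phenotypes: pd.DataFrame
    timeseries: RoiTimeSeriesSet
    volumes: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        """Write the plain-text study layout.

        ``phenotypes.csv``, ``atlas.tsv``, ``volumes.csv`` and one
        ``timeseries/<subject_id>.tsv`` per subject (rows = timepoints,
        columns = roi_ids).
        """
        out = Path(out_dir)
        (out / "timeseries").mkdir(parents=True, exist_ok=True)
        self.phenotypes.to_csv(out / "phenotypes.csv", index=False)
        self.atlas.table.to_csv(out / "atlas.tsv", sep="\t", index=False)
        vol = self.volumes.copy()
        vol.index.name = "subject_id"
        vol.to_csv(out / "volumes.csv")
        for k, sid in enumerate(self.timeseries.subject_ids):
            df = pd.DataFrame(self.timeseries.data[k],
                              columns=self.timeseries.roi_ids)
            df.to_csv(out / "timeseries" / f"{sid}.tsv", sep="\t", index=False)


def simulate_dataset(config: CohortConfig, atlas: RoiAtlas | None = None) -> SyntheticDataset:
    """Run the full generator: atlas, phenotypes, time series, volumes."""
    if atlas is None:
        atlas_seed = int(config.streams()["atlas"].integers(2**31))
        atlas = generate_atlas(seed=atlas_seed)
    cohort = generate_cohort(config)
    ts = generate_timeseries(cohort, atlas, config)
    vols = generate_volumes(cohort, atlas, config)
    return SyntheticDataset(config=config, atlas=atlas, phenotypes=cohort,
                            timeseries=ts, volumes=vols)
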