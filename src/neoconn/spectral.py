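"""fALFF: fractional amplitude of low-frequency fluctuations.

fALFF of an ROI series is the ratio of BOLD spectral power in the
0.01-0.1 Hz band to the total power from the series' fundamental
frequency up to Nyquist.  With the default scan parameters (164 volumes
at TR 1.555 s) the fundamental is ~0.0039 Hz and Nyquist ~0.32 Hz.

The spectrum is the raw one-sided periodogram of the mean-removed series
(boxcar window, no taper, no Welch averaging): analytically simple and
exactly Parseval-consistent — the summed non-DC power equals the
time-domain population variance (denominator T).  The ratio of two
band sums is invariant to any overall scaling of the series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

__all__ = ["SpectralConfig", "power_spectrum", "compute_falff", "falff_vector",
           "falff_panel"]


@dataclass(frozen=True)
class SpectralConfig:
    """Band limits for the fALFF ratio, in Hz.

    ``floor_freq=None`` uses the series' own fundamental 1/(T*TR) as the
    lower edge of the total-power band; for the default scan length this
    evaluates to the conventional 0.0039 Hz.
    """

    band_low: float = 0.01
    band_high: float = 0.1
    floor_freq: float | None = None
    tr_seconds: float = 1.555

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if self.band_high > nyquist + 1e-12:
            raise ValueError(f"band_high {self.band_high} exceeds Nyquist {nyquist:.4g}")
        if self.floor_freq is not None and self.floor_freq > self.band_low:
            raise ValueError("floor_freq must not exceed band_low")

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


def power_spectrum(series: np.ndarray, tr_seconds: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of a mean-removed series.

    Returns (frequencies in Hz at k/(T*TR), power).  Power is scaled so
    that the sum over non-DC bins equals the population variance of the
    series (Parseval).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 32:
        raise ValueError("series must be 1-D with length >= 32")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    freqs, power = sp_signal.periodogram(
        x, fs=1.0 / tr_seconds, window="boxcar", detrend="constant",
        scaling="spectrum")
    return freqs, power


def compute_falff(series: np.ndarray, config: SpectralConfig) -> float:
    """Low-band to total power ratio of one series; lies in [0, 1].

    Band membership is closed on both ends; the DC bin never counts.
    Raises on a constant series (zero total power).
    """
    freqs, power = power_spectrum(series, config.tr_seconds)
    floor = config.floor_freq
    if floor is None:
        floor = freqs[1]  # fundamental 1/(T*TR)
    total_mask = (freqs >= floor - 1e-15) & (freqs <= config.nyquist + 1e-15) & (freqs > 0)
    band_mask = (total_mask & (freqs >= config.band_low - 1e-12)
                 & (freqs <= config.band_high + 1e-12))
    total = power[total_mask].sum()
    if total <= 0:
        raise ValueError("zero total power: constant series")
    return float(power[band_mask].sum() / total)


def falff_vector(timeseries: np.ndarray, config: SpectralConfig,
                 roi_ids: np.ndarray | None = None) -> np.ndarray:
    """fALFF per column of a T x N array; errors name the offending ROI."""
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be T x N")
    out = np.empty(ts.shape[1])
    for j in range(ts.shape[1]):
        try:
            out[j] = compute_falff(ts[:, j], config)
        except ValueError as err:
            rid = roi_ids[j] if roi_ids is not None else j
            raise ValueError(f"ROI {rid}: {err}") from err
    return out


def falff_panel(tsset, config: SpectralConfig | None = None) -> np.ndarray:
    """Subjects x ROIs fALFF matrix for a cohort time-series set."""
    if config is None:
        config = SpectralConfig(tr_seconds=tsset.tr_seconds)
    return np.stack([
        falff_vector(tsset.data[s], config, roi_ids=tsset.roi_ids)
        for s in range(tsset.n_subjects)
    ])
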