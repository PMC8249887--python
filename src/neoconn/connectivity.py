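"""Global-signal-adjusted functional connectivity and nodal strength.

The connectivity estimate for an ROI pair (i, j) is the coefficient on
the z-scored series i in a least-squares fit of the z-scored series j on
{intercept, series i, global signal}, where the global signal is the
z-score of the across-ROI mean of the raw series.  The fit is not
commutative, so the two directed coefficients are averaged to give the
undirected edge value.  Without the global covariate the coefficient
reduces exactly to the Pearson correlation of the two series.

Nodal strength (rsFCNS) of ROI j is the mean over the other N-1 ROIs of
the squared edge values — invariant to edge sign flips.  An optional
root-mean-square variant takes the square root of that mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import edge_pairs

__all__ = [
    "ConnectivityResult",
    "zscore_series",
    "global_signal",
    "compute_rsfc",
    "zero_negative_edges",
    "compute_rsfcns",
    "connectivity_panel",
    "nodal_strength_panel",
]

_COLLINEAR_TOL = 1e-10


@dataclass
class ConnectivityResult:
    """Symmetric N x N connectivity matrix plus its canonical edge vector.

    The diagonal is NaN (self-connectivity is undefined).  The edge
    vector enumerates the upper triangle row-major (i < j), length
    N(N-1)/2 — 4,005 for the default 90-ROI parcellation.
    """

    matrix: np.ndarray = field(repr=False)
    positive_only: bool = False

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectivity matrix must be square")
        off = ~np.eye(m.shape[0], dtype=bool)
        if not np.allclose(m[off], m.T[off], rtol=0, atol=0):
            raise ValueError("connectivity matrix must be symmetric")

    @property
    def n_rois(self) -> int:
        return self.matrix.shape[0]

    @property
    def edge_index(self) -> list[tuple[int, int]]:
        return edge_pairs(self.n_rois)

    @property
    def edge_vector(self) -> np.ndarray:
        iu = np.triu_indices(self.n_rois, k=1)
        return self.matrix[iu]


def zscore_series(series: np.ndarray, roi: object = None) -> np.ndarray:
    """Z-score with sample SD (denominator T-1).

    A constant series raises (identifying the ROI when given) rather
    than being silently zeroed — downstream regressions would be
    meaningless on degenerate input.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("series must be 1-D with length >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        label = f" (ROI {roi})" if roi is not None else ""
        raise ValueError(f"constant series{label}: cannot z-score")
    return (x - x.mean()) / sd


def global_signal(timeseries: np.ndarray, normalize_first: bool = False) -> np.ndarray:
    """Global nuisance regressor: z-score of the across-ROI mean signal.

    With ``normalize_first=True`` each ROI is z-scored before averaging
    (the alternative reading of "normalized average"); the default
    averages the raw relative-signal-change series and z-scores once.
    """
    ts = np.asarray(timeseries, dtype=float)
    if normalize_first:
        cols = np.stack([zscore_series(ts[:, j], roi=j) for j in range(ts.shape[1])], axis=1)
        return zscore_series(cols.mean(axis=1))
    return zscore_series(ts.mean(axis=1))


def compute_rsfc(timeseries: np.ndarray, include_global: bool = True,
                 normalize_global_first: bool = False) -> ConnectivityResult:
    """GLM connectivity matrix from a T x N ROI time-series array.

    For every ordered pair the z-scored target series is regressed on
    {intercept, z-scored source series, global signal}; the returned
    matrix averages the two directed coefficients.  With
    ``include_global=False`` the global covariate is dropped and the
    entries equal plain Pearson correlations.

    Raises if any ROI series is constant, or if a source series is
    collinear with the global signal (rank-deficient design).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be T x N")
    t, n = ts.shape
    if t < 8 or n < 3:
        raise ValueError("need T >= 8 timepoints and N >= 3 ROIs")

    z = np.empty_like(ts)
    for j in range(n):
        z[:, j] = zscore_series(ts[:, j], roi=j)

    # All regressors and targets have exactly zero mean, so the fit with
    # an explicit intercept has intercept 0 and the slope coefficients
    # follow from centered Gram products.
    if include_global:
        g = global_signal(ts, normalize_first=normalize_global_first)
        c = z.T @ z                       # S_ij
        cg = z.T @ g                      # S_ig
        sgg = float(g @ g)
        den = np.diag(c) * sgg - cg**2    # per source ROI i
        bad = den <= _COLLINEAR_TOL * np.diag(c) * sgg
        if np.any(bad):
            i = int(np.argmax(bad))
            raise ValueError(
                f"rank-deficient design: ROI {i} is collinear with the global signal")
        num = c * sgg - np.outer(cg, cg)  # num[i, j] for coefficient i -> j
        b = num / den[:, None]
    else:
        c = z.T @ z
        b = c / np.diag(c)[:, None]

    m = 0.5 * (b + b.T)
    np.fill_diagonal(m, np.nan)
    return ConnectivityResult(matrix=m, positive_only=False)


def zero_negative_edges(conn: ConnectivityResult) -> ConnectivityResult:
    """Positive-connectivity control: clamp negative edges to zero."""
    m = conn.matrix.copy()
    off = ~np.eye(conn.n_rois, dtype=bool)
    m[off & (m < 0)] = 0.0
    return ConnectivityResult(matrix=m, positive_only=True)


def compute_rsfcns(conn: ConnectivityResult, rms: bool = False) -> np.ndarray:
    """Nodal strength: per-ROI mean of squared edge values.

    ``values[j] = (1/(N-1)) * sum_{i != j} M[i, j]**2``; with
    ``rms=True`` the square root of that mean is returned instead.
    """
    m = conn.matrix
    n = conn.n_rois
    if n < 2:
        raise ValueError("nodal strength needs N >= 2")
    sq = np.where(np.isnan(m), 0.0, m) ** 2
    values = sq.sum(axis=0) / (n - 1)
    return np.sqrt(values) if rms else values


def connectivity_panel(tsset, include_global: bool = True,
                       positive_only: bool = False) -> np.ndarray:
    """Subjects x edges matrix of rsFC values for a whole cohort."""
    rows = []
    for s in range(tsset.n_subjects):
        conn = compute_rsfc(tsset.data[s], include_global=include_global)
        if positive_only:
            conn = zero_negative_edges(conn)
        rows.append(conn.edge_vector)
    return np.asarray(rows)


def nodal_strength_panel(tsset, include_global: bool = True,
                         positive_only: bool = False, rms: bool = False) -> np.ndarray:
    """Subjects x ROIs matrix of nodal strength values for a cohort."""
    rows = []
    for s in range(tsset.n_subjects):
        conn = compute_rsfc(tsset.data[s], include_global=include_global)
        if positive_only:
            conn = zero_negative_edges(conn)
        rows.append(compute_rsfcns(conn, rms=rms))
    return np.asarray(rows)
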