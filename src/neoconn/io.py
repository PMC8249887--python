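"""Plain-text study layout readers, plus an optional MATLAB adapter.

The on-disk layout written by the simulator (and accepted for user
data) is: ``phenotypes.csv`` (subject_id, ga_weeks, pma_weeks),
``atlas.tsv`` (one row per ROI), ``volumes.csv`` (wide, subject x ROI)
and ``timeseries/<subject_id>.tsv`` (rows = timepoints, columns = ROI
ids, header row).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RoiAtlas
from .simulate import RoiTimeSeriesSet

__all__ = ["read_atlas", "read_phenotypes", "read_timeseries_dir",
           "read_volumes", "load_mat_timeseries"]


def read_atlas(path: str | Path) -> RoiAtlas:
    table = pd.read_csv(path, sep="\t")
    return RoiAtlas(table)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject_id", "ga_weeks"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype table must have columns {sorted(required)}")
    return df


def read_volumes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.columns = [int(c) for c in df.columns]
    return df


def read_timeseries_dir(directory: str | Path, phenotypes: pd.DataFrame,
                        tr_seconds: float) -> RoiTimeSeriesSet:
    """Assemble a cohort time-series set from per-subject TSV files."""
    directory = Path(directory)
    mats = []
    roi_ids = None
    for sid in phenotypes["subject_id"]:
        f = directory / f"{sid}.tsv"
        if not f.exists():
            raise FileNotFoundError(f"no time-series file for subject {sid}: {f}")
        df = pd.read_csv(f, sep="\t")
        ids = np.array([int(c) for c in df.columns])
        if roi_ids is None:
            roi_ids = ids
        elif not np.array_equal(ids, roi_ids):
            raise ValueError(f"subject {sid}: ROI columns differ from the cohort's")
        mats.append(df.to_numpy(dtype=float))
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent time-series shapes across subjects: {shapes}")
    return RoiTimeSeriesSet(data=np.stack(mats), tr_seconds=tr_seconds,
                            subject_ids=list(phenotypes["subject_id"]),
                            roi_ids=roi_ids)


def load_mat_timeseries(path: str | Path, key: str | None = None,
                        tr_seconds: float = 1.555,
                        subject_ids: list[str] | None = None) -> RoiTimeSeriesSet:
    """Adapter for a MATLAB .mat deposit of ROI time series.

    Accepts either a 3-D array (subjects x timepoints x rois) or a cell
    array / object array of per-subject timepoints x rois matrices under
    ``key`` (when ``key`` is None the first non-metadata variable is
    used).  This is an optional convenience; everything downstream only
    needs a :class:`RoiTimeSeriesSet`.
    """
    from scipy.io import loadmat

    mat = loadmat(path, squeeze_me=True)
    names = [k for k in mat if not k.startswith("__")]
    if key is None:
        if not names:
            raise ValueError("no variables found in .mat file")
        key = names[0]
    if key not in mat:
        raise KeyError(f"variable {key!r} not in .mat file (has {names})")
    raw = mat[key]
    if isinstance(raw, np.ndarray) and raw.dtype == object:
        mats = [np.asarray(m, dtype=float) for m in raw.ravel()]
        data = np.stack(mats)
    else:
        data = np.asarray(raw, dtype=float)
        if data.ndim == 2:
            data = data[None]
    if subject_ids is None:
        subject_ids = [f"sub-{i + 1:03d}" for i in range(data.shape[0])]
    return RoiTimeSeriesSet(data=data, tr_seconds=tr_seconds,
                            subject_ids=subject_ids,
                            roi_ids=np.arange(1, data.shape[2] + 1))
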