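"""Regional volume panels: validation, alignment and totals.

Volumes arrive as inputs (mm^3, one value per subject and ROI); this
module validates them against the phenotype table and computes the
whole-brain total (sum of ROI volumes) used by the global univariate
analysis.  Estimating volumes from images is outside this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["VolumePanel", "load_volumes", "total_volume"]


@dataclass
class VolumePanel:
    """Validated subjects x ROIs volume table (mm^3)."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            missing = self.data.isna().stack()
            sid, rid = missing[missing].index[0]
            raise ValueError(f"missing volume for subject {sid}, ROI {rid}")
        if (self.data.to_numpy() <= 0).any():
            bad = (self.data <= 0).stack()
            sid, rid = bad[bad].index[0]
            raise ValueError(f"non-positive volume for subject {sid}, ROI {rid}")

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    @property
    def roi_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def load_volumes(table: pd.DataFrame, phenotypes: pd.DataFrame | None = None) -> VolumePanel:
    """Build a validated panel from long or wide volume input.

    Long input has columns (subject_id, roi_id, volume_mm3); wide input
    is indexed by subject with one column per ROI.  When a phenotype
    table is given the panel is aligned to its subject order and any
    unknown or missing subject raises.
    """
    if {"subject_id", "roi_id", "volume_mm3"}.issubset(table.columns):
        dup = table.duplicated(["subject_id", "roi_id"])
        if dup.any():
            row = table[dup].iloc[0]
            raise ValueError(
                f"duplicate volume row for subject {row['subject_id']}, ROI {row['roi_id']}")
        wide = table.pivot(index="subject_id", columns="roi_id", values="volume_mm3")
    else:
        wide = table.copy()

    if phenotypes is not None:
        expected = list(phenotypes["subject_id"])
        unknown = set(wide.index) - set(expected)
        if unknown:
            raise ValueError(f"unknown subject_id in volume table: {sorted(unknown)[0]}")
        absent = set(expected) - set(wide.index)
        if absent:
            raise ValueError(f"no volumes for subject {sorted(absent)[0]}")
        wide = wide.loc[expected]
    return VolumePanel(data=wide.sort_index(axis=1))


def total_volume(panel: VolumePanel) -> pd.Series:
    """Per-subject whole-brain volume: the sum of ROI volumes (mm^3)."""
    return panel.data.sum(axis=1).rename("total_volume_mm3")
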