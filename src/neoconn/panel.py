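"""Feature panels: per-subject feature tables aligned to phenotype."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeaturePanel", "combine_feature_spaces"]


@dataclass
class FeaturePanel:
    """Subjects x features matrix for one metric, aligned to GA at birth.

    ``x`` is indexed by subject_id with one column per feature (edge
    labels like ``rsfc:3-17`` or ROI labels like ``falff:42``); ``ga``
    holds gestational age at birth (weeks) in the same subject order.
    """

    x: pd.DataFrame = field(repr=False)
    ga: pd.Series = field(repr=False)
    metric_name: str = "custom"

    def __post_init__(self) -> None:
        if not self.x.index.equals(self.ga.index):
            raise ValueError("feature matrix and GA series have mismatched subjects")
        if self.x.isna().any().any():
            raise ValueError("feature panel contains missing values")
        if self.x.columns.duplicated().any():
            dup = self.x.columns[self.x.columns.duplicated()][0]
            raise ValueError(f"duplicated feature id: {dup}")

    @property
    def n_subjects(self) -> int:
        return len(self.x)

    @property
    def n_features(self) -> int:
        return self.x.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return [str(c) for c in self.x.columns]

    @property
    def values(self) -> np.ndarray:
        return self.x.to_numpy(dtype=float)

    @property
    def ga_values(self) -> np.ndarray:
        return self.ga.to_numpy(dtype=float)

    def subset(self, mask: np.ndarray, suffix: str | None = None) -> "FeaturePanel":
        """Column subset by boolean mask over features."""
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self.n_features:
            raise ValueError("mask length does not match feature count")
        name = self.metric_name if suffix is None else f"{self.metric_name}:{suffix}"
        return FeaturePanel(x=self.x.loc[:, mask], ga=self.ga, metric_name=name)

    @staticmethod
    def from_array(values: np.ndarray, ga: np.ndarray, subject_ids: list[str],
                   feature_ids: list[str], metric_name: str) -> "FeaturePanel":
        idx = pd.Index(subject_ids, name="subject_id")
        x = pd.DataFrame(np.asarray(values, dtype=float), index=idx, columns=feature_ids)
        return FeaturePanel(x=x, ga=pd.Series(np.asarray(ga, dtype=float), index=idx,
                                              name="ga_weeks"),
                            metric_name=metric_name)


def combine_feature_spaces(*panels: FeaturePanel, metric_name: str = "combined") -> FeaturePanel:
    """Column-wise concatenation of feature panels over the same subjects.

    Feature ids must be globally unique (they carry metric provenance);
    a subject mismatch or duplicate id raises.  Per-feature scaling is
    left to the model's training-fold standardization.
    """
    if not panels:
        raise ValueError("need at least one panel")
    first = panels[0]
    if len(panels) == 1:
        return first
    for p in panels[1:]:
        if not p.x.index.equals(first.x.index):
            raise ValueError("panels cover different subjects")
        if not np.allclose(p.ga_values, first.ga_values):
            raise ValueError("panels carry inconsistent GA values")
    x = pd.concat([p.x for p in panels], axis=1)
    if x.columns.duplicated().any():
        dup = x.columns[x.columns.duplicated()][0]
        raise ValueError(f"duplicated feature id across panels: {dup}")
    return FeaturePanel(x=x, ga=first.ga, metric_name=metric_name)
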