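"""Brain parcellation atlas: ROI metadata and edge taxonomies.

A 90-region whole-brain parcellation is described by a table of ROI
metadata (hemisphere, lobe group, medial/lateral location, centroid
coordinates and the homotopic partner region in the opposite
hemisphere).  Pairwise connections between ROIs are classified into the
three taxonomies used by grouped connectivity analyses:

* subcortico-cortical vs cortico-cortical (an edge is subcortico-cortical
  if at least one endpoint is subcortical, so subcortical-subcortical
  edges fall in that class and the two classes partition the edge set);
* long-range vs short-range, by a median split of the Euclidean
  distances between ROI centroids (the median element goes to "short");
* homotopic vs non-homotopic (mutually partnered mirror regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LOBES",
    "DEFAULT_LOBE_COUNTS",
    "RoiAtlas",
    "EdgeTaxonomy",
    "generate_atlas",
    "classify_edges",
    "edge_pairs",
]

LOBES = ("subcortical", "frontal", "temporal", "parietal", "occipital")

#: Default number of ROIs per lobe group for the 90-region parcellation.
DEFAULT_LOBE_COUNTS = {
    "subcortical": 8,
    "frontal": 34,
    "temporal": 18,
    "parietal": 16,
    "occipital": 14,
}

# Plausible centroid coordinate ranges (mm, RAS-like) per lobe, used by the
# synthetic atlas generator: (y_range, z_range).
_LOBE_YZ = {
    "subcortical": ((-30.0, 10.0), (-10.0, 20.0)),
    "frontal": ((5.0, 65.0), (-10.0, 60.0)),
    "temporal": ((-45.0, 15.0), (-30.0, 5.0)),
    "parietal": ((-70.0, -20.0), (20.0, 65.0)),
    "occipital": ((-95.0, -55.0), (-10.0, 30.0)),
}


@dataclass
class RoiAtlas:
    """ROI metadata table for an even number of mirror-paired regions.

    The ``table`` has one row per ROI with columns ``roi_id`` (1-based),
    ``name``, ``hemisphere`` ("left"/"right"), ``lobe``, ``medial``
    (bool), ``x``/``y``/``z`` centroid coordinates in mm and
    ``homotopic_partner`` (the partner's ``roi_id``).  Rows are ordered
    by ``roi_id``; all edge vectorization downstream follows this order.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {
            "roi_id", "name", "hemisphere", "lobe", "medial",
            "x", "y", "z", "homotopic_partner",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        t = self.table.sort_values("roi_id").reset_index(drop=True)
        if t["roi_id"].duplicated().any():
            raise ValueError("duplicate roi_id in atlas table")
        bad_lobe = set(t["lobe"]) - set(LOBES)
        if bad_lobe:
            raise ValueError(f"unknown lobe labels: {sorted(bad_lobe)}")
        self.table = t
        self._validate_homotopy()
        cent = self.centroids
        # pairwise-distinct centroids
        d = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.any(d == 0.0):
            raise ValueError("atlas centroids are not pairwise distinct")

    def _validate_homotopy(self) -> None:
        t = self.table
        partners = t.set_index("roi_id")["homotopic_partner"]
        hemi = t.set_index("roi_id")["hemisphere"]
        if partners.isna().any():
            return  # partnerless atlas is allowed; taxonomy will refuse it
        for rid, pid in partners.items():
            if pid not in partners.index:
                raise ValueError(f"ROI {rid}: partner {pid} not in atlas")
            if partners.loc[pid] != rid:
                raise ValueError(f"homotopic pairing is not an involution at ROI {rid}")
            if pid == rid or hemi.loc[pid] == hemi.loc[rid]:
                raise ValueError(f"ROI {rid} and partner {pid} are not in opposite hemispheres")

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def roi_ids(self) -> np.ndarray:
        return self.table["roi_id"].to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def lobes(self) -> np.ndarray:
        return self.table["lobe"].to_numpy()

    @property
    def has_partners(self) -> bool:
        return not self.table["homotopic_partner"].isna().any()

    def lobe_counts(self) -> dict[str, int]:
        return self.table["lobe"].value_counts().to_dict()

    def n_homotopic_pairs(self) -> int:
        return self.n_rois // 2 if self.has_partners else 0


def edge_pairs(n: int) -> list[tuple[int, int]]:
    """Canonical edge order: upper triangle, row-major, 0-based (i < j)."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def _allocate_pairs(n_pairs: int) -> dict[str, int]:
    """Split homotopic pairs across lobes by largest remainder, keeping
    the default 90-ROI proportions (4/17/9/8/7 pairs)."""
    base = {k: v // 2 for k, v in DEFAULT_LOBE_COUNTS.items()}
    total = sum(base.values())
    exact = {k: n_pairs * v / total for k, v in base.items()}
    alloc = {k: int(np.floor(x)) for k, x in exact.items()}
    rem = n_pairs - sum(alloc.values())
    order = sorted(exact, key=lambda k: (exact[k] - np.floor(exact[k]), base[k]), reverse=True)
    for k in order[:rem]:
        alloc[k] += 1
    return alloc


def generate_atlas(n_rois: int = 90, seed: int = 0, jitter_mm: float = 0.4) -> RoiAtlas:
    """Generate a synthetic mirror-paired atlas with ``n_rois`` regions.

    Left-hemisphere centroids are drawn per lobe and mirrored through the
    midline to define homotopic partners; a small isotropic jitter
    (``jitter_mm`` mm, Gaussian) is then added to every centroid so that
    inter-centroid distances are generically distinct (exact mirror
    symmetry would tie every within-hemisphere distance with its
    contralateral twin and make the long/short median split degenerate).

    Subcortical regions are flagged medial; within each cortical lobe
    roughly 40% of pairs are medial (small |x|), the rest lateral.

    Parameters
    ----------
    n_rois : even int >= 4
    seed : int
        Seed for the centroid draws; identical seeds give identical atlases.
    """
    if n_rois % 2 != 0:
        raise ValueError("n_rois must be even: homotopy requires mirror pairs")
    if n_rois < 4:
        raise ValueError("n_rois must be >= 4")
    rng = np.random.default_rng(seed)
    alloc = _allocate_pairs(n_rois // 2)

    rows = []
    rid = 1
    for lobe in LOBES:
        n_pairs = alloc[lobe]
        (y_lo, y_hi), (z_lo, z_hi) = _LOBE_YZ[lobe]
        n_medial = n_pairs if lobe == "subcortical" else int(np.ceil(0.4 * n_pairs))
        for p in range(n_pairs):
            medial = p < n_medial
            x = rng.uniform(3.0, 13.0) if medial else rng.uniform(18.0, 55.0)
            y = rng.uniform(y_lo, y_hi)
            z = rng.uniform(z_lo, z_hi)
            for hemi, sx in (("left", -1.0), ("right", 1.0)):
                rows.append({
                    "roi_id": rid,
                    "name": f"{lobe}_{p + 1}_{hemi[0].upper()}",
                    "hemisphere": hemi,
                    "lobe": lobe,
                    "medial": medial,
                    "x": sx * x,
                    "y": y,
                    "z": z,
                    "homotopic_partner": rid + 1 if hemi == "left" else rid - 1,
                })
                rid += 1
    table = pd.DataFrame(rows)
    jitter = rng.normal(0.0, jitter_mm, size=(len(table), 3))
    table[["x", "y", "z"]] = table[["x", "y", "z"]].to_numpy() + jitter
    return RoiAtlas(table)


@dataclass
class EdgeTaxonomy:
    """Classification of every unordered ROI pair.

    ``table`` has one row per edge in canonical order with columns
    ``i``/``j`` (0-based row positions), ``roi_i``/``roi_j`` (1-based
    ids), ``cortico_class``, ``range_class``, ``homotopy_class`` and
    ``centroid_distance`` (mm).  ``median_distance`` records the split
    point of the long/short partition.
    """

    table: pd.DataFrame = field(repr=False)
    median_distance: float = 0.0

    def counts(self, column: str) -> dict[str, int]:
        return self.table[column].value_counts().to_dict()

    def mask(self, column: str, value: str) -> np.ndarray:
        return (self.table[column] == value).to_numpy()


def classify_edges(atlas: RoiAtlas) -> EdgeTaxonomy:
    """Classify all N(N-1)/2 edges into the three grouped-analysis taxonomies.

    Raises if the atlas carries no homotopic-partner annotations, since a
    silent default would corrupt the homotopic/non-homotopic grouping.
    """
    if not atlas.has_partners:
        raise ValueError("atlas has no homotopic partner annotations; "
                         "homotopy classification unavailable")
    n = atlas.n_rois
    ids = atlas.roi_ids
    lobes = atlas.lobes
    cent = atlas.centroids
    partner = atlas.table.set_index("roi_id")["homotopic_partner"]

    pairs = edge_pairs(n)
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    dist = np.linalg.norm(cent[ii] - cent[jj], axis=1)
    median = float(np.median(dist))

    sub = lobes == "subcortical"
    cortico = np.where(sub[ii] | sub[jj], "subcortico-cortical", "cortico-cortical")
    # median element (and any tie at the median) goes to short-range
    range_class = np.where(dist <= median, "short", "long")
    homo = np.array([
        partner.loc[ids[a]] == ids[b] for a, b in pairs
    ])
    homotopy = np.where(homo, "homotopic", "non-homotopic")

    table = pd.DataFrame({
        "i": ii,
        "j": jj,
        "roi_i": ids[ii],
        "roi_j": ids[jj],
        "cortico_class": cortico,
        "range_class": range_class,
        "homotopy_class": homotopy,
        "centroid_distance": dist,
    })
    return EdgeTaxonomy(table=table, median_distance=median)
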