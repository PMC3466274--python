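"""Coarse-scale pattern information.

At the 10-cluster level of the geometry, each subject's clustering is
compared against the 10-region anatomical atlas (Rand index), and summarised
in 55 regional-connectivity *retention* features: for each of the 10 regions
the fraction of within-region ROI pairs that still share a cluster
(short-range connectivity retained), and for each of the 45 region pairs the
fraction of cross-region ROI pairs that share a cluster (long-range
connectivity retained).  Group differences are screened per feature with
Welch two-sample t-tests; a positive t means more connectivity in the ASD
group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import rand_score

from .core import ClusteringLevel

__all__ = [
    "REGION_ORDER",
    "DEFAULT_REGION_COUNTS",
    "Atlas",
    "CoarseFeatures",
    "ScreenResult",
    "rand_index",
    "coarse_feature_names",
    "retention_features",
    "screen_features",
]

#: canonical region order for feature indexing (fixed for reproducibility)
REGION_ORDER = (
    "Subcortical",
    "Parietal",
    "Occipital",
    "Cerebelum",
    "Frontal",
    "Temporal",
    "Limbic",
    "Insular",
    "Central",
    "Cingulum",
)

#: ROI counts per region of the default 106-ROI, 10-region parcellation
DEFAULT_REGION_COUNTS = {
    "Subcortical": 10,
    "Parietal": 10,
    "Occipital": 14,
    "Cerebelum": 20,
    "Frontal": 22,
    "Temporal": 8,
    "Limbic": 8,
    "Insular": 2,
    "Central": 6,
    "Cingulum": 6,
}


@dataclass(frozen=True)
class Atlas:
    """ROI atlas: each ROI has a name, an anatomical region and xyz coordinates (mm).

    ``table`` is indexed by roi_id with columns roi_name, region, x, y, z.
    """

    table: pd.DataFrame
    region_order: tuple = REGION_ORDER

    def __post_init__(self) -> None:
        required = {"roi_name", "region", "x", "y", "z"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"atlas table missing columns {sorted(missing)}")
        unknown = set(self.table["region"]) - set(self.region_order)
        if unknown:
            raise ValueError(f"regions not in region_order: {sorted(unknown)}")

    @property
    def roi_ids(self) -> tuple:
        return tuple(self.table.index)

    @property
    def n(self) -> int:
        return len(self.table)

    def region_labels(self, roi_ids=None) -> np.ndarray:
        """Integer region label per ROI (position in region_order)."""
        lut = {r: i for i, r in enumerate(self.region_order)}
        rois = self.roi_ids if roi_ids is None else tuple(roi_ids)
        return np.array([lut[self.table.at[r, "region"]] for r in rois])

    def region_counts(self) -> dict:
        counts = self.table["region"].value_counts()
        return {r: int(counts.get(r, 0)) for r in self.region_order}

    def coordinates(self, roi_ids=None) -> np.ndarray:
        rois = self.roi_ids if roi_ids is None else list(roi_ids)
        return self.table.loc[rois, ["x", "y", "z"]].to_numpy(dtype=float)

    @classmethod
    def bundled(cls) -> "Atlas":
        """The packaged 106-ROI atlas (synthetic coordinates, true region sizes)."""
        from importlib.resources import files

        path = files("dcgnet.data").joinpath("atlas106.tsv")
        with path.open() as fh:
            table = pd.read_csv(fh, sep="\t", comment="#", index_col="roi_id")
        return cls(table=table)


def _as_labels(partition, elements=None):
    """Normalise a partition (dict element→label, or aligned label sequence)."""
    if isinstance(partition, dict):
        keys = sorted(partition) if elements is None else list(elements)
        if set(keys) != set(partition):
            raise ValueError("partitions are over different element sets")
        return np.asarray([partition[k] for k in keys]), tuple(keys)
    labels = np.asarray(list(partition))
    return labels, tuple(range(labels.size))


def rand_index(a, b) -> float:
    """Proportion of element pairs on which two partitions concur.

    A pair is concordant when both partitions place it together or both
    place it apart; the index is concordant pairs over all pairs.  Accepts
    dicts mapping element to cluster label (element sets must match) or two
    aligned label sequences.
    """
    if isinstance(a, dict) or isinstance(b, dict):
        if not (isinstance(a, dict) and isinstance(b, dict)):
            raise ValueError("both partitions must be dicts when either is")
        if set(a) != set(b):
            raise ValueError("partitions are over different element sets")
        keys = sorted(a)
        la, _ = _as_labels(a, keys)
        lb, _ = _as_labels(b, keys)
    else:
        la, _ = _as_labels(a)
        lb, _ = _as_labels(b)
        if la.size != lb.size:
            raise ValueError("partitions are over different element sets")
    if la.size < 2:
        raise ValueError("need at least 2 elements")
    return float(rand_score(la, lb))


def coarse_feature_names(region_order=REGION_ORDER) -> list[str]:
    """The 55 feature labels: 10 within-region then 45 between-region pairs."""
    names = [f"within_{r}" for r in region_order]
    names += [f"between_{a}_and_{b}" for a, b in combinations(region_order, 2)]
    return names


@dataclass(frozen=True)
class CoarseFeatures:
    """55 retention proportions for one subject/trial, in canonical order."""

    subject_id: str | None
    trial: str | None
    retention: np.ndarray
    names: tuple

    def __post_init__(self) -> None:
        r = np.asarray(self.retention, dtype=float)
        if r.size != len(self.names):
            raise ValueError("retention length must match names")
        finite = r[np.isfinite(r)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("retention proportions must lie in [0, 1]")
        object.__setattr__(self, "retention", r)
        object.__setattr__(self, "names", tuple(self.names))

    def to_series(self) -> pd.Series:
        return pd.Series(self.retention, index=list(self.names))


def retention_features(
    level: ClusteringLevel, atlas: Atlas, subject_id: str | None = None, trial: str | None = None
) -> CoarseFeatures:
    """Proportion of intra-/inter-regional ROI pairs sharing a cluster.

    For region A the intra feature is the fraction of ROI pairs within A
    that are co-clustered at this level; for regions {A, B} the inter
    feature is the fraction of pairs (i in A, j in B) co-clustered.  A
    region with fewer than 2 ROIs yields an undefined (NaN) intra feature.
    """
    if set(level.roi_ids) != set(atlas.roi_ids):
        raise ValueError("clustering level does not cover the atlas ROIs")
    order = [level.roi_ids.index(r) for r in atlas.roi_ids]
    membership = level.membership[order]
    region = atlas.region_labels()
    same_cluster = membership[:, None] == membership[None, :]
    values: list[float] = []
    n_regions = len(atlas.region_order)
    masks = [region == g for g in range(n_regions)]
    for g in range(n_regions):
        idx = np.flatnonzero(masks[g])
        if idx.size < 2:
            values.append(np.nan)
            continue
        block = same_cluster[np.ix_(idx, idx)]
        n_pairs = idx.size * (idx.size - 1) // 2
        values.append(float(np.triu(block, 1).sum() / n_pairs))
    for g, h in combinations(range(n_regions), 2):
        ia, ib = np.flatnonzero(masks[g]), np.flatnonzero(masks[h])
        if ia.size == 0 or ib.size == 0:
            values.append(np.nan)
            continue
        block = same_cluster[np.ix_(ia, ib)]
        values.append(float(block.mean()))
    return CoarseFeatures(
        subject_id=subject_id,
        trial=trial,
        retention=np.array(values),
        names=tuple(coarse_feature_names(atlas.region_order)),
    )


@dataclass(frozen=True)
class ScreenResult:
    """One screened regional-connectivity feature.

    ``t_statistic`` is signed ASD minus TD: positive means more retained
    connectivity in the ASD group.
    """

    feature: str
    t_statistic: float
    p_value: float

    @property
    def direction(self) -> str:
        return "ASD" if self.t_statistic > 0 else "TD"


def screen_features(asd, td, p_cut: float = 0.105, names=None) -> list[ScreenResult]:
    """Welch two-sample t-test per feature; keep features with p <= p_cut.

    ``asd`` and ``td`` are (subjects x features) arrays or DataFrames.  The
    default cut-off 0.105 retains everything down to the weakest effect the
    screening is meant to catch (raw p, no multiplicity correction — this is
    feature selection, not inference).  Features with zero variance in both
    groups have no defined t and are dropped with a warning.
    """
    if isinstance(asd, pd.DataFrame):
        names = names or list(asd.columns)
        asd = asd.to_numpy(dtype=float)
    if isinstance(td, pd.DataFrame):
        td = td.to_numpy(dtype=float)
    asd, td = np.asarray(asd, float), np.asarray(td, float)
    if asd.ndim != 2 or td.ndim != 2 or asd.shape[1] != td.shape[1]:
        raise ValueError("group matrices must be 2-D with equal column counts")
    if asd.shape[0] < 2 or td.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    names = list(names) if names is not None else coarse_feature_names()
    if len(names) != asd.shape[1]:
        raise ValueError("names length must match feature count")
    results = []
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(asd, td, axis=0, equal_var=False)
    for j, name in enumerate(names):
        if not np.isfinite(t[j]):
            warnings.warn(f"feature {name!r} has zero variance in both groups; skipped")
            continue
        if p[j] <= p_cut:
            results.append(ScreenResult(feature=name, t_statistic=float(t[j]), p_value=float(p[j])))
    return results
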