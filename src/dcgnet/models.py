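"""Model/Results front-end over the pipeline.

`DataCloudGeometry` wraps one subject's correlation matrix the way a
statistical model wraps its data: `fit(temperature)` returns a
:class:`GeometryResults` carrying the sharing matrix, cluster count and
membership at that scale, `fit_trajectory` the count-vs-temperature curve,
and `tune` the level matched to a target cluster count.
`ConnectivityClassifier` wraps a cohort's motif configurations (plus
optional coarse features); `fit()` runs the leave-one-out logistic
procedure and returns its :class:`~dcgnet.classify.ClassificationResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .classify import ClassificationResult, ModelSpec, loocv_classify, tau_sweep
from .coarse import Atlas, rand_index, retention_features
from .core import (
    ClusteringLevel,
    SharingMatrix,
    WalkParams,
    derive_seed,
    level_from_sharing,
    sharing_matrix,
)
from .fine import (
    DEFAULT_PRUNE_HEIGHT,
    FINEST_TEMPERATURE,
    MotifConfiguration,
    motif_configuration,
    motif_configurations,
)
from .matrices import CorrelationMatrix, power_transform
from .tuning import Trajectory, cluster_trajectory, critical_temperatures, tune_to_count

__all__ = [
    "DataCloudGeometry",
    "GeometryResults",
    "TrajectoryResults",
    "ConnectivityClassifier",
    "tuned_levels",
    "coarse_feature_table",
    "rand_index_table",
]


class DataCloudGeometry:
    """Multiscale clustering geometry model for one correlation matrix."""

    def __init__(self, corr: CorrelationMatrix, walk_params: WalkParams | None = None):
        self.corr = corr
        self.walk_params = walk_params or WalkParams()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, walk_params: WalkParams | None = None, **tags):
        return cls(CorrelationMatrix.from_dataframe(df, **tags), walk_params=walk_params)

    def fit(self, temperature: float) -> "GeometryResults":
        """One clustering level at the given temperature."""
        sharing = sharing_matrix(power_transform(self.corr, temperature), self.walk_params)
        level = level_from_sharing(sharing)
        return GeometryResults(model=self, sharing=sharing, level=level)

    def fit_trajectory(self, temperatures=None) -> "TrajectoryResults":
        """Cluster count against temperature over a grid."""
        from .tuning import default_temperature_grid

        temperatures = (
            default_temperature_grid() if temperatures is None else np.asarray(temperatures)
        )
        traj = cluster_trajectory(self.corr, temperatures, self.walk_params)
        return TrajectoryResults(model=self, trajectory=traj)

    def tune(self, k_target: int, temperatures=None) -> "GeometryResults":
        """The level tuned to (about) ``k_target`` clusters."""
        level = tune_to_count(self.corr, k_target, temperatures, self.walk_params)
        sharing = sharing_matrix(
            power_transform(self.corr, level.temperature), self.walk_params
        )
        return GeometryResults(model=self, sharing=sharing, level=level)


@dataclass(frozen=True)
class GeometryResults:
    """A fitted clustering level plus the sharing matrix behind it."""

    model: DataCloudGeometry
    sharing: SharingMatrix
    level: ClusteringLevel

    @property
    def k(self) -> int:
        return self.level.k

    @property
    def membership(self) -> np.ndarray:
        return self.level.membership

    def motifs(self, prune_height: float = DEFAULT_PRUNE_HEIGHT) -> MotifConfiguration:
        """Prune this level's HC tree into motifs (meaningful at fine scale)."""
        return motif_configuration(
            self.sharing,
            prune_height,
            subject_id=self.model.corr.subject_id,
            trial=self.model.corr.trial,
        )

    def rand_index_against(self, atlas: Atlas) -> float:
        region = atlas.region_labels(self.level.roi_ids)
        return rand_index(region, self.level.membership)

    def summary(self) -> str:
        corr = self.model.corr
        sizes = np.bincount(self.level.membership)[1:]
        lines = [
            "Data cloud geometry level",
            "=" * 40,
            f"subject:       {corr.subject_id or '-'} ({corr.group or '-'}/{corr.trial or '-'})",
            f"n ROIs:        {corr.n}",
            f"temperature:   {self.level.temperature:.4g}",
            f"clusters (k):  {self.level.k}"
            + (
                f"  [eigengap estimate {self.level.estimated_k}]"
                if self.level.estimated_k not in (None, self.level.k)
                else ""
            ),
            f"cluster sizes: {sorted(sizes.tolist(), reverse=True)}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class TrajectoryResults:
    """A fitted cluster-count trajectory."""

    model: DataCloudGeometry
    trajectory: Trajectory

    def critical_temperatures(self, fraction: float = 0.5) -> list[float]:
        return critical_temperatures(self.trajectory, fraction)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trajectory.points, columns=["temperature", "k"])

    def summary(self) -> str:
        k = self.trajectory.counts
        crit = self.critical_temperatures()
        lines = [
            "Cluster-count trajectory",
            "=" * 40,
            f"grid: {len(k)} temperatures in [{self.trajectory.temperatures[0]:.4g}, "
            f"{self.trajectory.temperatures[-1]:.4g}]",
            f"k range: {k.max()} -> {k.min()}",
            f"critical temperatures: {[round(t, 4) for t in crit]}",
        ]
        return "\n".join(lines)


def tuned_levels(
    cohort,
    k_target: int = 10,
    temperatures=None,
    params: WalkParams | None = None,
    base_seed: int = 0,
) -> dict:
    """Tune every subject-trial matrix of a cohort to ``k_target`` clusters.

    Returns a dict keyed by (subject_id, trial).  Walk seeds are derived per
    subject-trial from ``base_seed`` so the result is order-independent.
    """
    params = params or WalkParams()
    out = {}
    for (sid, trial), corr in cohort.matrices.items():
        p = replace(params, seed=derive_seed(base_seed, sid, trial))
        out[(sid, trial)] = tune_to_count(corr, k_target, temperatures, p)
    return out


def coarse_feature_table(levels: dict, atlas: Atlas) -> pd.DataFrame:
    """55-column retention-feature table indexed by (subject_id, trial)."""
    rows = {}
    for (sid, trial), level in levels.items():
        rows[(sid, trial)] = retention_features(level, atlas, subject_id=sid, trial=trial).to_series()
    df = pd.DataFrame(rows).T
    df.index.names = ["subject_id", "trial"]
    return df


def rand_index_table(levels: dict, atlas: Atlas) -> pd.Series:
    """Rand index of each tuned level against the anatomical regions."""
    vals = {
        key: rand_index(atlas.region_labels(level.roi_ids), level.membership)
        for key, level in levels.items()
    }
    s = pd.Series(vals)
    s.index.names = ["subject_id", "trial"]
    return s


class ConnectivityClassifier:
    """LOOCV logistic classifier over a cohort's motif configurations."""

    def __init__(self, configs: dict, groups: dict, coarse: pd.DataFrame | None = None):
        self.configs = configs
        self.groups = groups
        self.coarse = coarse

    @classmethod
    def from_cohort(
        cls,
        cohort,
        walk_params: WalkParams | None = None,
        base_seed: int = 0,
        temperature: float = FINEST_TEMPERATURE,
        prune_height: float = DEFAULT_PRUNE_HEIGHT,
        coarse: pd.DataFrame | None = None,
    ) -> "ConnectivityClassifier":
        """Extract fine-scale configurations from a simulated/loaded cohort."""
        configs = motif_configurations(
            cohort.matrices.values(),
            temperature=temperature,
            prune_height=prune_height,
            params=walk_params,
            base_seed=base_seed,
        )
        return cls(configs=configs, groups=dict(cohort.groups), coarse=coarse)

    def fit(self, spec: ModelSpec | None = None, **kwargs) -> ClassificationResult:
        return loocv_classify(self.configs, self.groups, spec=spec, coarse=self.coarse, **kwargs)

    def tau_sweep(self, **kwargs) -> pd.DataFrame:
        return tau_sweep(self.configs, self.groups, coarse=self.coarse, **kwargs)
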