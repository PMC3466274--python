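"""Temperature sweeps: cluster-count trajectories, phase transitions, tuning.

Sweeping the temperature from small to large reveals the evolution of the
clustering structure from fine (many small core clusters) to coarse (one
cluster).  The trajectory of cluster count against temperature typically
shows a high plateau (~50 for the 106-ROI pair structure), a steep drop at a
critical temperature, and a slow decay to 1.  "Tuning" a subject to a target
cluster count picks, from this trajectory, the temperature whose estimated
count is closest to the target, then cuts that temperature's HC tree to the
target — the level with (about) K clusters, comparable across subjects even
though each subject's raw correlation scale is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ClusteringLevel,
    WalkParams,
    estimate_cluster_count,
    level_from_sharing,
    sharing_matrix,
    tree_support,
)
from .matrices import CorrelationMatrix, power_transform

__all__ = [
    "Trajectory",
    "default_temperature_grid",
    "cluster_trajectory",
    "tune_to_count",
    "critical_temperatures",
]


def default_temperature_grid(n_points: int = 40, low: float = 0.001, high: float = 5.0):
    """Logarithmically spaced temperature grid covering fine to coarse scales."""
    return np.geomspace(low, high, n_points)


@dataclass(frozen=True)
class Trajectory:
    """Ordered (temperature, cluster count) pairs for one subject/trial."""

    points: tuple
    subject_id: str | None = None
    trial: str | None = None

    def __post_init__(self) -> None:
        temps = np.array([t for t, _ in self.points], dtype=float)
        if temps.size and np.any(np.diff(temps) <= 0):
            raise ValueError("trajectory temperatures must be strictly increasing")
        object.__setattr__(self, "points", tuple((float(t), int(k)) for t, k in self.points))

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([t for t, _ in self.points])

    @property
    def counts(self) -> np.ndarray:
        return np.array([k for _, k in self.points])


def _sweep(corr: CorrelationMatrix, temperatures, params: WalkParams):
    """Yield (T, sharing matrix, estimated K) along the grid."""
    for t in temperatures:
        p = sharing_matrix(power_transform(corr, float(t)), params)
        yield float(t), p, estimate_cluster_count(p)


def cluster_trajectory(
    corr: CorrelationMatrix, temperatures, params: WalkParams | None = None
) -> Trajectory:
    """Estimated cluster count at each grid temperature.

    Raw per-temperature estimates are reported without smoothing or
    monotonicity enforcement; real trajectories are near-monotone but noisy.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    if temperatures.size == 0:
        raise ValueError("temperature grid is empty")
    params = params or WalkParams()
    points = tuple((t, k) for t, _, k in _sweep(corr, temperatures, params))
    return Trajectory(points=points, subject_id=corr.subject_id, trial=corr.trial)


def tune_to_count(
    corr: CorrelationMatrix,
    k_target: int,
    temperatures=None,
    params: WalkParams | None = None,
) -> ClusteringLevel:
    """Tune one subject's geometry to the level with ``k_target`` clusters.

    Sweeps the grid, selects the temperature whose estimated cluster count
    is closest to ``k_target`` (ties broken toward the lower temperature),
    and cuts that temperature's complete-linkage tree into ``k_target``
    clusters.  The returned level records the achieved label count ``k``
    (which can differ from the request when the tree ties) and keeps the raw
    eigengap estimate in ``estimated_k`` as a diagnostic.
    """
    if temperatures is None:
        temperatures = default_temperature_grid()
    temperatures = np.asarray(temperatures, dtype=float)
    if temperatures.size == 0:
        raise ValueError("temperature grid is empty")
    if not 1 <= k_target <= corr.n:
        raise ValueError(f"k_target must be in [1, {corr.n}]")
    params = params or WalkParams()
    points = list(_sweep(corr, temperatures, params))
    estimates = [k for _, _, k in points]
    if k_target > max(estimates):
        # target beyond the finest attainable count: return the finest
        # supported level at its natural (estimated) cut, lowest T first
        t_star, p_star, k_star = next(
            pt for pt in points if pt[2] == max(estimates)
        )
        level = level_from_sharing(p_star, k=k_star)
    else:
        # gate on tree support: a temperature whose geometry genuinely has
        # ~k_target clusters shows a wide merge-height interval for a
        # k_target-way cut, while fine-plateau and merged-mush temperatures
        # do not.  Among well-supported temperatures, prefer agreement of
        # the eigengap estimate and the achieved cut count with the target,
        # then the lower temperature.
        scored = []
        for t, p, k in points:
            cut = level_from_sharing(p, k=k_target)
            score = abs(k - k_target) + abs(cut.k - k_target)
            scored.append((score, t, cut, k, tree_support(p, k_target)))
        s_max = max(s[4] for s in scored)
        kept = [s for s in scored if s_max == 0 or s[4] >= 0.5 * s_max]
        _, t_star, level, k_star, _ = min(kept, key=lambda s: (s[0], s[1]))
    return ClusteringLevel(
        temperature=t_star,
        k=level.k,
        membership=level.membership,
        roi_ids=level.roi_ids,
        estimated_k=k_star,
    )


def critical_temperatures(traj: Trajectory, fraction: float = 0.5) -> list[float]:
    """Temperatures of the phase transitions in a cluster-count trajectory.

    A transition is the midpoint of a grid interval whose absolute count
    change is at least ``fraction`` of the largest change; a flat trajectory
    has none.
    """
    if len(traj.points) < 2:
        raise ValueError("need at least 2 trajectory points")
    temps = traj.temperatures
    drops = np.abs(np.diff(traj.counts)).astype(float)
    largest = drops.max()
    if largest == 0:
        return []
    hits = np.flatnonzero(drops >= fraction * largest)
    return [float((temps[i] + temps[i + 1]) / 2.0) for i in hits]
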