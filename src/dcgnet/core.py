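"""Data-cloud-geometry core: regulated walks, cluster sharing, one clustering level.

One level of the connectivity clustering geometry is produced in four steps:

1.  power-transform the correlation matrix at temperature ``T``
    (:func:`dcgnet.matrices.power_transform`);
2.  run an ensemble of *regulated random walks* on the similarity graph.
    Each walk moves to an active (not yet removed) node with probability
    proportional to similarity, and a node is removed from the graph when it
    has accumulated ``removal_visits`` visits.  A walk trapped inside a
    tight cluster exhausts that cluster's nodes in a burst of removals
    before escaping, so large gaps in the removal-time sequence delimit
    clusters *for that walk*;
3.  summarise the ensemble in a cluster-sharing probability matrix ``P``:
    entry ``(i, j)`` is the fraction of walks in which ``i`` and ``j`` were
    removed within the same burst (segment);
4.  count clusters spectrally from ``D^{-1/2} P D^{-1/2}`` (eigengap rule)
    and cut a complete-linkage HC tree on dissimilarity ``1 - P`` to that
    count.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .matrices import SYMMETRY_TOL, CorrelationMatrix, SimilarityMatrix, power_transform

__all__ = [
    "WalkParams",
    "WalkRecord",
    "SharingMatrix",
    "ClusteringLevel",
    "run_regulated_walk",
    "sharing_matrix",
    "estimate_cluster_count",
    "cluster_level",
    "level_from_sharing",
]


@dataclass(frozen=True)
class WalkParams:
    """Knobs of the regulated-walk ensemble.

    removal_visits : visits a node tolerates before it is removed (m >= 1).
    n_walks        : ensemble size per sharing matrix.
    gap_factor     : c in the segment-boundary rule gap > mean + c * sd.
    seed           : base seed; each walk w uses SeedSequence([seed, w]).
    """

    removal_visits: int = 3
    n_walks: int = 100
    gap_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.removal_visits < 1:
            raise ValueError("removal_visits must be >= 1")
        if self.n_walks < 1:
            raise ValueError("n_walks must be >= 1")
        if self.gap_factor <= 0:
            raise ValueError("gap_factor must be positive")


@dataclass(frozen=True)
class WalkRecord:
    """Removal bookkeeping of a single regulated walk.

    ``removal_order[k]`` is the k-th node removed, at global step
    ``removal_steps[k]`` (strictly increasing).  ``segments`` partitions the
    removal order into bursts separated by large removal-time gaps.
    """

    removal_order: np.ndarray
    removal_steps: np.ndarray
    segments: tuple

    def segment_labels(self) -> np.ndarray:
        """Per-node segment index (0-based), aligned with node indices."""
        n = self.removal_order.size
        labels = np.empty(n, dtype=int)
        for s, seg in enumerate(self.segments):
            labels[np.asarray(seg)] = s
        return labels


@dataclass(frozen=True)
class SharingMatrix:
    """Cluster-sharing probabilities: (i, j) = co-segment frequency over walks."""

    values: np.ndarray
    temperature: float
    n_walks: int
    roi_ids: tuple = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.abs(v - v.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValueError("sharing matrix must be symmetric")
        roi_ids = tuple(self.roi_ids) or tuple(range(1, v.shape[0] + 1))
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "roi_ids", roi_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ClusteringLevel:
    """One level of the geometry: temperature, cluster count, membership.

    ``membership`` maps node position to a cluster label in ``1..k`` with
    every label used; labels are canonicalised by order of first appearance.
    """

    temperature: float
    k: int
    membership: np.ndarray
    roi_ids: tuple = ()
    #: eigengap estimate at this temperature, when it differs from the cut count
    estimated_k: int | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.membership, dtype=int)
        labels = np.unique(m)
        if not np.array_equal(labels, np.arange(1, self.k + 1)):
            raise ValueError(f"membership labels must be 1..{self.k}, each used")
        roi_ids = tuple(self.roi_ids) or tuple(range(1, m.size + 1))
        if len(roi_ids) != m.size:
            raise ValueError("roi_ids length mismatch")
        object.__setattr__(self, "membership", m)
        object.__setattr__(self, "roi_ids", roi_ids)

    def clusters(self) -> list:
        """Clusters as lists of ROI ids, in label order."""
        out = []
        for lab in range(1, self.k + 1):
            out.append([self.roi_ids[i] for i in np.flatnonzero(self.membership == lab)])
        return out


@njit(cache=True)
def _walk_kernel(S, m, seed):  # pragma: no cover - exercised via run_regulated_walk
    np.random.seed(seed)
    n = S.shape[0]
    active = np.ones(n, dtype=np.bool_)
    visits = np.zeros(n, dtype=np.int64)
    order = np.empty(n, dtype=np.int64)
    steps = np.empty(n, dtype=np.int64)
    removed = 0
    current = np.random.randint(0, n)
    step = 1
    visits[current] = 1
    while True:
        if active[current] and visits[current] >= m:
            active[current] = False
            order[removed] = current
            steps[removed] = step
            removed += 1
            if removed == n:
                break
        # transition out of `current` (whether or not it was just removed):
        # proportional to similarity restricted to active nodes
        total = 0.0
        for j in range(n):
            if active[j] and j != current:
                total += S[current, j]
        if total > 0.0:
            r = np.random.random() * total
            acc = 0.0
            nxt = -1
            for j in range(n):
                if active[j] and j != current:
                    acc += S[current, j]
                    if acc >= r:
                        nxt = j
                        break
            if nxt == -1:  # float round-off at the tail
                for j in range(n - 1, -1, -1):
                    if active[j] and j != current:
                        nxt = j
                        break
        else:
            # dead end (all-zero active similarity row): restart uniformly
            k = 0
            for j in range(n):
                if active[j]:
                    k += 1
            pick = np.random.randint(0, k)
            nxt = -1
            k = 0
            for j in range(n):
                if active[j]:
                    if k == pick:
                        nxt = j
                        break
                    k += 1
        current = nxt
        step += 1
        visits[current] += 1
    return order, steps


def _bimodal_split(gaps: np.ndarray) -> float | None:
    """Threshold separating small from large gaps by maximal between-class variance.

    Returns ``None`` when the gaps are all equal (no split possible).
    """
    vals = np.sort(gaps)
    n = vals.size
    if vals[0] == vals[-1]:
        return None
    cum = np.cumsum(vals)
    best, threshold = -1.0, None
    for k in range(1, n):
        if vals[k] == vals[k - 1]:
            continue
        w0 = k / n
        m0 = cum[k - 1] / k
        m1 = (cum[-1] - cum[k - 1]) / (n - k)
        sb = w0 * (1.0 - w0) * (m0 - m1) ** 2
        if sb > best:
            best, threshold = sb, (vals[k - 1] + vals[k]) / 2.0
    return threshold


def _segments_from_steps(order: np.ndarray, steps: np.ndarray, gap_factor: float) -> tuple:
    """Cut the removal sequence into bursts at large removal-time gaps.

    Cluster exhaustion shows up as runs of closely spaced removals separated
    by long wandering gaps, so the gap distribution is split into a small and
    a large class at the threshold maximising between-class variance, and
    boundaries are placed at large-class gaps.  As a guard against slicing a
    homogeneous removal stream (a single cluster), cuts are applied only when
    the largest gap exceeds ``mean + gap_factor * sd`` of all gaps — i.e.
    when the gap distribution has a genuine heavy tail.
    """
    n = order.size
    if n <= 1:
        return (tuple(order.tolist()),)
    gaps = np.diff(steps).astype(float)
    threshold = _bimodal_split(gaps)
    if threshold is None or gaps.max() <= gaps.mean() + gap_factor * gaps.std():
        return (tuple(order.tolist()),)
    cut_after = np.flatnonzero(gaps > threshold)
    segments = []
    start = 0
    for c in cut_after:
        segments.append(tuple(order[start : c + 1].tolist()))
        start = c + 1
    segments.append(tuple(order[start:].tolist()))
    return tuple(segments)


def derive_seed(base_seed: int, *parts) -> int:
    """Derive a reproducible 32-bit seed from a base seed and context parts.

    Parts may be ints, floats (keyed by their bit pattern) or strings
    (CRC-hashed), so one run seed can deterministically fan out per
    (subject, trial, temperature) without collisions.
    """
    ints = [int(base_seed) & 0xFFFFFFFF]
    for p in parts:
        if isinstance(p, (int, np.integer)):
            ints.append(int(p) & 0xFFFFFFFF)
        elif isinstance(p, float):
            bits = int(np.float64(p).view(np.uint64))
            ints.extend([bits & 0xFFFFFFFF, bits >> 32])
        else:
            ints.append(zlib.crc32(str(p).encode()))
    return int(np.random.SeedSequence(ints).generate_state(1)[0])


def _walk_seed(base_seed: int, walk_index: int) -> int:
    # stable 32-bit stream per (base seed, walk index)
    return int(np.random.SeedSequence([int(base_seed), int(walk_index)]).generate_state(1)[0])


def run_regulated_walk(sim: SimilarityMatrix, params: WalkParams, seed: int) -> WalkRecord:
    """Run one regulated random walk until every node has been removed.

    From the current node the walk moves to an active node ``j`` with
    probability proportional to ``s(current, j)``; a node is removed upon its
    ``removal_visits``-th visit; when the current node's active similarity
    row is all zero the walk restarts at a uniformly random active node.
    Segment boundaries are placed between consecutive removals whose step gap
    exceeds ``mean + gap_factor * sd`` of all gaps in the walk.
    """
    if sim.n < 2:
        raise ValueError("need at least 2 nodes to walk")
    order, steps = _walk_kernel(
        np.ascontiguousarray(sim.values), int(params.removal_visits), int(seed) % (2**32)
    )
    segments = _segments_from_steps(order, steps, params.gap_factor)
    return WalkRecord(removal_order=order, removal_steps=steps, segments=segments)


def sharing_matrix(sim: SimilarityMatrix, params: WalkParams) -> SharingMatrix:
    """Aggregate ``params.n_walks`` regulated walks into co-segment frequencies.

    Deterministic for a fixed ``params.seed``: walk ``w`` draws its RNG
    stream from ``SeedSequence([seed, w])``.
    """
    n = sim.n
    counts = np.zeros((n, n))
    seed_t = derive_seed(params.seed, float(sim.temperature))
    for w in range(params.n_walks):
        record = run_regulated_walk(sim, params, seed=_walk_seed(seed_t, w))
        for seg in record.segments:
            idx = np.asarray(seg)
            counts[np.ix_(idx, idx)] += 1.0
    p = counts / params.n_walks
    np.fill_diagonal(p, 1.0)
    return SharingMatrix(
        values=p, temperature=sim.temperature, n_walks=params.n_walks, roi_ids=sim.roi_ids
    )


def estimate_cluster_count(sharing: SharingMatrix | np.ndarray, tol: float = 1e-8) -> int:
    """Number of clusters from the spectrum of ``D^{-1/2} P D^{-1/2}``.

    Eigenvalues are sorted in decreasing order and the count is the number
    lying above the largest consecutive gap — the significantly non-zero
    part of the normalised spectrum.  A flat spectrum (no gap above ``tol``,
    e.g. the identity matrix) falls back to counting eigenvalues above
    ``tol``, so ``n`` mutually unrelated nodes give ``n`` clusters.
    """
    p = sharing.values if isinstance(sharing, SharingMatrix) else np.asarray(sharing, float)
    if np.abs(p - p.T).max(initial=0.0) > SYMMETRY_TOL:
        raise ValueError("sharing matrix must be symmetric")
    n = p.shape[0]
    if n == 1:
        return 1
    d = p.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)  # diagonal is 1, so d >= 1 always
    m = inv_sqrt[:, None] * p * inv_sqrt[None, :]
    lam = np.sort(np.linalg.eigvalsh((m + m.T) / 2.0))[::-1]
    gaps = lam[:-1] - lam[1:]
    if gaps.max() <= tol:
        return max(1, int(np.sum(lam > tol)))
    return int(np.argmax(gaps)) + 1


def _canonical_relabel(raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Relabel to 1..k by order of first appearance."""
    labels: dict[int, int] = {}
    out = np.empty(raw.size, dtype=int)
    for i, lab in enumerate(raw):
        out[i] = labels.setdefault(int(lab), len(labels) + 1)
    return out, len(labels)


def level_from_sharing(sharing: SharingMatrix, k: int | None = None) -> ClusteringLevel:
    """Cut the complete-linkage HC tree on ``1 - P`` into ``k`` clusters.

    ``k`` defaults to :func:`estimate_cluster_count`; the achieved count can
    differ from the request when the tree has ties, and is reported as-is.
    """
    if k is None:
        k = estimate_cluster_count(sharing)
    n = sharing.n
    if n == 1 or k >= n:
        raw = np.arange(1, n + 1)
    elif k <= 1:
        raw = np.ones(n, dtype=int)
    else:
        diss = np.clip(1.0 - sharing.values, 0.0, None)
        np.fill_diagonal(diss, 0.0)
        z = linkage(squareform(diss, checks=False), method="complete")
        raw = fcluster(z, t=k, criterion="maxclust")
    membership, achieved = _canonical_relabel(np.asarray(raw))
    return ClusteringLevel(
        temperature=sharing.temperature, k=achieved, membership=membership, roi_ids=sharing.roi_ids
    )


def tree_support(sharing: SharingMatrix, k: int) -> float:
    """Width of the merge-height interval over which the HC tree has exactly k clusters.

    A temperature whose geometry genuinely contains ``k`` clusters shows a
    wide gap between the last within-cluster merge and the first
    between-cluster merge; heavily tied trees at off-scale temperatures
    have zero width.  ``k = 1`` is always supported (infinite width).
    """
    n = sharing.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if k == 1 or n == 1:
        return np.inf
    diss = np.clip(1.0 - sharing.values, 0.0, None)
    np.fill_diagonal(diss, 0.0)
    heights = np.sort(linkage(squareform(diss, checks=False), method="complete")[:, 2])
    lower = 0.0 if k == n else heights[n - k - 1]
    return float(heights[n - k] - lower)


def cluster_level(
    corr: CorrelationMatrix, temperature: float, params: WalkParams
) -> ClusteringLevel:
    """One level of connectivity clustering geometry at a given temperature."""
    sim = power_transform(corr, temperature)
    return level_from_sharing(sharing_matrix(sim, params))
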