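"""Synthetic cohorts of correlation matrices with planted multiscale structure.

Each simulated subject's matrix is built on three nested connectivity
levels, mimicking functional connectivity organised by brain anatomy:

* a baseline correlation between any two ROIs (default 0.10);
* elevated within-region correlation for the 10 anatomical regions
  (default 0.45);
* near-perfect correlation inside planted *motifs* — left/right ROI pairs
  (default 0.90) — each included independently per subject with a
  group-specific probability, which is what creates group-differential
  motif prevalence.

Group-level regional shifts (more or less connectivity between chosen
region pairs in one group) plant the coarse-scale signal.  Symmetric
Gaussian noise is added, the diagonal reset, and the matrix repaired to the
nearest valid correlation matrix by eigenvalue clipping when needed.  The
generator returns the ground truth (included motifs, region labels)
alongside every matrix, so each pipeline stage can be scored without any
real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coarse import DEFAULT_REGION_COUNTS, Atlas
from .core import derive_seed
from .matrices import CorrelationMatrix

__all__ = [
    "CohortDesign",
    "Cohort",
    "make_atlas",
    "default_motifs",
    "strong_signal_design",
    "null_design",
    "simulate_subject",
    "simulate_cohort",
]


def make_atlas(counts: dict | None = None) -> Atlas:
    """Build an ROI atlas from region sizes, with synthetic coordinates.

    ROI ids are sequential 1-based integers grouped into regions in the
    given order (default: the 10-region parcellation with 106 ROIs).
    Coordinates are deterministic synthetic placeholders: regions sit at
    distinct centres and consecutive (odd, even) ROI pairs mirror left/right
    across the x = 0 midline, emulating bilateral homologue pairs.
    """
    counts = dict(counts) if counts is not None else dict(DEFAULT_REGION_COUNTS)
    for region, c in counts.items():
        if c <= 0:
            raise ValueError(f"region {region!r} must have a positive ROI count")
    rows = []
    roi = 1
    n_regions = len(counts)
    for g, (region, c) in enumerate(counts.items()):
        angle = 2.0 * np.pi * g / max(n_regions, 1)
        cy, cz = 60.0 * np.cos(angle), 60.0 * np.sin(angle)
        for i in range(c):
            side = "L" if i % 2 == 0 else "R"
            x = -30.0 - 2.0 * (i // 2) if side == "L" else 30.0 + 2.0 * (i // 2)
            rows.append(
                {
                    "roi_id": roi,
                    "roi_name": f"{region}_{i // 2 + 1}_{side}",
                    "region": region,
                    "x": round(x, 1),
                    "y": round(cy + 3.0 * (i // 2), 1),
                    "z": round(cz - 3.0 * (i // 2), 1),
                }
            )
            roi += 1
    table = pd.DataFrame(rows).set_index("roi_id")
    return Atlas(table=table, region_order=tuple(counts))


def default_motifs(n_rois: int = 106) -> tuple:
    """Consecutive (odd, even) ROI pairs — the left/right homologue pattern."""
    return tuple((2 * k + 1, 2 * k + 2) for k in range(n_rois // 2))


@dataclass(frozen=True)
class CohortDesign:
    """Generative settings for one synthetic cohort.

    ``inclusion`` maps each motif to its (ASD, TD) per-subject inclusion
    probability; motifs not listed use ``base_inclusion``.  ``regional_shifts``
    is a tuple of ``(region_a, region_b, group, delta)`` adding ``delta`` to
    that region-pair's correlations for subjects of ``group`` (``region_a ==
    region_b`` shifts within-region connectivity).  The default design is the
    strong-signal cohort: eight discriminating motifs with a prevalence gap
    of about 22 of 29 subjects, plus two modest regional shifts.
    """

    n_per_group: int = 29
    trials: tuple = ("green", "red")
    region_counts: dict = field(default_factory=lambda: dict(DEFAULT_REGION_COUNTS))
    motifs: tuple = ()
    base_inclusion: float = 0.7
    inclusion: dict = field(default_factory=dict)
    within_motif: float = 0.9
    within_region: float = 0.45
    baseline: float = 0.1
    regional_shifts: tuple = (
        ("Subcortical", "Frontal", "ASD", 0.08),
        ("Occipital", "Occipital", "ASD", -0.08),
    )
    noise_sd: float = 0.05
    red_noise_factor: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.motifs:
            n = sum(self.region_counts.values())
            object.__setattr__(self, "motifs", default_motifs(n))
        default_shifts = type(self).__dataclass_fields__["regional_shifts"].default
        if self.regional_shifts == default_shifts:
            # reduced atlases silently drop default shifts naming absent regions
            object.__setattr__(
                self,
                "regional_shifts",
                tuple(
                    s
                    for s in self.regional_shifts
                    if s[0] in self.region_counts and s[1] in self.region_counts
                ),
            )
        if not self.inclusion:
            object.__setattr__(self, "inclusion", _default_inclusion(self.motifs))
        if not (self.within_motif >= self.within_region >= self.baseline):
            raise ValueError(
                "infeasible level ordering: need within_motif >= within_region >= baseline"
            )
        probs = np.array(list(self.inclusion.values()), dtype=float)
        if probs.size and (probs.min() < 0 or probs.max() > 1):
            raise ValueError("inclusion probabilities must lie in [0, 1]")
        for a, b, group, _ in self.regional_shifts:
            for r in (a, b):
                if r not in self.region_counts:
                    raise ValueError(f"unknown region {r!r} in regional_shifts")

    @property
    def n_rois(self) -> int:
        return sum(self.region_counts.values())

    def inclusion_for(self, motif, group: str) -> float:
        pair = self.inclusion.get(tuple(sorted(motif)), (self.base_inclusion, self.base_inclusion))
        return pair[0] if group == "ASD" else pair[1]


def _default_inclusion(motifs, n_discriminating: int = 4, gap=(0.85, 0.10)) -> dict:
    """Strong-signal inclusion map: 4 ASD-enriched and 4 TD-enriched motifs."""
    motifs = [tuple(sorted(m)) for m in motifs]
    n_discriminating = min(n_discriminating, len(motifs) // 2)
    if n_discriminating == 0:
        return {}
    step = max(len(motifs) // (2 * n_discriminating + 1), 1)
    inclusion = {}
    for i in range(n_discriminating):
        inclusion[motifs[(2 * i) * step]] = gap  # ASD-enriched
        inclusion[motifs[(2 * i + 1) * step]] = gap[::-1]  # TD-enriched
    return inclusion


def strong_signal_design(**overrides) -> CohortDesign:
    """The default cohort: planted motif-prevalence gaps and regional shifts."""
    return CohortDesign(**overrides)


def null_design(**overrides) -> CohortDesign:
    """A cohort with no group differences anywhere (chance-level classification)."""
    base = CohortDesign(**overrides)
    flat = {tuple(sorted(m)): (base.base_inclusion, base.base_inclusion) for m in base.motifs}
    return replace(base, inclusion=flat, regional_shifts=())


def _region_labels(design: CohortDesign) -> np.ndarray:
    return np.concatenate(
        [np.full(c, g) for g, c in enumerate(design.region_counts.values())]
    )


def simulate_subject(
    design: CohortDesign,
    group: str,
    trial: str,
    subject_index: int,
    seed: int | None = None,
) -> tuple[CorrelationMatrix, frozenset]:
    """One subject-trial correlation matrix plus its planted ground truth.

    Deterministic in ``(design.seed, group, trial, subject_index)`` unless an
    explicit ``seed`` overrides the design seed.  Returns the validated
    matrix and the frozen set of motifs actually included for this subject.
    """
    base = design.seed if seed is None else seed
    rng = np.random.default_rng(derive_seed(base, group, trial, subject_index))
    n = design.n_rois
    region = _region_labels(design)
    values = np.full((n, n), design.baseline)
    for g in range(len(design.region_counts)):
        idx = np.flatnonzero(region == g)
        values[np.ix_(idx, idx)] = design.within_region
    region_index = {r: g for g, r in enumerate(design.region_counts)}
    for a, b, shift_group, delta in design.regional_shifts:
        if shift_group != group:
            continue
        ia = np.flatnonzero(region == region_index[a])
        ib = np.flatnonzero(region == region_index[b])
        values[np.ix_(ia, ib)] += delta
        if a != b:
            values[np.ix_(ib, ia)] += delta
    included = []
    for motif in design.motifs:
        if rng.random() < design.inclusion_for(motif, group):
            included.append(frozenset(motif))
            idx = np.array(sorted(motif)) - 1  # ROI ids are 1-based
            block = values[np.ix_(idx, idx)]
            values[np.ix_(idx, idx)] = np.maximum(block, design.within_motif)
    sd = design.noise_sd * (design.red_noise_factor if trial == "red" else 1.0)
    if sd > 0:
        noise = rng.normal(0.0, sd, (n, n))
        values += (noise + noise.T) / np.sqrt(2.0)
    values = np.clip(values, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    values = _nearest_valid_correlation(values)
    corr = CorrelationMatrix(
        values=values,
        roi_ids=tuple(range(1, n + 1)),
        subject_id=f"{group}{subject_index + 1:02d}",
        group=group,
        trial=trial,
    )
    return corr, frozenset(included)


def _nearest_valid_correlation(values: np.ndarray) -> np.ndarray:
    """Eigenvalue-clip to positive semidefinite, then renormalise the diagonal."""
    w, v = np.linalg.eigh((values + values.T) / 2.0)
    if w.min() >= -1e-10:
        return values
    w = np.clip(w, 0.0, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    d[d == 0] = 1.0
    repaired = repaired / np.outer(d, d)
    repaired = np.clip((repaired + repaired.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(repaired, 1.0)
    return repaired


@dataclass(frozen=True)
class Cohort:
    """All subject-trial matrices of one simulated study, with ground truth.

    ``matrices[(subject_id, trial)]`` holds the correlation matrices and
    ``truth[(subject_id, trial)]`` the planted motif sets; ``groups`` maps
    subject_id to its group label.
    """

    design: CohortDesign
    atlas: Atlas
    groups: dict
    matrices: dict
    truth: dict

    @property
    def subject_ids(self) -> tuple:
        return tuple(self.groups)

    def matrices_for(self, trial: str) -> list:
        return [m for (sid, tr), m in self.matrices.items() if tr == trial]

    def truth_ledger(self) -> pd.DataFrame:
        """One row per planted motif per subject-trial."""
        rows = [
            {"subject_id": sid, "trial": tr, "motif": ",".join(map(str, sorted(m)))}
            for (sid, tr), motifs in self.truth.items()
            for m in sorted(motifs, key=sorted)
        ]
        return pd.DataFrame(rows, columns=["subject_id", "trial", "motif"])


def simulate_cohort(design: CohortDesign | None = None) -> Cohort:
    """Simulate the full two-group cohort over all trials."""
    design = design or CohortDesign()
    atlas = make_atlas(design.region_counts)
    groups: dict = {}
    matrices: dict = {}
    truth: dict = {}
    for group in ("ASD", "TD"):
        for i in range(design.n_per_group):
            for trial in design.trials:
                corr, included = simulate_subject(design, group, trial, i)
                groups[corr.subject_id] = group
                matrices[(corr.subject_id, trial)] = corr
                truth[(corr.subject_id, trial)] = included
    return Cohort(design=design, atlas=atlas, groups=groups, matrices=matrices, truth=truth)
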