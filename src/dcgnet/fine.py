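"""Fine-scale pattern information: motifs, domains, prevalence, features.

At the finest scale (temperature 0.001) only near-perfect correlations keep
non-negligible similarity, and the bottom level of the geometry consists of
~50 small core clusters — *motifs*, typically left/right ROI pairs.  The
motif configurations of a group's subjects form a group-trial *motif
domain*, characterised by each motif's prevalence (how many of the group's
subjects carry it).  A subject's fine-scale features relate its own
configuration to the two groups' prevalence-restricted domains:

* an odds score — the summed log prevalence ratio (ASD over TD) of the
  subject's motifs present in both restricted domains, and
* two missing-motif counts — how many of the subject's motifs are absent
  from each restricted domain.

The exact functional forms of the odds and the predictor transformation
are not fully specified in the method's original description; the
log-ratio sum and the miss-count difference used here are documented
stand-ins chosen to be monotone in the described odds and to use all six
components (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import log

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import SharingMatrix, WalkParams, derive_seed, sharing_matrix
from .matrices import power_transform

__all__ = [
    "FINEST_TEMPERATURE",
    "DEFAULT_PRUNE_HEIGHT",
    "Motif",
    "MotifConfiguration",
    "MotifDomain",
    "FineFeatures",
    "motif_configuration",
    "motif_configurations",
    "motif_domain",
    "restrict_domain",
    "odds_score",
    "missing_counts",
    "fine_feature_vector",
]

#: the finest focal scale: similarities collapse except near-perfect correlations
FINEST_TEMPERATURE = 0.001
#: dissimilarity height at which the fine-scale HC tree is pruned into motifs
DEFAULT_PRUNE_HEIGHT = 0.85

#: a motif is identified canonically by its frozen set of ROI ids
Motif = frozenset


def canonical_motif(rois) -> frozenset:
    return frozenset(rois)


@dataclass(frozen=True)
class MotifConfiguration:
    """A subject/trial's set of motifs (pairwise-disjoint ROI sets, size >= 2)."""

    subject_id: str | None
    trial: str | None
    motifs: frozenset

    def __post_init__(self) -> None:
        motifs = frozenset(canonical_motif(m) for m in self.motifs)
        seen: set = set()
        for m in motifs:
            if len(m) < 2:
                raise ValueError("motifs must have at least 2 ROIs (no singletons)")
            if seen & m:
                raise ValueError("motifs within one configuration must be disjoint")
            seen |= m
        object.__setattr__(self, "motifs", motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    def __contains__(self, motif) -> bool:
        return canonical_motif(motif) in self.motifs


@dataclass(frozen=True)
class MotifDomain:
    """Group-trial ensemble of motifs with a prevalence function.

    ``prevalence[m]`` counts the member subjects whose configuration
    contains motif ``m`` (exact set identity).
    """

    group: str | None
    trial: str | None
    prevalence: dict
    n_subjects: int = 0

    def __post_init__(self) -> None:
        prev = {canonical_motif(m): int(c) for m, c in self.prevalence.items()}
        for m, c in prev.items():
            if c < 1:
                raise ValueError("prevalence counts must be >= 1")
            if self.n_subjects and c > self.n_subjects:
                raise ValueError("prevalence cannot exceed the number of subjects")
        object.__setattr__(self, "prevalence", prev)

    def __contains__(self, motif) -> bool:
        return canonical_motif(motif) in self.prevalence

    def __len__(self) -> int:
        return len(self.prevalence)

    @property
    def motifs(self) -> set:
        return set(self.prevalence)


def motif_configuration(
    p_fine: SharingMatrix,
    prune_height: float = DEFAULT_PRUNE_HEIGHT,
    subject_id: str | None = None,
    trial: str | None = None,
) -> MotifConfiguration:
    """Prune the fine-scale HC tree into motifs.

    The complete-linkage tree on dissimilarity ``1 - P`` is cut at
    ``prune_height``; branches with at least 2 members become motifs
    (singletons are excluded).  A sharing matrix with no off-diagonal mass
    yields an empty configuration.
    """
    if not 0 < prune_height <= 1:
        raise ValueError("prune_height must be in (0, 1]")
    n = p_fine.n
    if n < 2:
        return MotifConfiguration(subject_id=subject_id, trial=trial, motifs=frozenset())
    diss = np.clip(1.0 - p_fine.values, 0.0, None)
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method="complete")
    labels = fcluster(z, t=prune_height, criterion="distance")
    motifs = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if members.size >= 2:
            motifs.append(canonical_motif(p_fine.roi_ids[i] for i in members))
    return MotifConfiguration(subject_id=subject_id, trial=trial, motifs=frozenset(motifs))


def motif_configurations(
    matrices,
    temperature: float = FINEST_TEMPERATURE,
    prune_height: float = DEFAULT_PRUNE_HEIGHT,
    params: WalkParams | None = None,
    base_seed: int = 0,
) -> dict:
    """Fine-scale configurations for a collection of correlation matrices.

    Returns a dict keyed by (subject_id, trial).  Each matrix gets its own
    walk seed derived from ``base_seed`` and its tags, so results are
    reproducible and independent of iteration order.
    """
    params = params or WalkParams()
    out = {}
    for corr in matrices:
        seed = derive_seed(base_seed, corr.subject_id or "", corr.trial or "", float(temperature))
        p = sharing_matrix(power_transform(corr, temperature), replace(params, seed=seed))
        out[(corr.subject_id, corr.trial)] = motif_configuration(
            p, prune_height, subject_id=corr.subject_id, trial=corr.trial
        )
    return out


def motif_domain(configs, group: str | None = None, trial: str | None = None) -> MotifDomain:
    """Assemble member configurations into a domain with prevalence counts.

    All configurations must come from one trial; pass ``group`` to label
    the domain.
    """
    configs = list(configs)
    trials = {c.trial for c in configs}
    if len(trials) > 1:
        raise ValueError(f"mixed trials in one domain: {sorted(map(str, trials))}")
    prevalence: dict = {}
    for c in configs:
        for m in c.motifs:
            prevalence[m] = prevalence.get(m, 0) + 1
    return MotifDomain(
        group=group,
        trial=trial if trial is not None else (trials.pop() if trials else None),
        prevalence=prevalence,
        n_subjects=len(configs),
    )


def restrict_domain(dom: MotifDomain, tau: int) -> MotifDomain:
    """Keep only motifs with prevalence >= tau (the restricted motif domain)."""
    if tau < 1:
        raise ValueError("tau must be >= 1")
    kept = {m: c for m, c in dom.prevalence.items() if c >= tau}
    return MotifDomain(group=dom.group, trial=dom.trial, prevalence=kept, n_subjects=dom.n_subjects)


def odds_score(config: MotifConfiguration, dom_asd: MotifDomain, dom_td: MotifDomain) -> float:
    """Summed log prevalence ratio (ASD over TD) of motifs present in both domains.

    A motif carried by 10 of 29 ASD but 21 of 29 TD subjects contributes
    ``log(10/21) < 0`` — the subject is about twice as likely to come from
    the TD group on that motif's evidence.  Motifs absent from either
    restricted domain contribute nothing; an empty intersection gives 0.

    When both domains record their member count, prevalences are compared
    as per-subject proportions.  This matters under the jackknife: the
    subject's own group's domain has one fewer member, and raw counts would
    then be systematically lower on the own-group side for every subject —
    an artifact that encodes group membership itself.  With equal-sized
    domains the proportion ratio reduces exactly to the count ratio.
    """
    na, nt = dom_asd.n_subjects, dom_td.n_subjects
    scale = log(nt / na) if na > 0 and nt > 0 else 0.0
    total = 0.0
    for m in config.motifs:
        if m in dom_asd and m in dom_td:
            total += log(dom_asd.prevalence[m] / dom_td.prevalence[m]) + scale
    return total


def missing_counts(
    config: MotifConfiguration, dom_asd: MotifDomain, dom_td: MotifDomain
) -> tuple[int, int]:
    """How many of the subject's motifs are absent from each restricted domain."""
    miss_asd = sum(1 for m in config.motifs if m not in dom_asd)
    miss_td = sum(1 for m in config.motifs if m not in dom_td)
    return miss_asd, miss_td


@dataclass(frozen=True)
class FineFeatures:
    """Per-trial fine-scale components and the derived predictor vector.

    ``components[trial] = (odds, miss_asd, miss_td)``; with both trials this
    is the six-dimensional fine-scale pattern information.  The predictors
    are, per trial, the odds score and the miss-count difference
    ``miss_td - miss_asd`` (positive when the subject lacks TD-typical
    motifs, pointing toward ASD).
    """

    subject_id: str
    components: dict

    def predictors(self, trials=("green", "red")) -> np.ndarray:
        out = []
        for t in trials:
            if t not in self.components:
                raise KeyError(f"no fine features for trial {t!r}")
            odds, miss_asd, miss_td = self.components[t]
            out.extend([odds, miss_td - miss_asd])
        return np.asarray(out, dtype=float)


def fine_feature_vector(
    subject_id: str,
    configs: dict,
    groups: dict,
    tau: int,
    trials=("green", "red"),
    exclude: tuple = (),
    case_group: str = "ASD",
    control_group: str = "TD",
) -> FineFeatures:
    """Fine-scale features for one subject against jackknifed restricted domains.

    For each trial the subject's own group's domain is built from the other
    members (self-excluded); the opposite group's domain uses all of its
    members.  Both are restricted at prevalence threshold ``tau`` before the
    odds score and the two missing-motif counts are computed.  ``exclude``
    names additional subjects (e.g. a held-out test subject) dropped from
    every domain.

    A domain missing ``n`` of its group's members is restricted at
    ``tau - n`` instead of ``tau``.  Every feature involves only motifs the
    subject itself carries, and for a carried motif the jackknifed count is
    exactly one below the full-group count — so without this adjustment a
    motif whose full prevalence equals ``tau`` would be "missing" from the
    own-group domain of each of its carriers and present for everyone else,
    a deterministic marker of group membership that inflates null-cohort
    classification.  The adjusted threshold reproduces the full-domain
    membership for carried motifs.
    """
    if subject_id not in groups:
        raise KeyError(f"unknown subject {subject_id!r}")
    own = groups[subject_id]
    if own not in (case_group, control_group):
        raise ValueError(f"subject group {own!r} is neither {case_group!r} nor {control_group!r}")
    excluded = set(exclude)
    components = {}
    for trial in trials:
        if (subject_id, trial) not in configs:
            continue
        config = configs[(subject_id, trial)]
        domains = {}
        for g in (case_group, control_group):
            members, n_full = [], 0
            for (sid, tr), c in configs.items():
                if tr != trial or groups.get(sid) != g:
                    continue
                n_full += 1
                if sid in excluded:
                    continue
                if g == own and sid == subject_id:
                    continue  # jackknife: self-excluded from own group only
                members.append(c)
            tau_g = max(tau - (n_full - len(members)), 1)
            domains[g] = restrict_domain(motif_domain(members, group=g, trial=trial), tau_g)
        odds = odds_score(config, domains[case_group], domains[control_group])
        miss_asd, miss_td = missing_counts(config, domains[case_group], domains[control_group])
        components[trial] = (odds, miss_asd, miss_td)
    return FineFeatures(subject_id=subject_id, components=components)
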