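"""Readers and writers for the pipeline's on-disk artifacts.

Everything is plain TSV (matrices indexed by ROI-id strings so files
survive reordering) or YAML (run configuration).  Writers prepend header
comments recording the package version and the parameters that produced
the file.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coarse import Atlas
from .core import ClusteringLevel, SharingMatrix, WalkParams
from .fine import MotifDomain
from .matrices import CorrelationMatrix, SimilarityMatrix
from .simulate import Cohort, CohortDesign

logger = logging.getLogger("dcgnet")

__all__ = [
    "read_correlation_matrix",
    "write_correlation_matrix",
    "read_sharing_matrix",
    "write_sharing_matrix",
    "write_similarity_matrix",
    "write_membership",
    "write_trajectory",
    "motif_table",
    "write_motif_table",
    "export_edgelist",
    "RunConfig",
    "write_cohort_dir",
    "read_cohort_dir",
]


def _header(**params) -> str:
    from . import __version__

    lines = [f"# dcgnet {__version__}"]
    lines += [f"# {k}={v}" for k, v in params.items()]
    return "\n".join(lines) + "\n"


def _write_frame(df: pd.DataFrame, path, index: bool = True, **params) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(**params))
        df.to_csv(fh, sep="\t", index=index, float_format="%.17g")


def _read_square(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row ids do not match column ids")
    return df


def read_correlation_matrix(path, **tags) -> CorrelationMatrix:
    """Read and validate a square correlation TSV (ROI-id header and index)."""
    df = _read_square(path)
    try:
        return CorrelationMatrix(values=df.to_numpy(dtype=float), roi_ids=tuple(df.columns), **tags)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_correlation_matrix(corr: CorrelationMatrix, path) -> None:
    ids = [str(r) for r in corr.roi_ids]
    df = pd.DataFrame(corr.values, index=ids, columns=ids)
    _write_frame(
        df, path, subject=corr.subject_id, group=corr.group, trial=corr.trial, kind="correlation"
    )


def write_similarity_matrix(sim: SimilarityMatrix, path) -> None:
    ids = [str(r) for r in sim.roi_ids]
    df = pd.DataFrame(sim.values, index=ids, columns=ids)
    _write_frame(df, path, temperature=sim.temperature, kind="similarity")


def write_sharing_matrix(sharing: SharingMatrix, path) -> None:
    ids = [str(r) for r in sharing.roi_ids]
    df = pd.DataFrame(sharing.values, index=ids, columns=ids)
    _write_frame(df, path, temperature=sharing.temperature, n_walks=sharing.n_walks, kind="sharing")


def read_sharing_matrix(path, temperature: float | None = None, n_walks: int = 0) -> SharingMatrix:
    df = _read_square(path)
    meta = _read_header(path)
    return SharingMatrix(
        values=df.to_numpy(dtype=float),
        temperature=float(meta.get("temperature", temperature or 1.0)),
        n_walks=int(float(meta.get("n_walks", n_walks))),
        roi_ids=tuple(df.columns),
    )


def _read_header(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def write_membership(level: ClusteringLevel, path) -> None:
    df = pd.DataFrame(
        {"roi_id": [str(r) for r in level.roi_ids], "cluster_label": level.membership}
    )
    _write_frame(
        df,
        path,
        index=False,
        temperature=level.temperature,
        k=level.k,
        estimated_k=level.estimated_k,
        kind="membership",
    )


def write_trajectory(traj, path) -> None:
    df = pd.DataFrame(traj.points, columns=["temperature", "k"])
    _write_frame(df, path, index=False, subject=traj.subject_id, trial=traj.trial, kind="trajectory")


def motif_table(dom_asd: MotifDomain, dom_td: MotifDomain) -> pd.DataFrame:
    """Combined prevalence table over both groups' domains, largest gaps first."""
    motifs = sorted(dom_asd.motifs | dom_td.motifs, key=sorted)
    rows = []
    for m in motifs:
        pa = dom_asd.prevalence.get(m, 0)
        pt = dom_td.prevalence.get(m, 0)
        rows.append(
            {
                "motif": ",".join(str(r) for r in sorted(m)),
                "prevalence_asd": pa,
                "prevalence_td": pt,
                "abs_difference": abs(pa - pt),
            }
        )
    df = pd.DataFrame(rows, columns=["motif", "prevalence_asd", "prevalence_td", "abs_difference"])
    return df.sort_values(
        ["abs_difference", "motif"], ascending=[False, True], ignore_index=True
    )


def write_motif_table(dom_asd: MotifDomain, dom_td: MotifDomain, path) -> None:
    _write_frame(motif_table(dom_asd, dom_td), path, index=False, trial=dom_asd.trial, kind="motifs")


def export_edgelist(obj, atlas: Atlas, threshold: float | None = None) -> pd.DataFrame:
    """Wire co-clustered (or strongly sharing) ROI pairs for 3-D plotting.

    For a :class:`ClusteringLevel` every within-cluster pair becomes an edge
    of weight 1; for a :class:`SharingMatrix` pairs with sharing >=
    ``threshold`` are kept with the sharing as weight.  Each row carries
    both endpoints' atlas coordinates.
    """
    if isinstance(obj, ClusteringLevel):
        pairs = [
            (i, j, 1.0)
            for i, j in combinations(range(len(obj.roi_ids)), 2)
            if obj.membership[i] == obj.membership[j]
        ]
        roi_ids = obj.roi_ids
    elif isinstance(obj, SharingMatrix):
        if threshold is None:
            raise ValueError("a sharing matrix needs an explicit threshold")
        pairs = [
            (i, j, float(obj.values[i, j]))
            for i, j in combinations(range(obj.n), 2)
            if obj.values[i, j] >= threshold
        ]
        roi_ids = obj.roi_ids
    else:
        raise TypeError(f"cannot export edges from {type(obj).__name__}")
    missing = [r for r in roi_ids if r not in set(atlas.roi_ids)]
    if missing:
        raise ValueError(f"atlas lacks coordinates for ROIs: {missing}")
    coords = {r: atlas.table.loc[r, ["x", "y", "z"]].to_numpy(dtype=float) for r in roi_ids}
    rows = []
    for i, j, w in pairs:
        a, b = roi_ids[i], roi_ids[j]
        xa, ya, za = coords[a]
        xb, yb, zb = coords[b]
        rows.append(
            {"roi_a": a, "roi_b": b, "weight": w, "xa": xa, "ya": ya, "za": za, "xb": xb, "yb": yb, "zb": zb}
        )
    return pd.DataFrame(rows, columns=["roi_a", "roi_b", "weight", "xa", "ya", "za", "xb", "yb", "zb"])


@dataclass
class RunConfig:
    """A run's full parameterisation; round-trips losslessly through YAML."""

    seed: int = 0
    temperature_grid: dict = field(
        default_factory=lambda: {"n_points": 40, "low": 0.001, "high": 5.0}
    )
    walk: dict = field(
        default_factory=lambda: {"removal_visits": 3, "n_walks": 100, "gap_factor": 1.0}
    )
    prune_height: float = 0.85
    finest_temperature: float = 0.001
    k_coarse: int = 10
    tau: int = 14
    tau_range: tuple = (2, 22)
    variables: str = "fine"
    trial_modes: tuple = (("green",), ("green", "red"), ("red",))
    log_level: str = "INFO"

    def grid(self) -> np.ndarray:
        g = self.temperature_grid
        return np.geomspace(g["low"], g["high"], g["n_points"])

    def walk_params(self) -> WalkParams:
        return WalkParams(seed=self.seed, **self.walk)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["tau_range"] = list(self.tau_range)
        d["trial_modes"] = [list(m) for m in self.trial_modes]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["tau_range"] = tuple(d.get("tau_range", (2, 22)))
        d["trial_modes"] = tuple(tuple(m) for m in d.get("trial_modes", ()))
        return cls(**d)


def write_cohort_dir(cohort: Cohort, out_dir) -> Path:
    """Write a simulated cohort as a directory of TSVs plus metadata."""
    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    for (sid, trial), corr in cohort.matrices.items():
        write_correlation_matrix(corr, out / "matrices" / f"{sid}_{trial}.tsv")
    atlas_df = cohort.atlas.table.reset_index()
    _write_frame(atlas_df, out / "atlas.tsv", index=False, kind="atlas")
    groups = pd.DataFrame(
        sorted(cohort.groups.items()), columns=["subject_id", "group"]
    )
    _write_frame(groups, out / "groups.tsv", index=False, kind="groups")
    _write_frame(cohort.truth_ledger(), out / "truth.tsv", index=False, kind="truth")
    design = asdict(cohort.design)
    design["motifs"] = [list(m) for m in cohort.design.motifs]
    design["inclusion"] = {
        ",".join(map(str, k)): list(v) for k, v in cohort.design.inclusion.items()
    }
    design["regional_shifts"] = [list(s) for s in cohort.design.regional_shifts]
    design["trials"] = list(cohort.design.trials)
    (out / "design.yaml").write_text(yaml.safe_dump(design, sort_keys=False))
    logger.info("wrote cohort (%d matrices) to %s", len(cohort.matrices), out)
    return out


def read_design_yaml(path) -> CohortDesign:
    d = yaml.safe_load(Path(path).read_text())
    d["motifs"] = tuple(tuple(m) for m in d.get("motifs", ()))
    d["inclusion"] = {
        tuple(int(x) for x in k.split(",")): tuple(v) for k, v in d.get("inclusion", {}).items()
    }
    d["regional_shifts"] = tuple(tuple(s) for s in d.get("regional_shifts", ()))
    d["trials"] = tuple(d.get("trials", ("green", "red")))
    return CohortDesign(**d)


def read_cohort_dir(path) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort_dir`."""
    path = Path(path)
    design = read_design_yaml(path / "design.yaml")
    atlas_df = pd.read_csv(path / "atlas.tsv", sep="\t", comment="#").set_index("roi_id")
    atlas = Atlas(table=atlas_df, region_order=tuple(design.region_counts))
    groups_df = pd.read_csv(path / "groups.tsv", sep="\t", comment="#")
    groups = dict(zip(groups_df["subject_id"], groups_df["group"]))
    matrices = {}
    for f in sorted((path / "matrices").glob("*.tsv")):
        sid, trial = f.stem.rsplit("_", 1)
        corr = read_correlation_matrix(f, subject_id=sid, group=groups[sid], trial=trial)
        # matrix files use string ids; restore the atlas's integer ROI ids
        corr = CorrelationMatrix(
            values=corr.values,
            roi_ids=tuple(int(r) for r in corr.roi_ids),
            subject_id=sid,
            group=groups[sid],
            trial=trial,
        )
        matrices[(sid, trial)] = corr
    truth: dict = {}
    truth_df = pd.read_csv(path / "truth.tsv", sep="\t", comment="#")
    for _, row in truth_df.iterrows():
        key = (row["subject_id"], row["trial"])
        motif = frozenset(int(x) for x in str(row["motif"]).split(","))
        truth.setdefault(key, set()).add(motif)
    truth = {k: frozenset(v) for k, v in truth.items()}
    return Cohort(design=design, atlas=atlas, groups=groups, matrices=matrices, truth=truth)
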