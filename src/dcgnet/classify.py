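"""Leave-one-out logistic classification on fine (and coarse) features.

Each held-out subject is scored by a logistic regression fitted on the
remaining subjects; fine-scale predictors (odds score and miss-count
difference per trial) are built from prevalence-restricted motif domains
that never include the subject's own configuration in its own group's
domain.  Sensitivity is the correctly classified fraction of the ASD group,
specificity of the TD group, with the label cut at predicted probability
0.5.  The tau sweep re-runs the whole procedure across prevalence
thresholds and trial modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression

from .fine import fine_feature_vector

__all__ = [
    "VS_COARSE_1",
    "VS_COARSE_2",
    "VS_COARSE_3",
    "COARSE_VARIABLE_SETS",
    "ModelSpec",
    "ClassificationResult",
    "fit_logistic",
    "predict_proba",
    "loocv_classify",
    "tau_sweep",
]

# Named coarse-scale variable sets: (trial, canonical retention-feature name).
# Set 1 is the full screened list; sets 2 and 3 are its reduced refinements.
VS_COARSE_1 = (
    ("red", "within_Parietal"),
    ("red", "between_Cerebelum_and_Central"),
    ("red", "between_Temporal_and_Limbic"),
    ("red", "within_Insular"),
    ("red", "between_Subcortical_and_Occipital"),
    ("red", "between_Parietal_and_Limbic"),
    ("red", "between_Occipital_and_Limbic"),
    ("green", "between_Subcortical_and_Frontal"),
    ("green", "between_Parietal_and_Occipital"),
    ("green", "within_Occipital"),
)
VS_COARSE_2 = (
    ("red", "within_Insular"),
    ("red", "between_Subcortical_and_Occipital"),
    ("green", "between_Subcortical_and_Frontal"),
    ("green", "within_Occipital"),
)
VS_COARSE_3 = (
    ("red", "between_Parietal_and_Limbic"),
    ("green", "between_Subcortical_and_Frontal"),
    ("green", "between_Parietal_and_Occipital"),
    ("green", "within_Occipital"),
)
COARSE_VARIABLE_SETS = {
    "coarse1": VS_COARSE_1,
    "coarse2": VS_COARSE_2,
    "coarse3": VS_COARSE_3,
}


@dataclass(frozen=True)
class ModelSpec:
    """Which predictors enter the leave-one-out logistic regression.

    ``variables`` is ``"fine"``, one of ``"coarse1"/"coarse2"/"coarse3"``,
    or a combination like ``"fine+coarse2"``.  ``tau`` is the motif
    prevalence threshold (2..22); ``trials`` selects green-only, red-only or
    both trials for the fine predictors.
    """

    variables: str = "fine"
    tau: int = 14
    trials: tuple = ("green", "red")

    def __post_init__(self) -> None:
        if not 2 <= self.tau <= 22:
            raise ValueError("tau must be in [2, 22]")
        for part in self.parts:
            if part != "fine" and part not in COARSE_VARIABLE_SETS:
                raise ValueError(f"unknown variable set {part!r}")
        if not self.trials:
            raise ValueError("at least one trial mode required")

    @property
    def parts(self) -> tuple:
        return tuple(self.variables.split("+"))

    @property
    def uses_fine(self) -> bool:
        return "fine" in self.parts

    def coarse_columns(self) -> tuple:
        cols: list = []
        for part in self.parts:
            if part in COARSE_VARIABLE_SETS:
                cols.extend(COARSE_VARIABLE_SETS[part])
        return tuple(cols)


def fit_logistic(X, y, ridge_on_failure: float = 1e-4):
    """Maximum-likelihood logistic coefficients ``[intercept, slopes...]``.

    Plain Newton MLE via statsmodels; on perfect separation, a singular
    Hessian or non-convergence the fit falls back to a small L2 (ridge)
    penalty of strength ``ridge_on_failure`` applied to standardized slopes
    (never the intercept), which keeps coefficients finite on strongly
    separated synthetic cohorts.  Deterministic for fixed input.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) and y length n")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    scale = X.std(axis=0)
    degenerate = scale == 0
    design = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200, method="newton")
        ok = bool(fit.mle_retvals.get("converged", False))
        slopes_std = np.abs(fit.params[1:]) * np.where(degenerate, 1.0, scale)
        if ok and slopes_std.max(initial=0.0) < 30.0 and np.all(np.isfinite(fit.params)):
            return np.asarray(fit.params)
    except Exception:
        pass
    # ridge fallback on standardized, non-degenerate columns
    keep = ~degenerate
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / scale[keep] if keep.any() else None
    coefs = np.zeros(X.shape[1] + 1)
    if Xs is None or Xs.size == 0 or len(set(y)) < 2:
        base = y.mean()
        coefs[0] = np.log(base / (1 - base)) if 0 < base < 1 else (30.0 if base >= 1 else -30.0)
        return coefs
    clf = LogisticRegression(C=1.0 / ridge_on_failure, solver="lbfgs", max_iter=2000)
    clf.fit(Xs, y)
    slopes = np.zeros(X.shape[1])
    slopes[keep] = clf.coef_[0] / scale[keep]
    coefs[0] = float(clf.intercept_[0]) - float(np.dot(slopes[keep], X[:, keep].mean(axis=0)))
    coefs[1:] = slopes
    return coefs


def predict_proba(coefs, X) -> np.ndarray:
    """P(ASD) under fitted logistic coefficients ``[intercept, slopes...]``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    eta = coefs[0] + X @ np.asarray(coefs[1:], dtype=float)
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class ClassificationResult:
    """Per-subject LOOCV probabilities and the group-wise correct rates."""

    table: pd.DataFrame
    spec: ModelSpec
    case_group: str = "ASD"
    control_group: str = "TD"

    def _group_counts(self, group: str) -> tuple[int, int]:
        sub = self.table[self.table["group"] == group]
        return int((sub["predicted"] == group).sum()), len(sub)

    @property
    def sensitivity(self) -> float:
        num, den = self._group_counts(self.case_group)
        return num / den

    @property
    def specificity(self) -> float:
        num, den = self._group_counts(self.control_group)
        return num / den

    def rates(self) -> dict:
        se_num, se_den = self._group_counts(self.case_group)
        sp_num, sp_den = self._group_counts(self.control_group)
        return {"se_num": se_num, "se_den": se_den, "sp_num": sp_num, "sp_den": sp_den}

    def summary(self) -> str:
        r = self.rates()
        lines = [
            "Leave-one-out logistic classification",
            "=" * 45,
            f"variables:    {self.spec.variables}",
            f"tau:          {self.spec.tau}",
            f"trials:       {'+'.join(self.spec.trials)}",
            f"sensitivity:  {r['se_num']}/{r['se_den']} = {self.sensitivity:.3f}",
            f"specificity:  {r['sp_num']}/{r['sp_den']} = {self.specificity:.3f}",
        ]
        return "\n".join(lines)


def _fine_predictors(sid, configs, groups, spec, exclude=()):
    ff = fine_feature_vector(
        sid, configs, groups, tau=spec.tau, trials=spec.trials, exclude=exclude
    )
    return ff.predictors(spec.trials)


def _coarse_predictors(sid, coarse: pd.DataFrame, columns) -> np.ndarray:
    vals = [float(coarse.loc[(sid, trial), name]) for trial, name in columns]
    return np.asarray(vals)


def _design_row(sid, configs, groups, spec, coarse, exclude=()):
    parts = []
    if spec.uses_fine:
        parts.append(_fine_predictors(sid, configs, groups, spec, exclude=exclude))
    cols = spec.coarse_columns()
    if cols:
        if coarse is None:
            raise ValueError("spec requests coarse variables but no coarse features given")
        parts.append(_coarse_predictors(sid, coarse, cols))
    return np.concatenate(parts)


def loocv_classify(
    configs: dict,
    groups: dict,
    spec: ModelSpec | None = None,
    coarse: pd.DataFrame | None = None,
    refit_domains_per_fold: bool = True,
    case_group: str = "ASD",
    control_group: str = "TD",
) -> ClassificationResult:
    """Leave-one-out cross-validated logistic classification.

    ``configs`` maps (subject_id, trial) to a motif configuration and
    ``groups`` maps subject_id to its group.  ``coarse``, when coarse
    variable sets are requested, is a DataFrame indexed by (subject_id,
    trial) with the 55 retention features as columns.

    By default every fold recomputes the training subjects' fine features
    with the held-out subject removed from all motif domains (each
    training subject is additionally jackknifed out of its own group's
    domain), so nothing about the held-out subject touches the fit.
    ``refit_domains_per_fold=False`` switches to the faster precomputed
    mode — each subject's features computed once with only itself
    jackknifed out — which leaves the held-out subject inside the training
    subjects' domains; that mild transductive leak measurably inflates
    accuracy on cohorts with no group signal.
    """
    spec = spec or ModelSpec()
    subjects = sorted(groups)
    if len({g for g in groups.values()}) != 2:
        raise ValueError("need exactly two groups")
    for g in (case_group, control_group):
        if sum(1 for s in subjects if groups[s] == g) < 2:
            raise ValueError(f"need at least 2 subjects in group {g!r}")
    y = np.array([1.0 if groups[s] == case_group else 0.0 for s in subjects])
    base_rows = {
        s: _design_row(s, configs, groups, spec, coarse) for s in subjects
    }
    records = []
    for j, held_out in enumerate(subjects):
        train = [s for s in subjects if s != held_out]
        if refit_domains_per_fold:
            X_train = np.vstack(
                [_design_row(s, configs, groups, spec, coarse, exclude=(held_out,)) for s in train]
            )
            x_test = _design_row(held_out, configs, groups, spec, coarse, exclude=(held_out,))
        else:
            X_train = np.vstack([base_rows[s] for s in train])
            x_test = base_rows[held_out]
        y_train = np.delete(y, j)
        coefs = fit_logistic(X_train, y_train)
        p_hat = float(predict_proba(coefs, x_test)[0])
        predicted = case_group if p_hat > 0.5 else control_group
        records.append(
            {
                "subject_id": held_out,
                "group": groups[held_out],
                "p_hat": p_hat,
                "predicted": predicted,
                "correct": predicted == groups[held_out],
            }
        )
    table = pd.DataFrame.from_records(records).set_index("subject_id")
    return ClassificationResult(
        table=table, spec=spec, case_group=case_group, control_group=control_group
    )


def tau_sweep(
    configs: dict,
    groups: dict,
    taus=range(2, 23),
    trial_modes=(("green",), ("green", "red"), ("red",)),
    variables: str = "fine",
    coarse: pd.DataFrame | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Classification rates across prevalence thresholds and trial modes.

    One row per (tau, mode) with numerators and denominators spelled out.
    """
    rows = []
    for tau in taus:
        for mode in trial_modes:
            spec = ModelSpec(variables=variables, tau=int(tau), trials=tuple(mode))
            res = loocv_classify(configs, groups, spec=spec, coarse=coarse, **kwargs)
            r = res.rates()
            rows.append(
                {
                    "tau": int(tau),
                    "trials": "+".join(mode),
                    "se_num": r["se_num"],
                    "se_den": r["se_den"],
                    "sp_num": r["sp_num"],
                    "sp_den": r["sp_den"],
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                }
            )
    return pd.DataFrame(rows)
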