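"""Correlation and similarity matrices.

The pipeline's raw input is a subject- and trial-tagged symmetric ROI x ROI
correlation matrix.  Before any clustering it is mapped to a similarity
matrix by the power transformation

    s_ij = |r_ij| ** (1 / T)

where the temperature ``T`` plays the role of a focal scale: at very small
``T`` only near-perfect correlations retain non-negligible similarity (the
fine scale, many small core clusters), while at large ``T`` every non-zero
correlation is pushed toward 1 and the whole node set fuses into one
cluster.  The unknown per-subject scale of the raw correlations is never
estimated; sweeping ``T`` over a wide range makes it irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CorrelationMatrix",
    "SimilarityMatrix",
    "power_transform",
    "SYMMETRY_TOL",
]

#: numeric tolerance for symmetry / unit-diagonal validation
SYMMETRY_TOL = 1e-8


def _validate_square_symmetric(values: np.ndarray, tol: float = SYMMETRY_TOL) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"matrix must be square, got shape {values.shape}")
    asym = np.abs(values - values.T)
    if asym.max(initial=0.0) > tol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"matrix is asymmetric beyond tolerance {tol:g}: "
            f"entry ({i}, {j})={values[i, j]!r} vs ({j}, {i})={values[j, i]!r}"
        )
    return values


@dataclass(frozen=True)
class CorrelationMatrix:
    """A validated symmetric correlation matrix over named ROIs.

    Parameters
    ----------
    values
        ``n x n`` array of correlations; symmetric within ``1e-8``, unit
        diagonal, all entries in ``[-1, 1]``.
    roi_ids
        Ordered ROI identifiers, one per row.
    subject_id, group, trial
        Optional provenance tags (``group`` conventionally ``"ASD"`` or
        ``"TD"``; ``trial`` ``"green"`` or ``"red"``).
    """

    values: np.ndarray
    roi_ids: tuple
    subject_id: str | None = None
    group: str | None = None
    trial: str | None = None

    def __post_init__(self) -> None:
        values = _validate_square_symmetric(self.values)
        n = values.shape[0]
        roi_ids = tuple(self.roi_ids)
        if len(roi_ids) != n:
            raise ValueError(f"got {len(roi_ids)} roi_ids for an {n} x {n} matrix")
        if len(set(roi_ids)) != n:
            raise ValueError("roi_ids must be unique")
        diag = np.diag(values)
        if np.abs(diag - 1.0).max(initial=0.0) > SYMMETRY_TOL:
            i = int(np.argmax(np.abs(diag - 1.0)))
            raise ValueError(f"diagonal entry {i} is {diag[i]!r}, expected 1")
        out = np.abs(values) > 1.0 + SYMMETRY_TOL
        if out.any():
            i, j = np.argwhere(out)[0]
            raise ValueError(
                f"entry ({roi_ids[i]}, {roi_ids[j]})={values[i, j]!r} outside [-1, 1]"
            )
        # snap the tolerated numeric fuzz so downstream code sees exact bounds
        values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(values, 1.0)
        values.flags.writeable = False
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "roi_ids", roi_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_dataframe(cls, df, **tags) -> "CorrelationMatrix":
        """Build from a square ``pandas.DataFrame`` whose columns name the ROIs."""
        return cls(values=df.to_numpy(dtype=float), roi_ids=tuple(map(str, df.columns)), **tags)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Power-transformed similarities ``s_ij = |r_ij|^(1/T)`` at temperature ``T``."""

    values: np.ndarray
    temperature: float
    roi_ids: tuple = field(default=())

    def __post_init__(self) -> None:
        values = _validate_square_symmetric(self.values)
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if values.min(initial=0.0) < -SYMMETRY_TOL or values.max(initial=0.0) > 1 + SYMMETRY_TOL:
            raise ValueError("similarity entries must lie in [0, 1]")
        roi_ids = tuple(self.roi_ids) or tuple(range(1, values.shape[0] + 1))
        if len(roi_ids) != values.shape[0]:
            raise ValueError("roi_ids length mismatch")
        values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
        values.flags.writeable = False
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "roi_ids", roi_ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def power_transform(corr: CorrelationMatrix, temperature: float) -> SimilarityMatrix:
    """Map correlations to similarities ``s_ij = |r_ij| ** (1 / T)``.

    Small ``T`` sharpens fine structure (``0.99**1000 ~ 4e-5`` at
    ``T = 0.001``); large ``T`` drives every non-zero similarity toward 1.

    Raises
    ------
    ValueError
        If ``temperature <= 0`` or the input fails validation.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    s = np.abs(corr.values) ** (1.0 / temperature)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(values=s, temperature=float(temperature), roi_ids=corr.roi_ids)
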