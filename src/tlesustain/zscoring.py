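"""Normative covariate-adjusted z-scoring of regional morphometry.

Each regional measure (subcortical volume in mm^3, cortical thickness in mm)
is regressed on sex, age, age^2 and total intracranial volume in the
healthy-control group only.  A subject's z-score is the residual relative to
that normative prediction divided by the control residual sd, sign-flipped so
larger z means more gray-matter loss (atrophy-positive); regional enlargement
yields negative z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NormativeModel",
    "ZScoreMatrix",
    "fit_normative",
    "compute_zscores",
    "invert_zscores",
    "select_modeling_rois",
    "merge_rois",
]

COVARIATES = ("sex", "age", "tiv")
DEGENERATE_SD = 1e-8


@dataclass
class NormativeModel:
    """Per-ROI least-squares fit of measure ~ 1 + sex + age + age^2 + tiv.

    ``coef`` rows are (intercept, sex, age, age^2, tiv); ``resid_sd`` uses the
    unbiased denominator n - 5.  ``age_center`` is the control mean age
    subtracted before squaring (reduces collinearity; 0.0 disables).
    """

    rois: list
    coef: np.ndarray  # (R, 5)
    resid_sd: np.ndarray  # (R,)
    n_controls: int
    age_center: float = 0.0

    def design(self, table: pd.DataFrame) -> np.ndarray:
        age = table["age"].to_numpy(dtype=float)
        return np.column_stack(
            [
                np.ones(len(table)),
                table["sex"].to_numpy(dtype=float),
                age,
                (age - self.age_center) ** 2,
                table["tiv"].to_numpy(dtype=float),
            ]
        )

    def predict(self, table: pd.DataFrame) -> pd.DataFrame:
        X = self.design(table)
        return pd.DataFrame(X @ self.coef.T, index=table.index, columns=self.rois)


@dataclass
class ZScoreMatrix:
    """Subjects x ROIs atrophy-positive normative deviations."""

    values: np.ndarray
    subject_ids: list
    rois: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.rois)):
            raise ValueError("values shape does not match ids/rois")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("z-scores must be finite")

    @property
    def atrophy_positive(self) -> bool:
        """Orientation flag: larger z always means more atrophy."""
        return True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.rois,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ZScoreMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def subset(self, subject_ids) -> "ZScoreMatrix":
        df = self.to_frame().loc[list(subject_ids)]
        return ZScoreMatrix.from_frame(df)


def _roi_columns(table: pd.DataFrame) -> list:
    meta = {"subject_id", "group", "sex", "age", "tiv"}
    return [c for c in table.columns if c not in meta]


def fit_normative(
    controls: pd.DataFrame, rois=None, center_age: bool = True
) -> NormativeModel:
    """Fit the normative regression on healthy controls.

    Parameters
    ----------
    controls : table with sex/age/tiv covariate columns and ROI columns.
    rois : explicit ROI column list (default: every non-covariate column).
    center_age : subtract the control mean age before squaring.
    """
    for c in COVARIATES:
        if c not in controls.columns:
            raise ValueError(f"missing covariate column {c!r}")
    rois = list(rois) if rois is not None else _roi_columns(controls)
    n, p = len(controls), 5
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} controls, got {n}")
    age_center = float(controls["age"].mean()) if center_age else 0.0
    model = NormativeModel(
        rois=rois,
        coef=np.zeros((len(rois), p)),
        resid_sd=np.zeros(len(rois)),
        n_controls=n,
        age_center=age_center,
    )
    X = model.design(controls)
    # collinearity guard before solving
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("collinear covariate design (singular normal equations)")
    Y = controls[rois].to_numpy(dtype=float)
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    sd = np.sqrt((resid**2).sum(axis=0) / (n - p))
    low = sd < DEGENERATE_SD
    if low.any():
        bad = [rois[i] for i in np.flatnonzero(low)]
        raise ValueError(f"degenerate ROI(s) with ~zero residual variance: {bad}")
    model.coef = coef.T
    model.resid_sd = sd
    return model


def compute_zscores(model: NormativeModel, subjects: pd.DataFrame) -> ZScoreMatrix:
    """Atrophy-positive z-scores: z = -(observed - predicted) / resid_sd."""
    missing = [r for r in model.rois if r not in subjects.columns]
    if missing:
        raise ValueError(f"subject table lacks ROI column(s): {missing}")
    pred = model.predict(subjects)
    obs = subjects[model.rois].to_numpy(dtype=float)
    z = -(obs - pred.to_numpy()) / model.resid_sd[None, :]
    ids = (
        subjects["subject_id"].tolist()
        if "subject_id" in subjects.columns
        else list(subjects.index)
    )
    return ZScoreMatrix(z, ids, list(model.rois))


def invert_zscores(model: NormativeModel, Z: ZScoreMatrix,
                   covariates: pd.DataFrame) -> pd.DataFrame:
    """Map z-scores back to raw measures through the normative model
    (measure = predicted - z * resid_sd); inverse of :func:`compute_zscores`."""
    if list(Z.rois) != list(model.rois):
        raise ValueError("ROI set mismatch")
    pred = model.predict(covariates).to_numpy()
    raw = pred - Z.values * model.resid_sd[None, :]
    return pd.DataFrame(raw, index=covariates.index, columns=model.rois)


def select_modeling_rois(Z: ZScoreMatrix, roi_list) -> ZScoreMatrix:
    """Column subset, in ``roi_list`` order (the modelling feature set; the
    full matrix is kept separately for characterization)."""
    roi_list = list(roi_list)
    if len(set(roi_list)) != len(roi_list):
        raise ValueError("duplicate ROI name in selection list")
    unknown = [r for r in roi_list if r not in Z.rois]
    if unknown:
        raise ValueError(f"unknown ROI(s): {unknown}")
    idx = [Z.rois.index(r) for r in roi_list]
    return ZScoreMatrix(Z.values[:, idx], Z.subject_ids, roi_list)


def merge_rois(Z: ZScoreMatrix, merge_map: dict) -> ZScoreMatrix:
    """Average member-ROI z-scores into group columns (e.g. lobe-level
    down-sampling).  Groups must not overlap."""
    seen = {}
    for gname, members in merge_map.items():
        for m in members:
            if m in seen:
                raise ValueError(
                    f"ROI {m!r} appears in groups {seen[m]!r} and {gname!r}"
                )
            if m not in Z.rois:
                raise ValueError(f"unknown ROI {m!r} in group {gname!r}")
            seen[m] = gname
    cols = []
    for gname, members in merge_map.items():
        idx = [Z.rois.index(m) for m in members]
        cols.append(Z.values[:, idx].mean(axis=1))
    return ZScoreMatrix(
        np.column_stack(cols), Z.subject_ids, list(merge_map.keys())
    )
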