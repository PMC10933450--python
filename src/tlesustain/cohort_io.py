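"""Tabular I/O and model-artifact serialization.

Tables are CSV (UTF-8, "." decimal, header row); TSV is auto-detected from
the ``.tsv`` extension.  ROI columns are whatever numeric columns remain
after the mandatory metadata columns, with laterality encoded by
``Left_``/``Right_`` name prefixes.  Fitted models round-trip through a
single JSON artifact that carries enough metadata (seed, iteration counts,
feature list) to reproduce the run.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .progression import EventSet, SubtypeModel, build_event_set
from .zscoring import NormativeModel, ZScoreMatrix

__all__ = [
    "read_morphometry",
    "read_clinical",
    "write_table",
    "read_zscores",
    "write_zscores",
    "save_artifact",
    "load_artifact",
]

MORPH_REQUIRED = ("subject_id", "group", "sex", "age", "tiv")
CLIN_REQUIRED = ("subject_id",)
GROUP_LEVELS = {"patient", "control"}
OUTCOME_LEVELS = {"effective", "ineffective", "lost"}
ARM_LEVELS = {"OG", "MG"}


def _read(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df.to_csv(path, sep=sep, index=False)


def read_morphometry(path) -> pd.DataFrame:
    """Load and validate a morphometry table.

    Requires subject_id, group, sex, age, tiv and at least one numeric ROI
    column; ROI columns are all remaining columns.
    """
    df = _read(path)
    for col in MORPH_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"morphometry table missing column {col!r}")
    rois = [c for c in df.columns if c not in MORPH_REQUIRED]
    if not rois:
        raise ValueError("morphometry table has no ROI columns")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id {dup!r}")
    bad_group = set(df["group"]) - GROUP_LEVELS
    if bad_group:
        raise ValueError(f"unknown group value(s): {sorted(bad_group)}")
    for c in rois:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            raise ValueError(
                f"non-numeric or non-finite value in ROI column {c!r} "
                f"at row {int(np.flatnonzero(bad)[0])}")
        if (vals <= 0).any():
            raise ValueError(f"non-positive measure in ROI column {c!r}")
        df[c] = vals
    return df


def read_clinical(path) -> pd.DataFrame:
    """Load and validate a clinical table (subject_id plus free clinical
    columns; enum columns are checked against their level sets)."""
    df = _read(path)
    for col in CLIN_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"clinical table missing column {col!r}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in clinical table")
    if "outcome" in df.columns:
        bad = set(df["outcome"].dropna()) - OUTCOME_LEVELS
        if bad:
            raise ValueError(f"unknown outcome value(s): {sorted(bad)}")
    if "treatment_arm" in df.columns:
        bad = set(df["treatment_arm"].dropna()) - ARM_LEVELS
        if bad:
            raise ValueError(f"unknown treatment arm value(s): {sorted(bad)}")
    if "seizure_lateralization" in df.columns:
        bad = set(df["seizure_lateralization"].dropna()) - {"left", "right"}
        if bad:
            raise ValueError(f"unknown lateralization value(s): {sorted(bad)}")
    return df


def write_zscores(Z: ZScoreMatrix, path) -> None:
    Z.to_frame().to_csv(path)


def read_zscores(path) -> ZScoreMatrix:
    return ZScoreMatrix.from_frame(pd.read_csv(path, index_col="subject_id"))


# ---------------------------------------------------------------------------
# model artifact (JSON metadata + numeric arrays in one file)


def _normative_to_dict(m: NormativeModel) -> dict:
    return {
        "rois": list(m.rois),
        "coef": m.coef.tolist(),
        "resid_sd": m.resid_sd.tolist(),
        "n_controls": int(m.n_controls),
        "age_center": float(m.age_center),
    }


def _normative_from_dict(d: dict) -> NormativeModel:
    return NormativeModel(
        rois=list(d["rois"]),
        coef=np.asarray(d["coef"], dtype=float),
        resid_sd=np.asarray(d["resid_sd"], dtype=float),
        n_controls=int(d["n_controls"]),
        age_center=float(d["age_center"]),
    )


def _subtype_to_dict(m: SubtypeModel) -> dict:
    d = {
        "biomarkers": list(m.event_set.biomarkers),
        "thresholds": [list(t) for t in m.event_set.thresholds],
        "z_max": m.event_set.z_max,
        "orderings": [o.tolist() for o in m.orderings],
        "fractions": m.fractions.tolist(),
        "sigma": m.sigma.tolist(),
        "loglik": None if np.isnan(m.loglik) else float(m.loglik),
    }
    if m.mcmc is not None:
        d["mcmc"] = {
            "orderings": [s.tolist() for s in m.mcmc.orderings],
            "loglik_trace": m.mcmc.loglik_trace.tolist(),
            "acceptance_rate": float(m.mcmc.acceptance_rate),
            "seed": int(m.mcmc.seed),
            "ml_orderings": [o.tolist() for o in m.mcmc.ml_orderings],
            "ml_loglik": float(m.mcmc.ml_loglik),
        }
    return d


def _subtype_from_dict(d: dict) -> SubtypeModel:
    es = build_event_set(d["biomarkers"],
                         {b: t for b, t in zip(d["biomarkers"],
                                               d["thresholds"])},
                         d["z_max"])
    model = SubtypeModel(
        event_set=es,
        orderings=[np.asarray(o, dtype=np.intp) for o in d["orderings"]],
        fractions=np.asarray(d["fractions"], dtype=float),
        sigma=np.asarray(d["sigma"], dtype=float),
        loglik=float("nan") if d["loglik"] is None else float(d["loglik"]),
    )
    if "mcmc" in d:
        from .fitting import McmcSamples

        s = d["mcmc"]
        model.mcmc = McmcSamples(
            orderings=[np.asarray(o, dtype=np.intp) for o in s["orderings"]],
            loglik_trace=np.asarray(s["loglik_trace"], dtype=float),
            acceptance_rate=float(s["acceptance_rate"]),
            seed=int(s["seed"]),
            ml_orderings=[np.asarray(o, dtype=np.intp)
                          for o in s["ml_orderings"]],
            ml_loglik=float(s["ml_loglik"]),
        )
    return model


def save_artifact(path, subtype_model: SubtypeModel = None,
                  normative_model: NormativeModel = None,
                  metadata: dict = None) -> None:
    """Serialize fitted models plus run metadata into one JSON artifact."""
    doc = {"format": "tlesustain-artifact", "version": 1,
           "metadata": metadata or {}}
    if subtype_model is not None:
        doc["subtype_model"] = _subtype_to_dict(subtype_model)
    if normative_model is not None:
        doc["normative_model"] = _normative_to_dict(normative_model)
    Path(path).write_text(json.dumps(doc))


def load_artifact(path) -> dict:
    """Load an artifact; returns a dict with keys subtype_model,
    normative_model (when present) and metadata."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "tlesustain-artifact":
        raise ValueError("not a tlesustain model artifact")
    out = {"metadata": doc.get("metadata", {})}
    if "subtype_model" in doc:
        out["subtype_model"] = _subtype_from_dict(doc["subtype_model"])
    if "normative_model" in doc:
        out["normative_model"] = _normative_from_dict(doc["normative_model"])
    return out
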