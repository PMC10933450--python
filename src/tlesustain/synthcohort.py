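"""Synthetic TLE cohort generator with known ground truth.

Raw patient data for this kind of study are protected, so the generator
emulates the statistical structure the analysis assumes: a healthy-control
population following a linear covariate model (sex, age, age^2, TIV); three
patient subtypes whose modelled z-scores follow known event orderings that
begin at the left hippocampus, the right hippocampus and the frontal cortex
respectively; a fourth "normal" subtype without atrophy but with bilateral
amygdala enlargement; and clinical covariates and treatment outcomes whose
per-subtype distributions follow the published cohort summaries.

The mapping from latent z-scores back to raw mm/mm^3 measures inverts the
generator's own covariate model, so the pipeline's normative regression step
is genuinely exercised rather than bypassed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rois as _rois
from .progression import EventSet, build_event_set, validate_ordering

__all__ = ["CohortConfig", "GroundTruth", "make_ground_truth",
           "simulate_cohort", "simulate_outcomes"]

NORMAL_SUBTYPE = 3  # index of the no-atrophy subtype (labels are 0..2 + normal)


@dataclass
class CohortConfig:
    """Study-condition defaults for the generator.

    Sample sizes, subtype fractions, clinical means/sds and outcome
    probabilities follow the published cohort tables; morphometric scales
    (intercepts mm/mm^3, covariate slopes, noise sds) are realistic
    single-scanner values and are documented in the methods note.
    """

    rois: tuple = tuple(_rois.ALL_ROIS)
    modeling_rois: tuple = tuple(_rois.MODELING_ROIS)
    thresholds: tuple = (1.0, 2.0, 3.0)
    z_max: float = 5.0
    fractions: tuple = (0.287, 0.382, 0.139, 0.192)  # subtypes 1-3 + normal
    trajectory_heads: tuple = (
        "Left_Hippocampus", "Right_Hippocampus", "Left_Superiorfrontal",
    )
    # healthy-control covariate distributions
    control_age_mean: float = 26.4
    control_age_sd: float = 6.7
    age_bounds: tuple = (18.0, 60.0)
    patient_age_mean: float = 27.2
    patient_age_sd: float = 8.7
    tiv_mean: float = 1470.0  # cm^3
    tiv_sd: float = 140.0
    # subtype-wise clinical profiles (Table-scale values)
    onset_mean: tuple = (12.3, 16.0, 20.1, 18.5)
    onset_sd: tuple = (7.7, 9.7, 7.0, 11.4)
    left_lateralization: tuple = (79 / 85, 8 / 113, 21 / 41, 36 / 57)
    hs_rate: tuple = (0.953, 0.929, 0.390, 0.421)
    febrile_rate: tuple = (0.494, 0.434, 0.220, 0.123)
    operative_rate: tuple = (55 / 85, 57 / 113, 19 / 41, 21 / 57)
    # follow-up seizure-freedom probability per subtype, by treatment arm
    outcome_prob_og: tuple = (0.692, 0.722, 0.632, 0.450)
    outcome_prob_mg: tuple = (0.0909, 0.1316, 0.1579, 0.3929)
    lost_prob: dict = field(default_factory=lambda: {"OG": 7 / 152, "MG": 37 / 144})
    # amygdala enlargement of the normal subtype, in atrophy-positive z units
    amygdala_z_mean: float = -1.5
    amygdala_z_sd: float = 0.8


@dataclass
class GroundTruth:
    """Hidden generating quantities, kept for recovery tests."""

    config: CohortConfig
    event_set: EventSet
    orderings: list  # three trajectory orderings over the modelling ROIs
    fractions: np.ndarray  # four fractions; last mass = normal subtype
    seed: int
    subject_truth: pd.DataFrame = None  # filled by simulate_cohort

    @property
    def outcome_prob(self) -> dict:
        return {"OG": self.config.outcome_prob_og,
                "MG": self.config.outcome_prob_mg}


def _random_valid_ordering(es: EventSet, rng, head_event=None) -> np.ndarray:
    """Uniform-ish random valid ordering via per-biomarker sorted keys; an
    optional ``head_event`` id is pinned to position 1."""
    keys = np.empty(es.n_events)
    for b in range(es.n_biomarkers):
        m = es.event_biomarker == b
        keys[m] = np.sort(rng.random(int(m.sum())))
    if head_event is not None:
        keys[head_event] = -1.0
    order = np.argsort(keys, kind="stable")
    return validate_ordering(order, es)


def make_ground_truth(config: CohortConfig | None = None, seed: int = 0
                      ) -> GroundTruth:
    """Draw the three generating trajectories.

    Each trajectory's first event is pinned — (left hippocampus, z=1),
    (right hippocampus, z=1), (frontal cortex, z=1) — and the remaining
    event order is randomized per seed subject to threshold-order validity.
    """
    config = config or CohortConfig()
    f = np.asarray(config.fractions, dtype=float)
    if abs(f.sum() - 1.0) > 1e-9 or np.any(f < 0):
        raise ValueError("subtype fractions must be non-negative and sum to 1")
    es = build_event_set(config.modeling_rois, config.thresholds, config.z_max)
    rng = np.random.default_rng(seed)
    orderings = []
    for head_roi in config.trajectory_heads:
        b = config.modeling_rois.index(head_roi)
        head_event = int(np.flatnonzero(
            (es.event_biomarker == b) & (es.event_rank == 0))[0])
        orderings.append(_random_valid_ordering(es, rng, head_event))
    return GroundTruth(config=config, event_set=es, orderings=orderings,
                       fractions=f, seed=seed)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size=size)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return x


def _upper_truncated_normal(rng, mean, sd, hi, size):
    x = rng.normal(mean, sd, size=size)
    bad = x >= hi
    while bad.any():
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = x >= hi
    return x


class _RawScaleModel:
    """The generator's linear covariate model per ROI.

    measure = a0 + a_sex*sex + a_age*age + a_age2*(age-30)^2 + a_tiv*tiv + eps

    Volumes (mm^3) scale with their intercept; thickness (mm) uses absolute
    slopes.  ``noise_sd`` doubles as the z unit when mapping latent z-scores
    back to the raw scale.
    """

    THICKNESS_INTERCEPT = 2.5
    VOLUME_INTERCEPTS = {
        "Hippocampus": 4000.0, "Amygdala": 1700.0, "Caudate": 3600.0,
        "Accumbens": 600.0, "Pallidum": 1800.0, "Thalamus": 7200.0,
    }

    def __init__(self, roi_names):
        self.rois = list(roi_names)
        a0, a_sex, a_age, a_age2, a_tiv, sd = [], [], [], [], [], []
        for name in self.rois:
            base = name.split("_", 1)[1]
            if _rois.is_volume_roi(name):
                v = self.VOLUME_INTERCEPTS[base]
                a0.append(v * 0.4)  # intercept after TIV share
                a_sex.append(0.02 * v)
                a_age.append(-0.002 * v)
                a_age2.append(-2e-5 * v)
                a_tiv.append(0.6 * v / 1470.0)  # per cm^3
                sd.append(0.05 * v)
            else:
                a0.append(self.THICKNESS_INTERCEPT)
                a_sex.append(0.01)
                a_age.append(-0.002)
                a_age2.append(-2e-5)
                a_tiv.append(0.0)
                sd.append(0.1)
        self.coef = np.array([a0, a_sex, a_age, a_age2, a_tiv]).T  # (R, 5)
        self.noise_sd = np.asarray(sd)

    def predict(self, sex, age, tiv):
        X = np.column_stack([np.ones_like(age), sex, age, (age - 30.0) ** 2, tiv])
        return X @ self.coef.T


def _allocate_counts(fractions, n):
    """Largest-remainder allocation of n subjects to the subtype fractions."""
    raw = np.asarray(fractions) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def simulate_cohort(gt: GroundTruth, n_patients: int = 296,
                    n_controls: int = 81, seed: int = 0):
    """Generate (morphometry, clinical) tables and record per-subject truth.

    Controls follow the linear covariate model plus Gaussian noise.  Patients
    draw a subtype by largest-remainder allocation of the configured
    fractions; trajectory subjects draw a uniform stage on 1..E and modelled
    z ~ Normal(g[b, stage], 1); "normal"-subtype subjects have all modelled
    z < 1 (stage 0) and bilateral amygdala enlargement (negative z).
    """
    if n_patients < 1 or n_controls < 1:
        raise ValueError("need at least one patient and one control")
    cfg = gt.config
    unknown = [r for r in cfg.modeling_rois if r not in cfg.rois]
    if unknown:
        raise ValueError(f"modelling ROI(s) not in the ROI set: {unknown}")
    rng = np.random.default_rng(seed)
    raw_model = _RawScaleModel(cfg.rois)
    es = gt.event_set
    E = es.n_events
    R = len(cfg.rois)
    mod_idx = np.array([cfg.rois.index(r) for r in cfg.modeling_rois])
    amyg_idx = np.array([cfg.rois.index(r)
                         for r in ("Left_Amygdala", "Right_Amygdala")])

    def covariates(n, age_mean, age_sd):
        sex = rng.integers(0, 2, size=n).astype(float)
        age = _truncated_normal(rng, age_mean, age_sd, *cfg.age_bounds, n)
        tiv = rng.normal(cfg.tiv_mean, cfg.tiv_sd, size=n)
        return sex, age, tiv

    # --- controls ---
    sex_c, age_c, tiv_c = covariates(n_controls, cfg.control_age_mean,
                                     cfg.control_age_sd)
    raw_c = raw_model.predict(sex_c, age_c, tiv_c) + \
        rng.normal(size=(n_controls, R)) * raw_model.noise_sd

    # --- patients ---
    sex_p, age_p, tiv_p = covariates(n_patients, cfg.patient_age_mean,
                                     cfg.patient_age_sd)
    counts = _allocate_counts(gt.fractions, n_patients)
    subtype = np.repeat(np.arange(4), counts)
    rng.shuffle(subtype)
    stage = np.zeros(n_patients, dtype=int)
    Zlat = rng.normal(size=(n_patients, R))  # latent z, overwritten per block
    from .progression import expected_trajectory  # local to avoid cycle

    G = [expected_trajectory(o, es) for o in gt.orderings]
    for c in range(3):
        m = subtype == c
        k = rng.integers(1, E + 1, size=int(m.sum()))
        stage[m] = k
        Zlat[np.ix_(m, mod_idx)] = G[c][:, k].T + rng.normal(size=(m.sum(),
                                                                   len(mod_idx)))
    m = subtype == NORMAL_SUBTYPE
    n_norm = int(m.sum())
    Zlat[np.ix_(m, mod_idx)] = _upper_truncated_normal(
        rng, 0.0, 1.0, 1.0, (n_norm, len(mod_idx)))
    Zlat[np.ix_(m, amyg_idx)] = rng.normal(
        cfg.amygdala_z_mean, cfg.amygdala_z_sd, size=(n_norm, 2))
    # atrophy-positive z -> raw scale: measure = predicted - z * noise_sd
    raw_p = raw_model.predict(sex_p, age_p, tiv_p) - Zlat * raw_model.noise_sd

    ids_c = [f"hc{i:04d}" for i in range(n_controls)]
    ids_p = [f"pt{i:04d}" for i in range(n_patients)]
    morph = pd.DataFrame(
        np.vstack([raw_c, raw_p]), columns=list(cfg.rois))
    morph.insert(0, "subject_id", ids_c + ids_p)
    morph.insert(1, "group", ["control"] * n_controls + ["patient"] * n_patients)
    morph.insert(2, "sex", np.concatenate([sex_c, sex_p]).astype(int))
    morph.insert(3, "age", np.concatenate([age_c, age_p]))
    morph.insert(4, "tiv", np.concatenate([tiv_c, tiv_p]))

    st = subtype
    onset_mu = np.take(cfg.onset_mean, st)
    onset_sd = np.take(cfg.onset_sd, st)
    onset = np.clip(rng.normal(onset_mu, onset_sd), 0.5, age_p - 0.5)
    lateral = np.where(rng.random(n_patients) < np.take(cfg.left_lateralization,
                                                        st), "left", "right")
    hs = rng.random(n_patients) < np.take(cfg.hs_rate, st)
    febrile = rng.random(n_patients) < np.take(cfg.febrile_rate, st)
    arm = np.where(rng.random(n_patients) < np.take(cfg.operative_rate, st),
                   "OG", "MG")
    clin = pd.DataFrame({
        "subject_id": ids_p,
        "age_of_onset": onset,
        "illness_duration": age_p - onset,
        "seizure_lateralization": lateral,
        "hs_on_mri": hs,
        "febrile_history": febrile,
        "treatment_arm": arm,
    })
    gt.subject_truth = pd.DataFrame({
        "subject_id": ids_p,
        "true_subtype": subtype,
        "true_stage": stage,
    })
    return morph, clin


def simulate_outcomes(gt: GroundTruth, clin: pd.DataFrame, seed: int = 0
                      ) -> pd.DataFrame:
    """Append a follow-up ``outcome`` column (effective / ineffective / lost).

    Seizure freedom is Bernoulli with the per-(subtype, arm) probabilities of
    the ground truth; a per-arm loss-to-follow-up probability thins the
    denominators first.
    """
    if gt.subject_truth is None:
        raise ValueError("simulate_cohort must run before simulate_outcomes")
    if "treatment_arm" not in clin.columns:
        raise ValueError("clinical table lacks treatment_arm")
    rng = np.random.default_rng(seed)
    truth = gt.subject_truth.set_index("subject_id")
    st = truth.loc[clin["subject_id"], "true_subtype"].to_numpy()
    out = np.empty(len(clin), dtype=object)
    for arm, probs in gt.outcome_prob.items():
        probs = np.asarray(probs, dtype=float)
        if np.any((probs < 0) | (probs > 1)):
            raise ValueError("outcome probabilities must lie in [0, 1]")
        m = (clin["treatment_arm"] == arm).to_numpy()
        if not m.any():
            continue
        p = probs[st[m]]
        eff = rng.random(int(m.sum())) < p
        lost = rng.random(int(m.sum())) < gt.config.lost_prob.get(arm, 0.0)
        vals = np.where(eff, "effective", "ineffective")
        vals = np.where(lost, "lost", vals)
        out[m] = vals
    clin = clin.copy()
    clin["outcome"] = out
    return clin
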