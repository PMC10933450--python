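"""Surgical-outcome prediction: subtype-stratified SVM vs pooled baselines.

The stratified classifier trains one support-vector sub-classifier per
subtype (the rationale: each subtype has its own anatomy and clinical
profile, so one global separator can be a poor fit for all of them); the
pooled baseline trains a single classifier on everyone.  Both share the same
ten-fold splits so comparisons are paired.  Within every training fold,
features are z-standardized and reduced by PCA to the smallest number of
components explaining at least 95% of the variance; the kernel (linear, RBF
or polynomial) is chosen per stratum by inner cross-validation unless fixed.
Performance is summarized by sensitivity, specificity, accuracy and the
Youden index J = sensitivity + specificity - 1, with significance from a
permutation test that reruns the full cross-validation on shuffled outcome
labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ClassifierConfig",
    "FeatureMatrix",
    "PredictionReport",
    "build_features",
    "reduce_pca",
    "evaluate_stratified",
    "evaluate_pooled",
    "youden",
    "permutation_test",
]

POSITIVE = "effective"  # seizure freedom is the positive class


@dataclass
class ClassifierConfig:
    kernels: tuple = ("linear", "rbf", "poly")
    fixed_kernel: str = None  # overrides inner-CV kernel selection
    pca_variance: float = 0.95
    n_folds: int = 10
    inner_folds: int = 5
    class_weight: str = None  # None mirrors unweighted training; "balanced" opts in
    use_pca: bool = True


@dataclass
class FeatureMatrix:
    """Encoded subjects x features design with provenance metadata.

    Standardization/PCA parameters are deliberately absent: they are fit per
    training fold at cross-validation time to avoid information leak.
    """

    values: np.ndarray
    feature_names: list
    subject_ids: list
    provenance: list  # "clinical" or "mri" per feature

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features must be finite after encoding")


@dataclass
class PredictionReport:
    sensitivity: float
    specificity: float
    accuracy: float
    youden_j: float
    confusion: np.ndarray  # pooled over folds: [[tp, fn], [fp, tn]]
    fold_confusions: list
    per_subtype: dict = field(default_factory=dict)
    permutation_p: float = None
    config: ClassifierConfig = None
    seed: int = None


def youden(sensitivity: float, specificity: float) -> float:
    """Youden index J = sensitivity + specificity - 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return sensitivity + specificity - 1.0


def build_features(clin: pd.DataFrame, Z=None, drop=("outcome",
                                                     "treatment_arm")
                   ) -> FeatureMatrix:
    """One-hot encode categorical clinical columns, keep continuous ones,
    optionally append the MRI z-score block.

    Callers restrict rows to the surgical arm with known outcome first.
    """
    clin = clin.copy()
    ids = clin["subject_id"].tolist() if "subject_id" in clin.columns \
        else list(clin.index)
    X = clin.drop(columns=[c for c in drop + ("subject_id",)
                           if c in clin.columns])
    for c in X.columns:
        if X[c].isna().all():
            raise ValueError(f"column {c!r} is entirely missing")
    cat = [c for c in X.columns
           if not pd.api.types.is_numeric_dtype(X[c]) or X[c].dtype == bool]
    enc = pd.get_dummies(X, columns=cat, dtype=float)
    names = list(enc.columns)
    prov = ["clinical"] * len(names)
    values = enc.to_numpy(dtype=float)
    if Z is not None:
        zf = Z.to_frame().loc[ids]
        values = np.column_stack([values, zf.to_numpy()])
        names += list(zf.columns)
        prov += ["mri"] * zf.shape[1]
    return FeatureMatrix(values, names, ids, prov)


def reduce_pca(X: np.ndarray, variance_target: float = 0.95,
               train_rows=None):
    """PCA keeping the smallest component count whose cumulative explained
    variance reaches the target; fit on training rows only.

    Returns (reduced matrix for all rows, fitted PCA).
    """
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must lie in (0, 1]")
    X = np.asarray(X, dtype=float)
    fit_on = X if train_rows is None else X[train_rows]
    full = PCA()
    full.fit(fit_on)
    cum = np.cumsum(full.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_comp = min(n_comp, len(cum))
    pca = PCA(n_components=n_comp)
    pca.fit(fit_on)
    return pca.transform(X), pca


def _select_kernel(X, y, cfg: ClassifierConfig, rng) -> str:
    if cfg.fixed_kernel is not None:
        return cfg.fixed_kernel
    if len(cfg.kernels) == 1:
        return cfg.kernels[0]
    n = len(y)
    folds = min(cfg.inner_folds, np.bincount(y).min(), n)
    if folds < 2:
        return cfg.kernels[0]
    kf = KFold(n_splits=folds, shuffle=True,
               random_state=int(rng.integers(2**31)))
    best = (None, -np.inf)
    for kern in cfg.kernels:
        acc = []
        for tr, te in kf.split(X):
            if len(np.unique(y[tr])) < 2:
                continue
            clf = SVC(kernel=kern, class_weight=cfg.class_weight)
            clf.fit(X[tr], y[tr])
            acc.append((clf.predict(X[te]) == y[te]).mean())
        score = np.mean(acc) if acc else -np.inf
        if score > best[1]:
            best = (kern, score)
    return best[0] or cfg.kernels[0]


def _fit_predict(X_tr, y_tr, X_te, cfg: ClassifierConfig, rng):
    """Standardize -> PCA -> kernel-selected SVC, all fit on training rows."""
    scaler = StandardScaler().fit(X_tr)
    X_tr = scaler.transform(X_tr)
    X_te = scaler.transform(X_te)
    if cfg.use_pca and X_tr.shape[1] > 1:
        Xr, _ = reduce_pca(np.vstack([X_tr, X_te]), cfg.pca_variance,
                           train_rows=np.arange(len(X_tr)))
        X_tr, X_te = Xr[: len(X_tr)], Xr[len(X_tr):]
    kern = _select_kernel(X_tr, y_tr, cfg, rng)
    clf = SVC(kernel=kern, class_weight=cfg.class_weight)
    clf.fit(X_tr, y_tr)
    return clf.predict(X_te)


def _confusion(y_true, y_pred) -> np.ndarray:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    return np.array([[tp, fn], [fp, tn]])


def _metrics(conf: np.ndarray):
    (tp, fn), (fp, tn) = conf
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    acc = (tp + tn) / conf.sum() if conf.sum() else np.nan
    j = sens + spec - 1 if np.isfinite(sens) and np.isfinite(spec) else np.nan
    return sens, spec, acc, j


def _evaluate(X, y, strata, cfg: ClassifierConfig, seed: int
              ) -> PredictionReport:
    """Shared cross-validation engine; ``strata=None`` means pooled."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=seed)
    y_pred = np.full(n, -1)
    fold_confs = []
    groups = [None] if strata is None else sorted(set(strata))
    strata = None if strata is None else np.asarray(strata)
    for tr, te in kf.split(X):
        for g in groups:
            if g is None:
                tr_g, te_g = tr, te
            else:
                tr_g = tr[strata[tr] == g]
                te_g = te[strata[te] == g]
            if te_g.size == 0:
                continue
            if tr_g.size == 0 or len(np.unique(y[tr_g])) < 2:
                warnings.warn(
                    f"stratum {g!r}: single-class training data in a fold; "
                    "its held-out subjects are excluded from pooled metrics")
                continue
            y_pred[te_g] = _fit_predict(X[tr_g], y[tr_g], X[te_g], cfg, rng)
        fold_confs.append(_confusion(y[te][y_pred[te] >= 0],
                                     y_pred[te][y_pred[te] >= 0]))
    scored = y_pred >= 0
    conf = _confusion(y[scored], y_pred[scored])
    sens, spec, acc, j = _metrics(conf)
    per_subtype = {}
    if strata is not None:
        for g in groups:
            m = scored & (strata == g)
            c = _confusion(y[m], y_pred[m])
            s_, sp_, a_, j_ = _metrics(c)
            per_subtype[g] = {"sensitivity": s_, "specificity": sp_,
                              "accuracy": a_, "youden_j": j_, "n": int(m.sum())}
    return PredictionReport(sensitivity=sens, specificity=spec, accuracy=acc,
                            youden_j=j, confusion=conf,
                            fold_confusions=fold_confs,
                            per_subtype=per_subtype, config=cfg, seed=seed)


def evaluate_stratified(X, outcomes, subtypes, config=None, seed: int = 0
                        ) -> PredictionReport:
    """Ten-fold cross-validated subtype-stratified classifier: one SVM
    sub-classifier per subtype inside every fold; held-out subjects are
    predicted by their own subtype's sub-classifier and metrics pooled."""
    cfg = config or ClassifierConfig()
    X = X.values if isinstance(X, FeatureMatrix) else X
    return _evaluate(X, outcomes, subtypes, cfg, seed)


def evaluate_pooled(X, outcomes, config=None, seed: int = 0
                    ) -> PredictionReport:
    """Same folds and pipeline as the stratified evaluation, single
    classifier for everyone (the no-subtype-information baseline)."""
    cfg = config or ClassifierConfig()
    X = X.values if isinstance(X, FeatureMatrix) else X
    return _evaluate(X, outcomes, None, cfg, seed)


def permutation_test(X, outcomes, subtypes=None, config=None,
                     n_perm: int = 1000, seed: int = 0):
    """Permutation p-value for the cross-validated Youden index.

    Outcome labels are permuted and the full cross-validation rerun each
    time; p = (1 + #{J_perm >= J_obs}) / (1 + n_perm).
    Returns (p, observed report, permuted J array).
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives unstable p-values; refusing")
    cfg = config or ClassifierConfig()
    X = X.values if isinstance(X, FeatureMatrix) else X
    y = np.asarray(outcomes, dtype=int)
    obs = _evaluate(X, y, subtypes, cfg, seed)
    rng = np.random.default_rng(seed)
    j_perm = np.empty(n_perm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_perm):
            yp = rng.permutation(y)
            rep = _evaluate(X, yp, subtypes, cfg, seed)
            j_perm[b] = rep.youden_j
    p = (1.0 + np.sum(j_perm >= obs.youden_j)) / (1.0 + n_perm)
    obs.permutation_p = float(p)
    return float(p), obs, j_perm
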