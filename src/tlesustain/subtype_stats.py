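"""Subtype characterization statistics.

Stage-atrophy Spearman correlations, ROI-wise two-sample contrasts with
Benjamini-Hochberg FDR, one-vs-all and pairwise clinical comparisons (ANOVA
with LSD post-hoc tests for continuous variables, Pearson chi-square without
continuity correction for categorical ones), and seizure-freedom contingency
tables per treatment arm.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fitting import NORMAL_LABEL, SubjectAssignment
from .zscoring import ZScoreMatrix

__all__ = [
    "bh_fdr",
    "chi2_2x2",
    "stage_atrophy_correlation",
    "roiwise_group_comparison",
    "clinical_compare",
    "seizure_freedom_table",
]


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def chi2_2x2(table, correction: bool = False):
    """Pearson chi-square on a 2x2 table, no continuity correction by
    default (the convention used for the seizure-freedom contrasts).

    Returns (chi2, p).  Degenerate margins give (0, 1).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(t, correction=correction)
    return float(chi2), float(p)


def stage_atrophy_correlation(assign: SubjectAssignment, Z: ZScoreMatrix,
                              rois=None) -> pd.DataFrame:
    """Spearman correlation between SuStaIn stage and atrophy per trajectory
    subtype.

    ``rois`` selects the z-score column(s); multiple columns are averaged
    (e.g. mean cortical thickness z).  Subjects labelled "normal" are not
    staged on a trajectory and are excluded.
    """
    zf = Z.to_frame()
    cols = list(zf.columns) if rois is None else (
        [rois] if isinstance(rois, str) else list(rois))
    missing = [c for c in cols if c not in zf.columns]
    if missing:
        raise ValueError(f"unknown ROI(s): {missing}")
    summary = zf[cols].mean(axis=1)
    out = []
    tab = assign.table
    for label in sorted(set(tab["label"]) - {NORMAL_LABEL}):
        m = tab["label"] == label
        if int(m.sum()) < 3:
            warnings.warn(f"fewer than 3 staged subjects in {label}; skipped")
            continue
        stages = tab.loc[m, "stage"].to_numpy()
        vals = summary.loc[tab.index[m]].to_numpy()
        if np.all(stages == stages[0]) or np.all(vals == vals[0]):
            raise ValueError(f"constant input for {label}: "
                             "rank correlation undefined")
        res = stats.spearmanr(stages, vals)
        out.append({"subtype": label, "n": int(m.sum()),
                    "rho": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(out)


def roiwise_group_comparison(Z_a: ZScoreMatrix, Z_b: ZScoreMatrix,
                             equal_var: bool = True) -> pd.DataFrame:
    """ROI-wise two-sided two-sample t-tests (pooled variance by default)
    with BH-FDR across ROIs.

    Degenerate ROIs (zero pooled variance) are flagged and given p = 1 when
    the means agree, p = 0 when they differ.
    """
    if list(Z_a.rois) != list(Z_b.rois):
        raise ValueError("ROI sets differ between groups")
    if len(Z_a.subject_ids) < 2 or len(Z_b.subject_ids) < 2:
        raise ValueError("each group needs at least 2 subjects")
    A, B = Z_a.values, Z_b.values
    rows = []
    for i, roi in enumerate(Z_a.rois):
        a, b = A[:, i], B[:, i]
        degenerate = a.var(ddof=1) == 0 and b.var(ddof=1) == 0
        if degenerate:
            t, p = 0.0, 1.0
            if a.mean() != b.mean():
                t, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append({
            "roi": roi, "t": float(t), "p": float(p),
            "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
            "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
            "degenerate": bool(degenerate),
        })
    rep = pd.DataFrame(rows)
    rep["q"] = bh_fdr(rep["p"])
    return rep


def _anova_lsd(values: np.ndarray, groups: np.ndarray, levels):
    """One-way ANOVA plus LSD pairwise t-tests (unadjusted, pooled ANOVA
    error term)."""
    samples = [values[groups == g] for g in levels]
    F, p_anova = stats.f_oneway(*samples)
    n_tot = values.size
    k = len(levels)
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / (n_tot - k)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = samples[i], samples[j]
            se = np.sqrt(mse * (1 / a.size + 1 / b.size))
            t = (a.mean() - b.mean()) / se
            p = 2 * stats.t.sf(abs(t), n_tot - k)
            pairs.append((levels[i], levels[j], float(t), float(p)))
    return float(F), float(p_anova), pairs


def clinical_compare(clin: pd.DataFrame, labels: pd.Series,
                     mode: str = "one_vs_all",
                     continuous=None, categorical=None) -> pd.DataFrame:
    """Compare clinical variables across subtype labels.

    ``one_vs_all`` contrasts each subtype against all others (two-sample t /
    2 x L chi-square); ``pairwise`` contrasts every subtype pair (LSD t-tests
    on the pooled ANOVA error / 2 x L chi-square).  Continuous variables also
    report the omnibus ANOVA row.  BH-FDR is applied within each variable's
    family of contrasts.
    """
    if mode not in ("one_vs_all", "pairwise"):
        raise ValueError("mode must be 'one_vs_all' or 'pairwise'")
    labels = pd.Series(np.asarray(labels), index=clin.index)
    levels = sorted(labels.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 subtype labels")
    if continuous is None:
        continuous = [c for c in clin.columns
                      if pd.api.types.is_numeric_dtype(clin[c])
                      and clin[c].nunique() > 5 and c != "subject_id"]
    if categorical is None:
        categorical = [c for c in clin.columns
                       if c not in continuous and c != "subject_id"]
    rows = []
    for var in continuous:
        v = clin[var].to_numpy(dtype=float)
        F, pA, pairs = _anova_lsd(v, labels.to_numpy(), levels)
        fam = [{"variable": var, "contrast": "omnibus", "test": "anova_F",
                "statistic": F, "p": pA}]
        if mode == "pairwise":
            for a, b, t, p in pairs:
                fam.append({"variable": var, "contrast": f"{a}_vs_{b}",
                            "test": "lsd_t", "statistic": t, "p": p})
        else:
            for g in levels:
                a = v[labels == g]
                b = v[labels != g]
                t, p = stats.ttest_ind(a, b, equal_var=True)
                fam.append({"variable": var, "contrast": f"{g}_vs_rest",
                            "test": "t", "statistic": float(t), "p": float(p)})
        rows.append(fam)
    for var in categorical:
        v = clin[var]
        if v.nunique() < 2:
            warnings.warn(f"variable {var!r} has a single level; skipped")
            continue
        fam = []
        if mode == "one_vs_all":
            for g in levels:
                tab = pd.crosstab(labels == g, v)
                if tab.shape[0] < 2:
                    continue
                chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
                fam.append({"variable": var, "contrast": f"{g}_vs_rest",
                            "test": "chi2", "statistic": float(chi2),
                            "p": float(p)})
        else:
            for i in range(len(levels)):
                for j in range(i + 1, len(levels)):
                    m = labels.isin([levels[i], levels[j]])
                    tab = pd.crosstab(labels[m], v[m])
                    if min(tab.shape) < 2:
                        continue
                    chi2, p, _, _ = stats.chi2_contingency(tab,
                                                           correction=False)
                    fam.append({"variable": var,
                                "contrast": f"{levels[i]}_vs_{levels[j]}",
                                "test": "chi2", "statistic": float(chi2),
                                "p": float(p)})
        if fam:
            rows.append(fam)
    out = []
    for fam in rows:
        q = bh_fdr([r["p"] for r in fam])
        for r, qi in zip(fam, q):
            r["q"] = float(qi)
            out.append(r)
    return pd.DataFrame(out)


def seizure_freedom_table(clin: pd.DataFrame, labels: pd.Series,
                          arm: str) -> pd.DataFrame:
    """Follow-up seizure-freedom rates per subtype within one treatment arm,
    with one-vs-rest Pearson chi-square (no continuity correction).

    Subjects lost to follow-up are excluded from all denominators; the rate
    is effective / (effective + ineffective).
    """
    if "outcome" not in clin.columns:
        raise ValueError("clinical table lacks an outcome column")
    labels = pd.Series(np.asarray(labels), index=clin.index)
    m_arm = clin["treatment_arm"] == arm
    if not m_arm.any():
        raise ValueError(f"no subjects in treatment arm {arm!r}")
    sub = clin[m_arm & clin["outcome"].isin(["effective", "ineffective"])]
    lab = labels[sub.index]
    eff = (sub["outcome"] == "effective").astype(int)
    rows = []
    for g in sorted(lab.unique()):
        m = lab == g
        e, i = int(eff[m].sum()), int((~eff[m].astype(bool)).sum())
        re_, ri = int(eff[~m].sum()), int((~eff[~m].astype(bool)).sum())
        chi2, p = chi2_2x2([[e, i], [re_, ri]])
        rows.append({
            "arm": arm, "subtype": g,
            "effective": e, "ineffective": i,
            "rate_pct": 100.0 * e / (e + i) if e + i else np.nan,
            "rest_rate_pct": 100.0 * re_ / (re_ + ri) if re_ + ri else np.nan,
            "chi2": chi2, "p": p,
        })
    return pd.DataFrame(rows)
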