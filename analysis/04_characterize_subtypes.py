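"""Characterize the subtypes: stage-atrophy coupling, neuroanatomical
signatures and clinical/treatment-outcome contrasts.

Reproduces the characterization battery: Spearman correlation between
stage and mean modelled atrophy per trajectory; ROI-wise t-contrasts of
each subtype against the no-atrophy group with FDR; one-vs-all clinical
comparisons (ANOVA/LSD and chi-square); and the per-arm seizure-freedom
contingency tables with one-vs-rest chi-square.
"""

from pathlib import Path

import pandas as pd

from tlesustain import cohort_io, rois
from tlesustain.fitting import SubjectAssignment
from tlesustain.subtype_stats import (clinical_compare,
                                      roiwise_group_comparison,
                                      seizure_freedom_table,
                                      stage_atrophy_correlation)
from tlesustain.zscoring import select_modeling_rois

BASE = Path(__file__).resolve().parents[1] / "results"


def main():
    Z = cohort_io.read_zscores(BASE / "zscores.csv")
    Zm = select_modeling_rois(Z, rois.MODELING_ROIS)
    table = pd.read_csv(BASE / "assignments.csv", index_col="subject_id")
    assign = SubjectAssignment(
        table=table,
        posteriors=table.filter(like="p_trajectory").to_numpy())
    clin = cohort_io.read_clinical(BASE / "cohort" / "clinical.csv")
    labels = table.loc[clin["subject_id"], "label"]
    labels.index = clin.index

    rho = stage_atrophy_correlation(assign, Zm)
    rho.to_csv(BASE / "stage_atrophy_correlation.csv", index=False)
    print("stage vs mean modelled atrophy (Spearman):")
    print(rho.round(3).to_string(index=False))

    normal_ids = table.index[table["label"] == "normal"]
    reports = []
    for lab in sorted(set(table["label"]) - {"normal"}):
        ids = table.index[table["label"] == lab]
        rep = roiwise_group_comparison(Z.subset(ids), Z.subset(normal_ids))
        rep.insert(0, "contrast", f"{lab}_vs_normal")
        reports.append(rep)
        top = rep.sort_values("q").iloc[0]
        print(f"{lab} vs normal: strongest ROI contrast {top['roi']} "
              f"(t={top['t']:.1f}, q={top['q']:.2e})")
    pd.concat(reports).to_csv(BASE / "roiwise_contrasts.csv", index=False)

    drop = [c for c in ("subject_id", "outcome", "treatment_arm")
            if c in clin.columns]
    comp = clinical_compare(clin.drop(columns=drop), labels,
                            mode="one_vs_all")
    comp.to_csv(BASE / "clinical_comparisons.csv", index=False)
    sig = comp[comp["q"] < 0.05]
    print(f"clinical one-vs-all contrasts with q<0.05: {len(sig)} of "
          f"{len(comp)}")

    tabs = [seizure_freedom_table(clin, labels, arm) for arm in ("MG", "OG")]
    sf = pd.concat(tabs)
    sf.to_csv(BASE / "seizure_freedom.csv", index=False)
    print("seizure-freedom rates by arm and subtype:")
    print(sf.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
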