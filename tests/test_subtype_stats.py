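"""Characterization statistics: FDR, contingency and ANOVA oracles, plus
null-calibration simulations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlesustain.fitting import SubjectAssignment
from tlesustain.subtype_stats import (bh_fdr, chi2_2x2, clinical_compare,
                                      roiwise_group_comparison,
                                      seizure_freedom_table,
                                      stage_atrophy_correlation)
from tlesustain.zscoring import ZScoreMatrix


def _assignment(labels, stages):
    t = pd.DataFrame({"label": labels, "stage": stages})
    return SubjectAssignment(table=t, posteriors=np.ones((len(labels), 1)))


def _zmat(values, rois=None):
    values = np.asarray(values, dtype=float)
    rois = rois or [f"r{i}" for i in range(values.shape[1])]
    return ZScoreMatrix(values, list(range(values.shape[0])), rois)


class TestBhFdr:
    def test_hand_worked_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2,
                    max_size=25))
    @settings(max_examples=50, deadline=None)
    def test_step_up_definition_and_order_invariance(self, pvals):
        p = np.asarray(pvals)
        q = bh_fdr(p)
        m = len(p)
        order = np.argsort(p)
        # q_(i) = min_{j>=i} p_(j) * m / j, capped at 1
        expected = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.minimum(expected, 1.0)
        assert np.allclose(q[order], expected, atol=1e-12)
        assert np.all(q >= p - 1e-12)
        shuffled = np.random.default_rng(0).permutation(m)
        assert np.allclose(bh_fdr(p[shuffled]), q[shuffled])


class TestChi2:
    @given(st.lists(st.integers(min_value=1, max_value=80), min_size=4,
                    max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_closed_form_2x2(self, cells):
        a, b, c, d = cells
        chi2, _ = chi2_2x2([[a, b], [c, d]])
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        assert chi2 == pytest.approx(closed, rel=1e-10)

    def test_degenerate_margin(self):
        assert chi2_2x2([[0, 0], [3, 4]]) == (0.0, 1.0)

    def test_shape_check(self):
        with pytest.raises(ValueError):
            chi2_2x2([[1, 2, 3], [4, 5, 6]])


class TestStageAtrophyCorrelation:
    def test_monotone_gives_rho_one(self):
        stages = np.arange(20)
        Z = _zmat(stages[:, None] * 0.1)
        a = _assignment(["trajectory_1"] * 20, stages)
        rep = stage_atrophy_correlation(a, Z)
        assert rep.loc[0, "rho"] == pytest.approx(1.0)

    def test_null_noise(self):
        rng = np.random.default_rng(1)
        Z = _zmat(rng.normal(size=(100, 1)))
        a = _assignment(["trajectory_1"] * 100, rng.integers(0, 30, 100))
        rep = stage_atrophy_correlation(a, Z)
        assert abs(rep.loc[0, "rho"]) < 0.3
        assert rep.loc[0, "p"] > 0.001

    def test_constant_input_error(self):
        Z = _zmat(np.ones((10, 1)))
        a = _assignment(["trajectory_1"] * 10, np.arange(10))
        with pytest.raises(ValueError, match="constant"):
            stage_atrophy_correlation(a, Z)

    def test_normal_subtype_excluded(self):
        Z = _zmat(np.arange(8)[:, None].astype(float))
        a = _assignment(["trajectory_1"] * 4 + ["normal"] * 4,
                        [1, 2, 3, 4, 0, 0, 0, 0])
        rep = stage_atrophy_correlation(a, Z)
        assert list(rep["subtype"]) == ["trajectory_1"]


class TestRoiwiseComparison:
    def test_identical_groups(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(10, 5))
        rep = roiwise_group_comparison(_zmat(vals), _zmat(vals.copy()))
        assert np.allclose(rep["t"], 0.0)
        assert np.allclose(rep["q"], 1.0)

    def test_single_shifted_roi_detected_and_fdr_controlled(self):
        rng = np.random.default_rng(3)
        hits, fps = 0, []
        for rep_i in range(10):
            A = rng.normal(size=(50, 76))
            B = rng.normal(size=(50, 76))
            B[:, 7] += 2.0
            rep = roiwise_group_comparison(_zmat(A), _zmat(B))
            hits += rep.loc[7, "q"] < 0.01
            fps.append((rep.drop(index=7)["q"] < 0.05).mean())
        assert hits == 10
        assert np.mean(fps) <= 0.05

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            roiwise_group_comparison(_zmat(np.zeros((1, 3))),
                                     _zmat(np.zeros((5, 3))))


class TestClinicalCompare:
    def test_anova_closed_form_magnitude(self):
        # two groups, means 12.3 vs 18.0, sd 7, n=85/211: the subtype-onset
        # contrast scale; closed-form F is large and p far below 0.001
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 85) * 7
        a = (a - a.mean()) / a.std(ddof=0) * 7 + 12.3
        b = rng.normal(0, 1, 211) * 7
        b = (b - b.mean()) / b.std(ddof=0) * 7 + 18.0
        clin = pd.DataFrame({"onset": np.concatenate([a, b])})
        labels = ["s1"] * 85 + ["rest"] * 211
        rep = clinical_compare(clin, labels, mode="one_vs_all",
                               continuous=["onset"], categorical=[])
        omni = rep[rep["contrast"] == "omnibus"].iloc[0]
        assert omni["p"] < 0.001
        # exact F for the constructed summary stats: t^2 with the pooled
        # error term MSE = (85 + 211) * 49 / (296 - 2)
        mse = 49.0 * 296 / 294
        se = np.sqrt(mse * (1 / 85 + 1 / 211))
        assert omni["statistic"] == pytest.approx(((18.0 - 12.3) / se) ** 2,
                                                  rel=1e-6)

    def test_identical_groups_pairwise_p_one(self):
        vals = np.tile(np.arange(10.0), 2)
        clin = pd.DataFrame({"x": vals})
        labels = ["a"] * 10 + ["b"] * 10
        rep = clinical_compare(clin, labels, mode="pairwise",
                               continuous=["x"], categorical=[])
        pair = rep[rep["test"] == "lsd_t"].iloc[0]
        assert pair["p"] == pytest.approx(1.0)

    def test_categorical_equal_proportions(self):
        clin = pd.DataFrame({"flag": ["y", "n"] * 40})
        labels = np.repeat(["a", "b", "c", "d"], 20)
        rep = clinical_compare(clin, labels, mode="one_vs_all",
                               continuous=[], categorical=["flag"])
        assert np.allclose(rep["statistic"], 0.0, atol=1e-10)

    def test_single_level_variable_skipped(self):
        clin = pd.DataFrame({"flag": ["y"] * 20, "x": np.arange(20.0)})
        labels = ["a"] * 10 + ["b"] * 10
        with pytest.warns(UserWarning, match="single level"):
            rep = clinical_compare(clin, labels, continuous=["x"],
                                   categorical=["flag"])
        assert "flag" not in set(rep["variable"])

    def test_type_one_error_controlled_under_null(self):
        """Label-shuffled clinical data: the family-wise fraction of q<0.05
        across replicates stays at or below the nominal level."""
        rng = np.random.default_rng(5)
        frac = []
        for _ in range(100):
            clin = pd.DataFrame({"x": rng.normal(size=60),
                                 "y": rng.normal(size=60)})
            labels = rng.permutation(np.repeat(["a", "b", "c"], 20))
            rep = clinical_compare(clin, labels, mode="one_vs_all",
                                   continuous=["x", "y"], categorical=[])
            frac.append((rep["q"] < 0.05).mean())
        assert np.mean(frac) <= 0.05


class TestSeizureFreedom:
    MG = {"s1": (2, 20, 8), "s2": (5, 33, 18), "s3": (3, 16, 3),
          "s4": (11, 17, 8)}
    OG = {"s1": (36, 16, 3), "s2": (39, 15, 3), "s3": (12, 7, 0),
          "s4": (9, 11, 1)}

    @staticmethod
    def _clin(counts, arm):
        rows = []
        for st_, (e, i, l) in counts.items():
            rows += [(st_, "effective")] * e + [(st_, "ineffective")] * i \
                + [(st_, "lost")] * l
        clin = pd.DataFrame({"treatment_arm": arm,
                             "outcome": [r[1] for r in rows]})
        labels = pd.Series([r[0] for r in rows], index=clin.index)
        return clin, labels

    def test_medication_arm_contingency(self):
        clin, labels = self._clin(self.MG, "MG")
        t = seizure_freedom_table(clin, labels, "MG").set_index("subtype")
        assert t.loc["s4", "rate_pct"] == pytest.approx(39.29, abs=0.01)
        assert t.loc["s4", "rest_rate_pct"] == pytest.approx(12.66, abs=0.01)
        assert t.loc["s4", "chi2"] == pytest.approx(9.29, abs=0.01)

    def test_operative_arm_contingency(self):
        clin, labels = self._clin(self.OG, "OG")
        t = seizure_freedom_table(clin, labels, "OG").set_index("subtype")
        assert t.loc["s4", "rate_pct"] == pytest.approx(45.00, abs=0.01)
        assert t.loc["s4", "rest_rate_pct"] == pytest.approx(69.60, abs=0.01)
        assert t.loc["s4", "chi2"] == pytest.approx(4.66, abs=0.01)
        assert t.loc["s2", "rate_pct"] == pytest.approx(72.2, abs=0.05)
        assert t.loc["s3", "rate_pct"] == pytest.approx(63.2, abs=0.05)

    def test_all_effective(self):
        clin = pd.DataFrame({"treatment_arm": "OG",
                             "outcome": ["effective"] * 40})
        labels = pd.Series(np.repeat(["a", "b"], 20))
        t = seizure_freedom_table(clin, labels, "OG")
        assert np.allclose(t["rate_pct"], 100.0)
        assert np.allclose(t["chi2"], 0.0)

    def test_empty_arm(self):
        clin = pd.DataFrame({"treatment_arm": ["MG"], "outcome":
                             ["effective"]})
        with pytest.raises(ValueError, match="OG"):
            seizure_freedom_table(clin, pd.Series(["a"]), "OG")
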