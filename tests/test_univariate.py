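import numpy as np
import pandas as pd
import pytest
from scipy import stats

from breathflow import univariate
from breathflow.univariate import (kruskal_wallis, analyze_variable, lilliefors,
                                   posthoc_mean_ranks, relative_change_matrix,
                                   replicate_means, scfa_cluster_series)


class TestLilliefors:
    def test_type_one_error_calibrated(self):
        """Normal data at n=500: rejection rate over 1000 draws ~ alpha."""
        rng = np.random.default_rng(0)
        rejections = sum(
            lilliefors(rng.normal(size=500)).p_value < 0.05
            for _ in range(1000))
        assert abs(rejections / 1000 - 0.05) < 0.025

    def test_power_against_lognormal(self):
        rng = np.random.default_rng(1)
        rejections = sum(
            lilliefors(rng.lognormal(0, 1, size=200)).p_value < 0.05
            for _ in range(100))
        assert rejections / 100 > 0.9

    def test_statistic_affine_invariant(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        a = lilliefors(x).statistic
        b = lilliefors(5.0 * x - 3.0).statistic
        assert a == pytest.approx(b, abs=1e-12)

    def test_statistic_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.diagnostic")
        rng = np.random.default_rng(3)
        x = rng.lognormal(size=80)
        d_sm, p_sm = sm.lilliefors(x, dist="norm")
        res = lilliefors(x)
        assert res.statistic == pytest.approx(d_sm, abs=1e-10)
        # statsmodels' table p is approximate; agree on the decision
        assert (res.p_value < 0.05) == (p_sm < 0.05)

    def test_constant_sample_degenerate_non_normal(self):
        res = lilliefors(np.full(10, 3.0))
        assert res.p_value == 0.0 and "degenerate" in res.note

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            lilliefors([1.0, 2.0, 3.0])


class TestKruskalWallis:
    def test_hand_ranked_oracle(self):
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]], method="chi2")
        assert res.statistic == pytest.approx(7.2)
        assert res.p_value == pytest.approx(stats.chi2.sf(7.2, 2))

    def test_all_identical_values(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        groups = [rng.integers(0, 5, size=12).astype(float) for _ in range(3)]
        res = kruskal_wallis(groups, method="chi2")
        h_ref, p_ref = stats.kruskal(*groups)
        assert res.statistic == pytest.approx(h_ref, rel=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-12)

    def test_exact_and_chi2_agree_on_small_sample(self):
        groups = [[6.0, 7.0, 9.0], [4.0, 1.0, 2.0], [5.0, 8.0, 3.0]]
        p_exact = kruskal_wallis(groups, method="exact").p_value
        p_chi2 = kruskal_wallis(groups, method="chi2").p_value
        assert abs(p_exact - p_chi2) < 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestPosthocMeanRanks:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        res = posthoc_mean_ranks({"a": x, "b": x + rng.normal(0, 1e-6, 30)})
        assert res[0].p_value > 0.9

    def test_only_shifted_group_significant(self):
        rng = np.random.default_rng(6)
        groups = {"a": rng.normal(0, 1, 20), "b": rng.normal(0, 1, 20),
                  "c": rng.normal(6, 1, 20)}
        res = posthoc_mean_ranks(groups)
        by_pair = {r.groups: r.p_value for r in res}
        assert by_pair[("a", "b")] > 0.05
        assert by_pair[("a", "c")] < 0.01
        assert by_pair[("b", "c")] < 0.01

    def test_holm_adjustment_not_below_raw(self):
        rng = np.random.default_rng(7)
        groups = {"a": rng.normal(0, 1, 15), "b": rng.normal(0.5, 1, 15),
                  "c": rng.normal(1.0, 1, 15)}
        adj = posthoc_mean_ranks(groups, method="dunn")
        for r in adj:
            raw = 2 * stats.norm.sf(r.statistic)
            assert r.p_value >= raw - 1e-12


class TestDecisionRule:
    def test_normal_data_takes_anova_branch(self):
        rng = np.random.default_rng(8)
        groups = {"a": rng.normal(0, 1, 60), "b": rng.normal(0, 1, 60),
                  "c": rng.normal(0, 1, 60)}
        norm, omnibus, _ = analyze_variable(groups)
        assert not norm.significant and omnibus.test == "anova"

    def test_lognormal_data_takes_kruskal_branch(self):
        rng = np.random.default_rng(9)
        groups = {"a": rng.lognormal(0, 1, 60), "b": rng.lognormal(0, 1, 60),
                  "c": rng.lognormal(0, 1, 60)}
        norm, omnibus, _ = analyze_variable(groups)
        assert norm.significant and omnibus.test == "kruskal-wallis"


def toy_values():
    idx = pd.MultiIndex.from_tuples(
        [(p, tp, r) for p in ("P1", "P2") for tp in ("Day0", "Day1")
         for r in (1, 2)],
        names=["participant_id", "timepoint", "replicate"])
    rng = np.random.default_rng(10)
    values = pd.DataFrame(
        {ion: rng.lognormal(1, 0.1, len(idx))
         for ion in ("mz61.03", "mz75.05", "mz89.06")}, index=idx)
    design = pd.DataFrame({
        "participant_id": ["P1", "P2"], "group": ["St0", "St1"],
        "timepoint": ["Day0", "Day0"]})
    return values, design


class TestScfaCluster:
    def test_unit_concentrations_sum_to_three(self):
        values, design = toy_values()
        values.loc[:, :] = 1.0
        per_sample, _ = scfa_cluster_series(values, design)
        assert np.allclose(per_sample, 3.0)

    def test_missing_ion_reported(self):
        values, design = toy_values()
        with pytest.raises(ValueError, match="mz89.06"):
            scfa_cluster_series(values.drop(columns="mz89.06"), design)

    def test_group_means_match_brute_force(self):
        values, design = toy_values()
        per_sample, summary = scfa_cluster_series(values, design)
        for _, row in summary.iterrows():
            members = [
                v for (pid, tp), v in per_sample.items()
                if tp == row["timepoint"] and
                design.set_index("participant_id")["group"][pid] == row["group"]]
            assert row["mean"] == pytest.approx(np.mean(members))
            assert row["n"] == len(members)


class TestRelativeChange:
    def build(self, medians_by_cell):
        """One compound, one participant per group x timepoint cell."""
        rows, design_rows = [], []
        for i, ((g, tp), med) in enumerate(medians_by_cell.items()):
            pid = f"P{i}"
            rows.append(((pid, tp, 1), med))
            design_rows.append({"participant_id": pid, "group": g,
                                "timepoint": tp})
        idx = pd.MultiIndex.from_tuples(
            [r[0] for r in rows],
            names=["participant_id", "timepoint", "replicate"])
        values = pd.DataFrame({"mzA": [r[1] for r in rows]}, index=idx)
        return values, pd.DataFrame(design_rows)

    def test_hand_scaled_values(self):
        values, design = self.build({("St0", "Day0"): 2.0,
                                     ("St0", "Day1"): 4.0,
                                     ("St0", "Day2"): 6.0})
        rcm = relative_change_matrix(values, design)
        row = rcm.values.loc["mzA"]
        assert row[("St0", "Day0")] == pytest.approx(0.0)
        assert row[("St0", "Day1")] == pytest.approx(0.5)
        assert row[("St0", "Day2")] == pytest.approx(1.0)

    def test_scale_invariance(self):
        values, design = self.build({("St0", "Day0"): 2.0,
                                     ("St0", "Day1"): 4.0,
                                     ("St0", "Day2"): 6.0})
        a = relative_change_matrix(values, design).values
        b = relative_change_matrix(values * 37.5, design).values
        pd.testing.assert_frame_equal(a, b)

    def test_constant_compound_flagged_zero_row(self):
        values, design = self.build({("St0", "Day0"): 3.0,
                                     ("St0", "Day1"): 3.0})
        rcm = relative_change_matrix(values, design)
        assert rcm.flat_rows == ["mzA"]
        assert (rcm.values.loc["mzA"] == 0).all()

    def test_empty_reference_cell_rejected(self):
        values, design = self.build({("St1", "Day0"): 2.0,
                                     ("St1", "Day1"): 4.0})
        with pytest.raises(ValueError, match="reference"):
            relative_change_matrix(values, design)


def test_recovery_pattern_of_cell_medians(full_study, full_analysis):
    """Non-isoprene effect ions rise after day 1, dip at the rest sample
    and rise again; isoprene mirrors the pattern."""
    _, _, design, truth = full_study
    rcm = relative_change_matrix(
        full_analysis.matrix.retained_values(), design)
    effect_ions = [i for i in truth.exercise_responsive.index
                   if truth.exercise_responsive[i]
                   and i in rcm.values.index
                   and i not in full_analysis.exogenous_ions]
    assert len(effect_ions) >= 10
    for ion in effect_ions:
        row = rcm.values.loc[ion]
        day0, day1 = row[("St0", "Day0")], row[("St0", "Day1")]
        rest, day2 = row[("St0", "Day2am")], row[("St0", "Day2")]
        if ion == "mz69.07" or ion == "mz41.04":   # isoprene and fragment
            assert day1 < day0 and rest > day1 and day2 < rest
        else:
            assert day1 > day0 and rest < day1 and day2 > rest


def test_scfa_group_contrast_on_default_study(full_study, full_analysis):
    """Post-walking SCFA levels: St0 above both statin groups, no
    difference between the statin groups."""
    _, _, design, _ = full_study
    per_sample, _ = scfa_cluster_series(
        full_analysis.matrix.retained_values(), design)
    frame = per_sample.reset_index()
    group_of = design.drop_duplicates("participant_id").set_index(
        "participant_id")["group"]
    frame["group"] = frame["participant_id"].map(group_of)
    post = frame[frame["timepoint"].isin(["Day1", "Day2", "Day3"])]
    g = {k: post.loc[post.group == k, "scfa_ppbv"].to_numpy()
         for k in ("St0", "St1", "St2")}
    assert kruskal_wallis({k: g[k] for k in ("St0", "St1")},
                          method="chi2").p_value < 0.05
    assert kruskal_wallis({k: g[k] for k in ("St0", "St2")},
                          method="chi2").p_value < 0.05
    assert np.median(g["St0"]) > np.median(g["St1"])
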