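"""Statistical battery: oracles, identities, and the state decision table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fcstates import (StudyDesign, assign_state, bonferroni_adjust,
                      chi_square_test, classify_edge_states,
                      classify_node_metric_states, delta_correlations,
                      one_way_anova, p_from_r, paired_t, pearson_r,
                      two_sample_t, two_sample_t_from_summary)


class TestTwoSampleT:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = two_sample_t(x, list(x))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("variant", ["welch", "pooled"])
    def test_summary_form_agrees_with_raw(self, rng, variant):
        x = rng.standard_normal(14) * 2 + 1
        y = rng.standard_normal(9) * 3 - 0.5
        raw = two_sample_t(x, y, variant)
        summ = two_sample_t_from_summary(len(x), x.mean(), x.std(ddof=1),
                                         len(y), y.mean(), y.std(ddof=1),
                                         variant)
        assert summ.statistic == pytest.approx(raw.statistic, abs=1e-10)
        assert summ.p == pytest.approx(raw.p, abs=1e-10)
        assert summ.df == pytest.approx(raw.df, abs=1e-8)

    def test_equal_means_p_one(self):
        res = two_sample_t_from_summary(10, 5.0, 1.0, 12, 5.0, 2.0)
        assert res.p == pytest.approx(1.0)

    def test_label_exchange_flips_sign_only(self, rng):
        x, y = rng.standard_normal(10), rng.standard_normal(12) + 1
        a, b = two_sample_t(x, y), two_sample_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_matches_permutation_oracle(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20) + 0.5
        res = two_sample_t(x, y, "pooled")
        perm = sps.permutation_test(
            (x, y), lambda a, b, axis=-1: a.mean(axis=axis) - b.mean(axis=axis),
            permutation_type="independent", n_resamples=20000,
            rng=np.random.default_rng(0))
        assert res.p == pytest.approx(perm.pvalue, abs=0.02)


class TestPairedT:
    def test_no_change(self):
        pre = [1.0, 2.0, 3.0]
        res = paired_t(pre, list(pre))
        assert res.statistic == 0.0 and res.p == 1.0 and res.degenerate

    def test_constant_shift_degenerate(self):
        res = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.degenerate and res.p == 0.0 and res.statistic == np.inf

    def test_matches_one_sample_oracle(self, rng):
        pre = rng.standard_normal(15)
        post = pre + rng.standard_normal(15) * 0.5 + 0.2
        res = paired_t(pre, post)
        oracle = sps.ttest_1samp(post - pre, 0.0)
        assert res.statistic == pytest.approx(oracle.statistic, abs=1e-10)
        assert res.p == pytest.approx(oracle.pvalue, abs=1e-10)


class TestAnovaChi2:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = one_way_anova([g, list(g), list(g)])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.df == (2.0, 6.0)

    def test_two_group_f_equals_t_squared(self, rng):
        x, y = rng.standard_normal(10), rng.standard_normal(13) + 0.4
        f = one_way_anova([x, y])
        t = two_sample_t(x, y, "pooled")
        assert f.statistic == pytest.approx(t.statistic ** 2, abs=1e-10)
        assert f.p == pytest.approx(t.p, abs=1e-10)

    def test_three_groups_match_sum_of_squares_oracle(self, rng):
        groups = [rng.standard_normal(8) + d for d in (0.0, 0.3, 0.9)]
        res = one_way_anova(groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
        k, n = 3, len(allv)
        f = (ss_b / (k - 1)) / (ss_w / (n - k))
        assert res.statistic == pytest.approx(f, abs=1e-10)

    def test_chi2_proportional_table_zero(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_chi2_matches_expected_count_formula(self, rng):
        table = rng.integers(3, 30, (2, 3))
        res = chi_square_test(table)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row * col / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(chi2, abs=1e-10)
        assert res.df == 2.0  # k-1 for a 2 x 3 table

    def test_chi2_rejects_bad_tables(self):
        with pytest.raises(ValueError):
            chi_square_test([[1.5, 2.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [1, 2]])


class TestBonferroniAndCorrelation:
    def test_bonferroni_values(self):
        assert bonferroni_adjust([0.04], m=1)[0] == pytest.approx(0.04)
        assert bonferroni_adjust([0.01], m=10)[0] == pytest.approx(0.1)
        assert bonferroni_adjust([0.3], m=5)[0] == 1.0
        out = bonferroni_adjust([0.01, 0.02, 0.3])
        assert np.allclose(out, [0.03, 0.06, 0.9])

    def test_pearson_exact_cases(self, rng):
        x = rng.standard_normal(10)
        res = pearson_r(x, 2 * x + 1)
        assert res.statistic == pytest.approx(1.0)
        x = np.array([1.0, -1.0, 2.0, -2.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        y = y - y.mean()
        y = y - x * (x @ y) / (x @ x)  # orthogonalise after centring
        res = pearson_r(x, y)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_pearson_matches_permutation_oracle(self, rng):
        x = rng.standard_normal(20)
        y = 0.5 * x + rng.standard_normal(20)
        res = pearson_r(x, y)
        perm = sps.permutation_test(
            (x, y), lambda a, b: sps.pearsonr(a, b).statistic,
            permutation_type="pairings", n_resamples=20000,
            rng=np.random.default_rng(1))
        assert res.p == pytest.approx(perm.pvalue, abs=0.02)

    def test_p_from_r_agrees_with_pearson_p(self, rng):
        x = rng.standard_normal(24)
        y = 0.4 * x + rng.standard_normal(24)
        res = pearson_r(x, y)
        assert p_from_r(res.statistic, 24) == pytest.approx(res.p, abs=1e-10)
        assert p_from_r(0.0, 30) == pytest.approx(1.0)

    def test_p_from_r_input_validation(self):
        with pytest.raises(ValueError):
            p_from_r(1.0, 10)
        with pytest.raises(ValueError):
            p_from_r(0.5, 2)


class TestStateDecisionTable:
    @pytest.mark.parametrize("pattern,expected", [
        ((True, True, False), "cured"),
        ((True, False, False), "disorder"),
        ((True, False, True), "disorder"),
        ((False, True, True), "activated"),
        ((False, False, False), "unchanged"),
        ((False, True, False), "unchanged"),
        ((False, False, True), "unchanged"),
        ((True, True, True), "unchanged"),
    ])
    def test_all_patterns(self, pattern, expected):
        assert assign_state(*pattern) == expected

    def test_definitional_p_triple_is_cured(self):
        # (p1, p2, p3) = (0.001, 0.002, 0.60) at alpha 0.05, no correction
        assert assign_state(0.001 < 0.05, 0.002 < 0.05, 0.60 < 0.05) == "cured"

    def test_classify_edges_planted_pattern(self, rng):
        # edge 0: baseline-only shift restored after (cured);
        # edge 1: persistent shift (disorder); edge 2: null (unchanged)
        n_nc, n_pat = 20, 20
        nc = rng.standard_normal((n_nc, 3)) * 0.1
        bs = rng.standard_normal((n_pat, 3)) * 0.1
        post = rng.standard_normal((n_pat, 3)) * 0.1
        bs[:, 0] += 1.0
        bs[:, 1] += 1.0
        post[:, 1] += 1.0
        recs = classify_edge_states(nc, bs, post, ["e0", "e1", "e2"],
                                    alpha=0.05, correction="bonferroni")
        assert [r.state for r in recs] == ["cured", "disorder", "unchanged"]
        assert recs[0].direction == "increase"
        assert recs[0].nc_vs_bs.p_corrected >= recs[0].nc_vs_bs.p
        assert recs[1].anova.p < 0.05  # omnibus stored though unused

    def test_classify_is_deterministic_pure_function(self, rng):
        nc = rng.standard_normal((10, 4))
        bs = rng.standard_normal((12, 4))
        post = rng.standard_normal((12, 4))
        a = classify_edge_states(nc, bs, post, list("abcd"))
        b = classify_edge_states(nc, bs, post, list("abcd"))
        assert [r.state for r in a] == [r.state for r in b]
        assert all(r.state in ("disorder", "cured", "activated", "unchanged")
                   for r in a)

    def test_alpha_validation(self, rng):
        nc = rng.standard_normal((5, 2))
        with pytest.raises(ValueError, match="alpha"):
            classify_edge_states(nc, nc, nc, ["a", "b"], alpha=1.5)


class TestNodeMetricStates:
    def test_planted_degree_deficit_restored_is_cured(self, rng):
        controls = [f"NC{i}" for i in range(15)]
        patients = [f"P{i}" for i in range(15)]
        design = StudyDesign(controls, patients)
        rows = []
        for sid in controls:
            rows.append((sid, "single", "NC", "roiA",
                         20 + rng.normal(0, 1.0), 0.5, 0.5))
        for sid in patients:
            rows.append((sid, "baseline", "IBSbs", "roiA",
                         12 + rng.normal(0, 1.0), 0.5, 0.5))
            rows.append((sid, "post", "IBS1st", "roiA",
                         20 + rng.normal(0, 1.0), 0.5, 0.5))
        tab = pd.DataFrame(rows, columns=["subject_id", "session", "group",
                                          "roi", "degree", "clustering",
                                          "local_efficiency"])
        recs = classify_node_metric_states(tab, design, metrics=("degree",))
        assert len(recs) == 1
        assert recs[0].feature == ("roiA", "degree")
        assert recs[0].state == "cured"
        assert recs[0].direction == "decrease"

    def test_missing_pairing_raises(self, rng):
        design = StudyDesign(["NC0", "NC1"], ["P0", "P1"])
        rows = [("NC0", "single", "NC", "r", 1.0, 0, 0),
                ("NC1", "single", "NC", "r", 2.0, 0, 0),
                ("P0", "baseline", "IBSbs", "r", 1.0, 0, 0),
                ("P0", "post", "IBS1st", "r", 1.0, 0, 0),
                ("P1", "baseline", "IBSbs", "r", 1.0, 0, 0)]
        tab = pd.DataFrame(rows, columns=["subject_id", "session", "group",
                                          "roi", "degree", "clustering",
                                          "local_efficiency"])
        with pytest.raises(ValueError, match="P1"):
            classify_node_metric_states(tab, design, metrics=("degree",))


class TestDeltaCorrelations:
    def _clinical(self, patients, base, post_vals):
        rows = [{"subject_id": p, "session": "baseline", "ibs_sss": b,
                 "ibs_qol": np.nan, "hama": np.nan}
                for p, b in zip(patients, base)]
        rows += [{"subject_id": p, "session": "post", "ibs_sss": v,
                  "ibs_qol": np.nan, "hama": np.nan}
                 for p, v in zip(patients, post_vals)]
        return pd.DataFrame(rows)

    def test_identical_deltas_give_r_one(self, rng):
        patients = [f"P{i}" for i in range(10)]
        design = StudyDesign([], patients)
        deltas = rng.standard_normal(10)
        clin = self._clinical(patients, np.zeros(10), deltas)
        res = delta_correlations({("e", "x"): deltas}, clin, design,
                                 scores=("ibs_sss",))
        assert len(res) == 1
        assert res[0].r == pytest.approx(1.0)
        assert res[0].n == 10

    def test_incomplete_patient_dropped_from_n(self, rng):
        patients = [f"P{i}" for i in range(8)]
        design = StudyDesign([], patients)
        base = np.zeros(8)
        post = rng.standard_normal(8)
        post[3] = np.nan
        clin = self._clinical(patients, base, post)
        res = delta_correlations({("e", "x"): rng.standard_normal(8)}, clin,
                                 design, scores=("ibs_sss",))
        assert res[0].n == 7
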