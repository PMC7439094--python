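"""Fold changes, percentage reduction, gated tests, median test,
Tukey-Kramer letters, and the robust-change filter."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ccmetab as cm
from ccmetab.stratstats import GatedTestResult
from conftest import toy_design, toy_matrix


class TestFoldChange:
    def test_doubling(self):
        d = toy_design(["A"] * 6, ["VDS"] * 3 + ["VDD"] * 3)
        m = toy_matrix(np.array([1, 1, 1, 2, 2, 2], dtype=float)[:, None], d)
        fc = cm.fold_change(m, d)
        assert fc.loc["fold_change"].iloc[0] == pytest.approx(2.0)

    def test_identical_groups_give_one(self):
        d = toy_design(["A"] * 4, ["VDS", "VDS", "VDD", "VDD"])
        m = toy_matrix(np.array([3.0, 5.0, 3.0, 5.0])[:, None], d)
        assert cm.fold_change(m, d).loc["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_zero_vds_mean_flagged_undefined(self):
        d = toy_design(["A"] * 4, ["VDS", "VDS", "VDD", "VDD"])
        m = toy_matrix(np.array([0.0, 0.0, 2.0, 2.0])[:, None], d)
        assert np.isnan(cm.fold_change(m, d).loc["fold_change"].iloc[0])

    def test_by_strain_monte_carlo_coverage(self):
        """4.5-fold responder strain estimated within [3.4, 5.6] almost always."""
        target, hits, reps = 4.5, 0, 40
        for rep in range(reps):
            cfg = cm.SyntheticConfig(
                strains=("CC011", "CC017"),
                n_per_group={(s, d): 5 for s in ("CC011", "CC017")
                             for d in ("VDS", "VDD")},
                n_total=20, n_metabolites=30, n_diet_responsive=8,
                responder_specs=(("CC017", "set_g", math.log2(target), 6),),
                lod_quantile=0.0, seed=2000 + rep)
            matrix, design, truth = cm.simulate_study(cfg)
            fc = cm.fold_change(matrix, design, by_strain=True)
            est = fc.loc["CC017", truth.responder_sets["set_g"]].mean()
            hits += 3.4 <= est <= 5.6
        assert hits >= 0.9 * reps


class TestPctReduction:
    def _design_with_values(self, vds_vals, vdd_vals, strain="CC011"):
        n_vds, n_vdd = len(vds_vals), len(vdd_vals)
        d = toy_design([strain] * (n_vds + n_vdd),
                       ["VDS"] * n_vds + ["VDD"] * n_vdd)
        values = pd.Series(list(vds_vals) + list(vdd_vals), index=d.sample_ids)
        return d, values

    def test_printed_strain_means_give_minus_34_percent(self):
        d, values = self._design_with_values([15.9], [10.5])
        res = cm.pct_reduction_25ohd(values, d)
        assert res.per_sample.iloc[0] == pytest.approx(-33.96, abs=0.01)
        assert round(res.per_strain.loc["CC011", "mean"]) == -34

    def test_vdd_equal_to_vds_mean_is_zero(self):
        d, values = self._design_with_values([10.0, 14.0], [12.0])
        res = cm.pct_reduction_25ohd(values, d)
        assert res.per_sample.iloc[0] == pytest.approx(0.0)

    def test_all_zero_vdd_is_minus_100(self):
        d, values = self._design_with_values([8.0, 12.0], [0.0, 0.0])
        res = cm.pct_reduction_25ohd(values, d)
        assert np.allclose(res.per_sample, -100.0)

    def test_strain_mean_equals_mean_of_samples(self):
        rng = np.random.default_rng(0)
        d, values = self._design_with_values(rng.uniform(5, 20, 4),
                                             rng.uniform(2, 15, 5))
        res = cm.pct_reduction_25ohd(values, d)
        assert res.per_strain.loc["CC011", "mean"] == pytest.approx(
            res.per_sample.mean())

    def test_missing_vds_stratum_rejected(self):
        d = toy_design(["A", "A"], ["VDD", "VDD"])
        values = pd.Series([1.0, 2.0], index=d.sample_ids)
        with pytest.raises(cm.ValidationError, match="VDS"):
            cm.pct_reduction_25ohd(values, d)


class TestGatedTest:
    def test_clear_normal_shift_takes_parametric_branch(self):
        rng = np.random.default_rng(1)
        res = cm.gated_test([rng.normal(0, 1, 20), rng.normal(3, 1, 20)])
        assert res.test in ("t", "welch-t")
        assert res.p < 1e-3
        assert res.normal is True

    def test_identical_constant_groups_degenerate(self):
        with pytest.warns(UserWarning):
            res = cm.gated_test([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.p == 1.0 and res.test == "degenerate"

    def test_heavy_tailed_data_mostly_nonparametric(self):
        nonpar = 0
        for rep in range(100):
            rng = np.random.default_rng(3000 + rep)
            g1 = np.exp(rng.normal(0, 1.2, 15))
            g2 = np.exp(rng.normal(0, 1.2, 15))
            res = cm.gated_test([g1, g2])
            nonpar += res.test == "wilcoxon"
        assert nonpar > 50

    def test_normal_null_branch_rate_matches_gate_alpha(self):
        """Nonparametric branch rate ~= 1-(1-alpha)^2 for two normal groups."""
        nonpar = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(4000 + rep)
            res = cm.gated_test([rng.normal(size=20), rng.normal(size=20)])
            nonpar += res.test == "wilcoxon"
        expected = 1 - 0.95 ** 2
        band = 3 * math.sqrt(expected * (1 - expected) / reps)
        assert expected - band <= nonpar / reps <= expected + band

    def test_unequal_variance_routes_to_welch(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(0, 1, 30), rng.normal(0, 6, 30),
                  rng.normal(0, 1, 30)]
        res = cm.gated_test(groups)
        if res.normal:  # Shapiro can occasionally trip on a finite sample
            assert res.test in ("welch-anova", "anova")
            assert res.equal_variance is False

    def test_tiny_group_falls_back_nonparametric(self):
        with pytest.warns(UserWarning):
            res = cm.gated_test([[1.0], [2.0, 3.0, 4.0]])
        assert res.test in ("wilcoxon", "kruskal-wallis")

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        g1, g2 = rng.normal(0, 1, 12), rng.normal(1, 1, 12)
        p_fwd = cm.gated_test([g1, g2]).p
        p_rev = cm.gated_test([g2, g1]).p
        assert p_fwd == pytest.approx(p_rev)


class TestMedianTest:
    def test_separated_groups_fisher_exact(self):
        p = cm.median_test([[1, 2, 3], [10, 11, 12]])
        assert p == pytest.approx(0.1)

    def test_identical_groups(self):
        assert cm.median_test([[2, 2, 2], [2, 2, 2]]) == 1.0

    def test_agreement_with_scipy_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = rng.integers(2, 4)
            groups = [rng.normal(rng.uniform(-1, 1), 1, rng.integers(15, 30))
                      for _ in range(k)]
            expected = stats.contingency.expected_freq(
                np.array([[ (g > np.median(np.concatenate(groups))).sum(),
                            (g <= np.median(np.concatenate(groups))).sum()]
                          for g in groups]).T)
            if (expected < 5).any():
                continue  # our exact branch intentionally differs there
            p_pkg = cm.median_test(groups)
            _, p_ora, _, _ = stats.median_test(*groups, ties="below")
            assert p_pkg == pytest.approx(p_ora, abs=1e-8)


class TestTukeyKramer:
    def test_equal_means_share_a_letter(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(0, 1, 10) * 0.01 for _ in range(3)]
        res = cm.tukey_kramer(groups, labels=["x", "y", "z"])
        assert set(res.letters.values()) == {"a"}

    def test_outlying_group_gets_its_own_letter(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                  rng.normal(10, 1, 10)]
        res = cm.tukey_kramer(groups, labels=["g1", "g2", "g3"])
        assert res.letters["g1"] == res.letters["g2"] == "a"
        assert res.letters["g3"] == "b"

    def test_balanced_matches_statsmodels_oracle(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(10)
        groups = [rng.normal(mu, 1, 8) for mu in (0.0, 0.7, 1.5, 0.2)]
        res = cm.tukey_kramer(groups, labels=["a", "b", "c", "d"])
        data = np.concatenate(groups)
        labels = np.repeat(["a", "b", "c", "d"], 8)
        ora = pairwise_tukeyhsd(data, labels, alpha=0.05)
        for (g1, g2, *_), p in zip(ora.summary().data[1:], ora.pvalues):
            assert res.pairwise_p.loc[g1, g2] == pytest.approx(p, abs=1e-6)

    def test_two_groups_redirected(self):
        with pytest.raises(cm.ValidationError, match="two-group"):
            cm.tukey_kramer([[1.0, 2.0], [3.0, 4.0]])


class TestRobustChangeFilter:
    def _tables(self, vips, fcs):
        ids = [f"m{i}" for i in range(len(vips))]
        vip = pd.DataFrame({"rmsVIP": vips}, index=ids)
        resp = pd.DataFrame({"fold_change": fcs}, index=ids)
        return vip, resp

    def test_threshold_is_inclusive(self):
        vip, resp = self._tables([1.5, 1.4999], [2.0, 2.0])
        out = cm.robust_change_filter(vip, resp)
        assert bool(out["selected"].iloc[0]) and not bool(out["selected"].iloc[1])

    def test_symmetric_fold_threshold(self):
        vip, resp = self._tables([2.0, 2.0, 2.0], [0.6, 0.8, 1.6])
        out = cm.robust_change_filter(vip, resp)
        # 1/0.6 = 1.67 >= 1.5 counts; 1/0.8 = 1.25 does not
        assert out["robust"].tolist() == [True, False, True]

    def test_mismatched_ids_rejected(self):
        vip, resp = self._tables([2.0], [2.0])
        resp.index = ["other"]
        with pytest.raises(cm.ValidationError, match="mismatch"):
            cm.robust_change_filter(vip, resp)


class TestStrainResponseTable:
    def test_columns_and_letters_present(self, preprocessed_small):
        pre, design, _ = preprocessed_small
        sub = pre.values.iloc[:, :15]
        small = cm.AbundanceMatrix(values=sub, run_day=pre.run_day,
                                   stage="imputed")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = cm.strain_response_table(small, design)
        assert {"fold_change", "diet_p", "strain_effect_p",
                "diet_q_bh"} <= set(table.columns)
        assert table["diet_p"].between(0, 1).all()
        letters = table[[c for c in table.columns if c.startswith("letter_")]]
        assert (letters.apply(lambda c: c.str.len()) > 0).any().any()
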