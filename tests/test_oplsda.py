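"""OPLS-DA engine: oracle equivalence, orthogonality, VIP identities,
permutation counting, PCA, and one-vs-rest strain signatures."""

import numpy as np
import pandas as pd
import pytest

import ccmetab as cm
from ccmetab.oplsda import ModelError
from oracles import pls1_da_predictions, pca_from_covariance, vip_from_definition


def _random_instance(rng, n=16, p=12, sep=1.5):
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    X = rng.normal(size=(n, p))
    X[y == "b", : p // 3] += sep
    return X, y


class TestFitOplsda:
    def test_zero_ortho_equals_independent_pls1(self):
        """k_ortho=0 must reproduce one-component PLS1-DA to 1e-10."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            X, y = _random_instance(rng)
            model = cm.fit_oplsda(X, y, k_ortho=0, n_folds=4, seed=0)
            yhat_pkg = model.t_pred * model.q_pred + model.y_mean
            yhat_ora, r2y_ora = pls1_da_predictions(X, y)
            np.testing.assert_allclose(yhat_pkg, yhat_ora, atol=1e-10)
            assert model.r2y == pytest.approx(r2y_ora, abs=1e-10)

    def test_orthogonal_scores_orthogonal_to_y(self):
        rng = np.random.default_rng(1)
        for k_ortho in (1, 2):
            X, y = _random_instance(rng, n=24, p=30)
            model = cm.fit_oplsda(X, y, k_ortho=k_ortho, n_folds=4, seed=0)
            yc = np.where(y == "b", 1.0, -1.0)
            yc -= yc.mean()
            for a in range(k_ortho):
                assert abs(model.T_ortho[:, a] @ yc) < 1e-8

    def test_rank_one_class_aligned_is_perfectly_explained(self):
        rng = np.random.default_rng(2)
        y = np.array(["a"] * 8 + ["b"] * 8)
        yc = np.where(y == "b", 1.0, -1.0)
        v = rng.normal(size=10)
        X = np.outer(yc, v)
        model = cm.fit_oplsda(X, y, k_ortho=0, scaling="center",
                              n_folds=4, seed=0)
        assert model.r2y == pytest.approx(1.0, abs=1e-12)
        assert model.q2 > 0.99

    def test_removing_nuisance_direction_improves_q2(self):
        """A class-orthogonal structured direction hurts PLS1; OPLS-DA's
        orthogonal filter recovers the lost predictive power."""
        rng = np.random.default_rng(3)
        n, p = 20, 30
        y = np.array(["a", "b"] * (n // 2))
        yc = np.where(y == "b", 1.0, -1.0)
        g = rng.normal(size=n)
        g -= g @ yc / (yc @ yc) * yc  # nuisance scores, orthogonal to class
        v = rng.normal(size=p)
        u = rng.normal(size=p)
        X = np.outer(yc, v) + 4.0 * np.outer(g, u) + 0.1 * rng.normal(size=(n, p))
        plain = cm.fit_oplsda(X, y, k_ortho=0, n_folds=5, seed=7)
        opls = cm.fit_oplsda(X, y, k_ortho=1, n_folds=5, seed=7)
        assert opls.q2 >= plain.q2
        assert abs(opls.T_ortho[:, 0] @ (yc - yc.mean())) < 1e-8

    def test_q2_not_above_r2y_and_r2y_grows_with_k_ortho(self):
        rng = np.random.default_rng(4)
        X, y = _random_instance(rng, n=20, p=15)
        prev_r2y = -np.inf
        for k in (0, 1, 2):
            m = cm.fit_oplsda(X, y, k_ortho=k, n_folds=5, seed=1)
            assert m.q2 <= m.r2y + 1e-12
            assert m.r2y >= prev_r2y - 1e-12
            prev_r2y = m.r2y

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X, y = _random_instance(rng)
        m1 = cm.fit_oplsda(X, y, seed=9, n_folds=4)
        m2 = cm.fit_oplsda(X, y, seed=9, n_folds=4)
        assert m1.q2 == m2.q2 and m1.r2y == m2.r2y
        np.testing.assert_array_equal(m1.w_pred, m2.w_pred)

    def test_errors(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(8, 5))
        with pytest.raises(ModelError, match="2 classes"):
            cm.fit_oplsda(X, ["a"] * 8, n_folds=2)
        y = ["a"] * 4 + ["b"] * 4
        with pytest.raises(ModelError, match="rank"):
            cm.fit_oplsda(X, y, k_ortho=5, n_folds=2)
        Xn = X.copy()
        Xn[0, 0] = np.nan
        with pytest.raises(ModelError, match="missing"):
            cm.fit_oplsda(Xn, y, n_folds=2)


class TestVip:
    def test_mean_square_is_one_and_rms_matches_definition(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 5))
        y = ["a", "b"] * 4
        model = cm.fit_oplsda(X, y, k_ortho=1, n_folds=2, seed=0)
        vip = cm.compute_vip(model)
        assert (vip["VIP_pred"] ** 2).mean() == pytest.approx(1.0, abs=1e-10)
        assert (vip["VIP_ortho"] ** 2).mean() == pytest.approx(1.0, abs=1e-10)
        # recompute from the raw definition
        vp = vip_from_definition(model.w_pred[:, None], np.array([1.0]))
        np.testing.assert_allclose(vip["VIP_pred"], vp, atol=1e-12)
        vo = vip_from_definition(model.W_ortho, model.r2x_ortho)
        np.testing.assert_allclose(vip["VIP_ortho"], vo, atol=1e-12)
        rms = np.sqrt((vp ** 2 + vo ** 2) / 2)
        np.testing.assert_allclose(vip["rmsVIP"], rms, atol=1e-12)

    def test_single_variable_vip_is_one(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 1))
        y = ["a", "b"] * 5
        model = cm.fit_oplsda(X, y, k_ortho=0, n_folds=2, seed=0)
        vip = cm.compute_vip(model)
        assert vip["VIP_pred"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_concentrated_weight_closed_form(self):
        """If all predictive weight sits on one variable, its VIP is sqrt(p)."""
        n, p = 12, 6
        y = np.array(["a", "b"] * (n // 2))
        yc = np.where(y == "b", 1.0, -1.0)
        rng = np.random.default_rng(9)
        X = rng.normal(size=(n, p)) * 0.01
        X[:, 2] = yc  # only variable 2 carries class signal
        model = cm.fit_oplsda(X, y, k_ortho=0, scaling="center",
                              n_folds=2, seed=0)
        vip = cm.compute_vip(model)
        assert vip["VIP_pred"].iloc[2] == pytest.approx(np.sqrt(p), rel=1e-3)


class TestPermutationTest:
    def test_counting_formula_at_strong_signal(self):
        rng = np.random.default_rng(10)
        y = np.array(["a"] * 10 + ["b"] * 10)
        yc = np.where(y == "b", 1.0, -1.0)
        X = np.outer(yc, rng.normal(size=15)) + 0.05 * rng.normal(size=(20, 15))
        res = cm.permutation_test(X, y, n_perm=99, n_folds=5, seed=0)
        assert (res.q2_permuted >= res.q2_observed).sum() == 0
        assert res.p_q2 == pytest.approx(1 / 100)

    def test_addone_rule_consistency(self):
        rng = np.random.default_rng(11)
        X, y = _random_instance(rng, n=14, p=8, sep=0.3)
        res = cm.permutation_test(X, y, n_perm=49, n_folds=3, seed=2)
        expect = (1 + (res.q2_permuted >= res.q2_observed).sum()) / 50
        assert res.p_q2 == pytest.approx(expect)
        assert 0 < res.p_q2 <= 1 and len(res.q2_permuted) == 49

    def test_deterministic_and_rejects_bad_nperm(self):
        rng = np.random.default_rng(12)
        X, y = _random_instance(rng, n=12, p=6)
        r1 = cm.permutation_test(X, y, n_perm=19, n_folds=3, seed=5)
        r2 = cm.permutation_test(X, y, n_perm=19, n_folds=3, seed=5)
        np.testing.assert_array_equal(r1.q2_permuted, r2.q2_permuted)
        with pytest.raises(ModelError):
            cm.permutation_test(X, y, n_perm=0, n_folds=3, seed=0)


class TestPca:
    def test_collinear_points_explained_by_first_component(self):
        t = np.linspace(-2, 2, 9)
        X = np.column_stack([t, 3 * t])
        scores, loadings, evr = cm.pca(X, n_components=1)
        assert evr[0] == pytest.approx(1.0)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(12, 7))
        scores, _, _ = cm.pca(X, n_components=4)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(10, 6))
        scores, loadings, evr = cm.pca(X, n_components=3)
        s_ora, l_ora, evr_ora = pca_from_covariance(X, 3)
        np.testing.assert_allclose(evr, evr_ora, atol=1e-8)
        for k in range(3):  # eigenvector signs are arbitrary
            sign = np.sign(loadings[:, k] @ l_ora[:, k])
            np.testing.assert_allclose(loadings[:, k], sign * l_ora[:, k],
                                       atol=1e-8)
            np.testing.assert_allclose(scores[:, k], sign * s_ora[:, k],
                                       atol=1e-8)

    def test_rank_limit(self):
        X = np.ones((5, 3))
        with pytest.raises(ModelError):
            cm.pca(X, n_components=2)


class TestStrainSignature:
    def test_recovers_injected_strain_shift(self):
        cfg = cm.SyntheticConfig(
            strains=("CC001", "CC011", "CC017", "CC032"),
            n_total=40, n_metabolites=120, n_diet_responsive=0,
            responder_specs=(),
            strain_shift_specs=(
                ("CC011", [f"met{j + 1:04d}" for j in range(30)], 2.0),),
            seed=31,
        )
        matrix, design, _ = cm.simulate_study(cfg)
        pre = cm.preprocess(matrix)
        _, vip, signature = cm.strain_signature(pre, design, "CC011", "VDS",
                                                seed=0)
        shifted = {f"met{j + 1:04d}" for j in range(30)}
        assert len(shifted & set(signature)) / 30 >= 0.8

    def test_specificity_under_null(self):
        """Without strain effects, one-vs-rest separation is insignificant."""
        non_sig = 0
        reps = 12
        for rep in range(reps):
            cfg = cm.SyntheticConfig(
                strains=("CC001", "CC011"), n_total=24,
                n_per_group={(s, d): 6 for s in ("CC001", "CC011")
                             for d in ("VDS", "VDD")},
                n_metabolites=60, n_diet_responsive=0, responder_specs=(),
                frac_strain_affected=0.0, lod_quantile=0.0, seed=500 + rep,
            )
            matrix, design, _ = cm.simulate_study(cfg)
            pre = cm.preprocess(matrix)
            stratum = design.table.index[design.table["diet"] == "VDS"]
            y = np.where(design.table.loc[stratum, "strain"] == "CC011",
                         "CC011", "other")
            res = cm.permutation_test(pre.values.loc[stratum], y,
                                      n_perm=39, n_folds=3, seed=rep)
            non_sig += res.p_q2 > 0.05
        assert non_sig >= 0.75 * reps

    def test_single_strain_stratum_rejected(self, small_study):
        matrix, design, _ = small_study
        pre = cm.preprocess(matrix)
        only = design.table.index[design.table["strain"] == "CC017"]
        sub_design = design.subset(only)
        sub_matrix = cm.AbundanceMatrix(values=pre.values.loc[only],
                                        run_day=pre.run_day.loc[only],
                                        stage="imputed")
        with pytest.raises(ModelError):
            cm.strain_signature(sub_matrix, sub_design, "CC017", "VDS")

    def test_absent_strain_rejected(self, small_study):
        matrix, design, _ = small_study
        pre = cm.preprocess(matrix)
        with pytest.raises(ModelError, match="absent"):
            cm.strain_signature(pre, design, "CC042", "VDS")
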