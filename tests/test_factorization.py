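"""Alternating constrained least-squares fitting."""

import numpy as np
import pandas as pd
import pytest

import tfactivity as T
from tfactivity.constraints import ActivityBounds, activity_bounds
from tfactivity.factorization import _sse
from tfactivity.reference import projected_gradient_fit


def _one_gene_setup(sign):
    net = T.NetworkMap.from_edges([("F", "g1"), ("F", "g2")])
    signs = T.SignConstraintMatrix.from_edge_signs(
        {("F", "g1"): sign, ("F", "g2"): sign}, net
    )
    tfa = T.ActivityMatrix(
        pd.DataFrame([[1.0, 2.0, 3.0]], index=["F"], columns=["s1", "s2", "s3"])
    )
    expr = T.ExpressionMatrix(
        pd.DataFrame(
            [[3.0, 5.0, 7.0], [3.0, 5.0, 7.0]],
            index=["g1", "g2"],
            columns=["s1", "s2", "s3"],
        )
    )
    return expr, tfa, signs


class TestCSStep:
    def test_exact_linear_solve(self):
        expr, tfa, signs = _one_gene_setup(+1)
        cs = T.cs_step(expr, tfa, signs)
        assert cs.baselines.loc["g1"] == pytest.approx(1.0, abs=1e-9)
        assert cs.cs.loc["g1", "F"] == pytest.approx(2.0, abs=1e-9)

    def test_wrong_sign_pins_cs_at_zero(self):
        expr, tfa, signs = _one_gene_setup(-1)
        cs = T.cs_step(expr, tfa, signs)
        assert cs.cs.loc["g1", "F"] == pytest.approx(0.0, abs=1e-12)
        assert cs.baselines.loc["g1"] == pytest.approx(5.0, abs=1e-9)
        # brute force over cs <= 0 with optimal intercept per cs
        a = np.array([1.0, 2.0, 3.0])
        e = np.array([3.0, 5.0, 7.0])
        grid = np.linspace(-5, 0, 2001)
        sses = [np.sum((e - np.mean(e - c * a) - c * a) ** 2) for c in grid]
        best = grid[int(np.argmin(sses))]
        assert best == pytest.approx(0.0, abs=1e-6)
        assert min(sses) >= _sse_one(e, a, 0.0) - 1e-9

    def test_noiseless_identifiability(self, rng):
        net = T.NetworkMap.from_edges([("F", "g1"), ("F", "g2"), ("H", "g1"), ("H", "g2")])
        signs = T.SignConstraintMatrix.from_edge_signs(
            {("F", "g1"): 1, ("F", "g2"): -1, ("H", "g1"): -1, ("H", "g2"): 1}, net
        )
        A = pd.DataFrame(
            rng.uniform(0.2, 2.0, size=(2, 6)),
            index=["F", "H"],
            columns=[f"s{i}" for i in range(6)],
        )
        true_cs = pd.DataFrame(
            [[1.5, -0.7], [-0.9, 1.2]], index=["g1", "g2"], columns=["F", "H"]
        )
        b = pd.Series([5.0, 6.0], index=["g1", "g2"])
        E = T.ExpressionMatrix(true_cs @ A + np.outer(b, np.ones(6)))
        cs = T.cs_step(E, T.ActivityMatrix(A), signs)
        np.testing.assert_allclose(cs.cs.to_numpy(), true_cs.to_numpy(), atol=1e-8)
        np.testing.assert_allclose(cs.baselines.to_numpy(), b.to_numpy(), atol=1e-8)


def _sse_one(e, a, c):
    b = np.mean(e - c * a)
    return float(np.sum((e - b - c * a) ** 2))


class TestTFAStep:
    def _cs(self):
        net_genes = ["g1", "g2", "g3"]
        cs = pd.DataFrame(
            [[1.0, 0.0], [0.5, 1.5], [0.0, -1.0]], index=net_genes, columns=["F", "H"]
        )
        return T.ControlStrengthMatrix(cs, pd.Series([5.0, 4.0, 6.0], index=net_genes))

    def test_deletion_activity_exactly_zero(self):
        cs = self._cs()
        key = T.PerturbationKey({"ko": ("F", "deletion")}, ("wt",))
        bounds = activity_bounds(key, ["F", "H"], ["wt", "ko"])
        rng = np.random.default_rng(1)
        E = T.ExpressionMatrix(
            pd.DataFrame(
                rng.normal(5, 1, size=(3, 2)), index=cs.gene_ids, columns=["wt", "ko"]
            )
        )
        tfa = T.tfa_step(E, cs, bounds)
        assert tfa.activities.loc["F", "ko"] == 0.0
        assert tfa.activities.loc["H", "ko"] >= 1e-4

    def test_noiseless_recovery_with_slack_bounds(self):
        cs = self._cs()
        A_true = pd.DataFrame(
            [[1.0, 0.4, 2.0], [0.7, 1.9, 0.3]], index=["F", "H"],
            columns=["s1", "s2", "s3"],
        )
        E = T.ExpressionMatrix(
            cs.cs @ A_true + np.outer(cs.baselines, np.ones(3))
        )
        bounds = ActivityBounds.floor_only(["F", "H"], ["s1", "s2", "s3"])
        tfa = T.tfa_step(E, cs, bounds)
        np.testing.assert_allclose(tfa.values, A_true.to_numpy(), atol=1e-8)

    def test_overexpression_sits_at_bound_when_optimum_below(self):
        cs = self._cs()
        key = T.PerturbationKey({"oe": ("F", "overexpression")}, ("wt",))
        bounds = activity_bounds(key, ["F", "H"], ["wt", "oe"])
        # expression in 'oe' generated with F LOW, so the unconstrained
        # optimum violates the overexpression bound
        A_gen = pd.DataFrame(
            [[1.0, 0.1], [0.8, 0.9]], index=["F", "H"], columns=["wt", "oe"]
        )
        E = T.ExpressionMatrix(cs.cs @ A_gen + np.outer(cs.baselines, np.ones(2)))
        tfa = T.tfa_step(E, cs, bounds)
        ref = tfa.activities.loc["F", "wt"]
        assert tfa.activities.loc["F", "oe"] == pytest.approx(ref + 1e-4, abs=1e-10)
        # brute-force 1-d check: constrained optimum of the OE sample over
        # a grid never beats the solver's objective
        C = cs.cs.to_numpy()
        resid = E.data["oe"].to_numpy() - cs.baselines.to_numpy()
        aH = tfa.activities.loc["H", "oe"]
        sol = float(
            np.sum((resid - C @ np.array([tfa.activities.loc["F", "oe"], aH])) ** 2)
        )
        for aF in np.linspace(ref + 1e-4, ref + 2.0, 400):
            for aH_g in np.linspace(1e-4, 3.0, 200):
                val = float(np.sum((resid - C @ np.array([aF, aH_g])) ** 2))
                assert val >= sol - 1e-9


class TestNormalize:
    def test_mean_one_and_product_preserved(self, small_fit):
        cs, tfa = small_fit.cs, small_fit.tfa
        before = cs.cs.to_numpy() @ tfa.values
        cs2, tfa2 = T.normalize_mean_activity(cs, tfa)
        assert np.allclose(tfa2.activities.mean(axis=1).to_numpy(), 1.0, atol=1e-12)
        after = cs2.cs.to_numpy() @ tfa2.values
        assert np.max(np.abs(before - after)) < 1e-10

    def test_idempotent(self, small_fit):
        cs1, tfa1 = T.normalize_mean_activity(small_fit.cs, small_fit.tfa)
        cs2, tfa2 = T.normalize_mean_activity(cs1, tfa1)
        pd.testing.assert_frame_equal(tfa1.activities, tfa2.activities)
        pd.testing.assert_frame_equal(cs1.cs, cs2.cs)

    def test_zero_mean_row_errors(self):
        cs = T.ControlStrengthMatrix(
            pd.DataFrame([[1.0]], index=["g"], columns=["F"]),
            pd.Series([0.0], index=["g"]),
        )
        tfa = T.ActivityMatrix(pd.DataFrame([[0.0, 0.0]], index=["F"], columns=["a", "b"]))
        with pytest.raises(T.ValidationError, match="F"):
            T.normalize_mean_activity(cs, tfa)


class TestFitModel:
    def test_noiseless_recovery(self, small_truth, small_noiseless, small_fit):
        res = small_fit
        assert res.r2_train[-1] >= 0.999
        truth_cs, truth_tfa = T.normalize_mean_activity(
            small_truth.cs, small_truth.tfa
        )
        fit = res.tfa.activities
        true = truth_tfa.activities.loc[fit.index, fit.columns]
        for tf in fit.index:
            assert np.corrcoef(fit.loc[tf], true.loc[tf])[0, 1] >= 0.99

    def test_training_r2_monotone(self, small_fit):
        r2 = np.asarray(small_fit.r2_train)
        assert np.all(np.diff(r2) >= -1e-9)

    def test_fitted_cs_signs_match_truth(self, small_truth, small_fit):
        for tf in small_truth.net.tfs:
            for g in small_truth.net.targets_of(tf):
                fitted = small_fit.cs.cs.loc[g, tf]
                assert fitted * small_truth.signs.sign_of(tf, g) >= 0

    def test_scale_invariance_of_normalized_solution(self, small_truth):
        # scaling a TF's true CS column by c and its activities by 1/c
        # yields identical data, hence an identical fit
        gt = small_truth
        c = 3.0
        tf0 = gt.net.tfs[0]
        cs_scaled = gt.cs.cs.copy()
        cs_scaled[tf0] *= c
        tfa_scaled = gt.tfa.activities.copy()
        tfa_scaled.loc[tf0] /= c
        E1 = T.generate_expression(gt, 0.0, seed=12)
        pred2 = cs_scaled.to_numpy() @ tfa_scaled.to_numpy() + gt.cs.baselines.to_numpy()[:, None]
        E2 = T.ExpressionMatrix(
            pd.DataFrame(pred2, index=gt.cs.gene_ids, columns=gt.tfa.sample_ids)
        )
        np.testing.assert_allclose(E1.values, E2.values, atol=1e-9)

    def test_seed_reproducibility(self, small_truth, small_noiseless):
        cfg = T.FitConfig(n_inits=1, max_iter=5, seed=9)
        r1 = T.fit_model(
            small_noiseless, small_truth.net, small_truth.signs, small_truth.key, cfg
        )
        r2 = T.fit_model(
            small_noiseless, small_truth.net, small_truth.signs, small_truth.key, cfg
        )
        pd.testing.assert_frame_equal(r1.cs.cs, r2.cs.cs)
        pd.testing.assert_frame_equal(r1.tfa.activities, r2.tfa.activities)

    def test_activity_bounds_respected(self, small_truth, small_fit):
        small_fit.tfa.validate_against(small_truth.key)

    def test_oracle_equivalence_small_instance(self):
        cfg = T.GeneratorConfig(
            n_tfs=3, n_genes=12, targets_per_tf=(3, 6), noise_sd=0.3,
            n_unperturbed=2, seed=21,
        )
        gt = T.generate_ground_truth(cfg)
        e = T.generate_expression(gt, 0.3, seed=22)
        fc = T.FitConfig(
            n_inits=5, max_iter=100, seed=1, stopping="train_converge", train_tol=1e-10
        )
        res = T.fit_model(e, gt.net, gt.signs, gt.key, fc)
        esub = T.ExpressionMatrix(e.data.loc[res.cs.gene_ids, res.tfa.sample_ids])
        als = _sse(esub, res.cs, res.tfa)
        bounds = activity_bounds(gt.key, gt.net.tfs, res.tfa.sample_ids)
        oracle_sse, _, _ = projected_gradient_fit(esub, gt.signs, bounds, seed=2)
        assert als <= 1.01 * oracle_sse


class TestRefit:
    def test_constant_shift_absorbed_by_baselines(self, small_truth, small_fit):
        gt = small_truth
        e2 = T.generate_expression(gt, 0.0, seed=30)
        tfa_a, base_a, _ = T.refit_activities(e2, small_fit.cs)
        shifted = T.ExpressionMatrix(e2.data + 2.5)
        tfa_b, base_b, _ = T.refit_activities(shifted, small_fit.cs)
        np.testing.assert_allclose(
            base_b.to_numpy(), base_a.to_numpy() + 2.5, atol=1e-6
        )
        np.testing.assert_allclose(tfa_b.values, tfa_a.values, atol=1e-6)

    def test_recovery_up_to_cs_scale(self, small_truth, small_fit):
        gt = small_truth
        e2 = T.generate_expression(gt, 0.0, seed=31)
        tfa2, _, r2 = T.refit_activities(e2, small_fit.cs)
        assert r2 >= 0.999
        true = gt.tfa.activities.loc[tfa2.tf_ids, tfa2.sample_ids]
        for tf in tfa2.tf_ids:
            assert np.corrcoef(tfa2.activities.loc[tf], true.loc[tf])[0, 1] >= 0.99

    def test_empty_gene_intersection_errors(self, small_fit):
        off = T.ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0]], index=["nope"], columns=["a", "b"])
        )
        with pytest.raises(T.ValidationError):
            T.refit_activities(off, small_fit.cs)


class TestSignedBinaryAndR2:
    def test_signed_binary_values(self, small_truth):
        cs = T.signed_binary_cs(small_truth.signs)
        S = small_truth.signs.signs
        assert ((cs.cs == S).to_numpy()).all()
        assert (cs.baselines == 0).all()

    def test_perfect_reconstruction_r2_one(self, small_truth):
        gt = small_truth
        e = T.generate_expression(gt, 0.0, seed=12)
        esub = T.ExpressionMatrix(e.data.loc[gt.cs.gene_ids])
        assert T.variance_explained(esub, gt.cs, gt.tfa) == pytest.approx(1.0, abs=1e-12)

    def test_baseline_only_model_r2_zero(self, small_truth):
        gt = small_truth
        e = T.generate_expression(gt, 0.0, seed=12)
        zero_cs = T.ControlStrengthMatrix(
            gt.cs.cs * 0.0, e.data.mean(axis=1)
        )
        assert T.variance_explained(e, zero_cs, gt.tfa) == pytest.approx(0.0, abs=1e-12)

    def test_fitted_beats_random_cs(self, small_truth, small_noiseless, small_fit, rng):
        gt = small_truth
        random_cs = T.ControlStrengthMatrix(
            gt.signs.signs.astype(float)
            * rng.uniform(0.2, 2.0, size=gt.signs.signs.shape),
            small_noiseless.data.loc[gt.signs.signs.index].mean(axis=1),
        )
        random_tfa = T.ActivityMatrix(
            pd.DataFrame(
                rng.lognormal(0, 0.5, size=(len(gt.net.tfs), len(gt.tfa.sample_ids))),
                index=gt.net.tfs,
                columns=gt.tfa.sample_ids,
            )
        )
        esub = T.ExpressionMatrix(small_noiseless.data.loc[gt.signs.signs.index])
        r2_rand = T.variance_explained(esub, random_cs, random_tfa)
        assert small_fit.r2_train[-1] > r2_rand
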