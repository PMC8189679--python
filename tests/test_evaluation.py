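"""Metric computations: standardization, direction, ranks, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tfactivity as T
from tfactivity.evaluation import StandardizedActivityMatrix


def _tfa(values, tfs, samples):
    return T.ActivityMatrix(pd.DataFrame(values, index=tfs, columns=samples))


class TestStandardize:
    def test_constant_row_all_zero(self):
        z = T.standardize_activities(_tfa([[2.0, 2.0, 2.0]], ["A"], list("abc")))
        assert (z.z.loc["A"] == 0).all()

    def test_hand_zscore_of_powers_of_two(self):
        # log2 of (1,2,4) is (0,1,2); z-scores are -sqrt(3/2)-style symmetric
        z = T.standardize_activities(_tfa([[1.0, 2.0, 4.0]], ["A"], list("abc")))
        expected = stats.zscore([0.0, 1.0, 2.0])
        np.testing.assert_allclose(z.z.loc["A"].to_numpy(), expected, atol=1e-12)

    def test_rows_have_zero_mean_unit_sd(self, rng):
        vals = rng.lognormal(0, 1, size=(5, 30))
        z = T.standardize_activities(_tfa(vals, [f"T{i}" for i in range(5)], [f"s{i}" for i in range(30)]))
        assert np.abs(z.z.mean(axis=1).to_numpy()).max() < 1e-9
        assert np.abs(z.z.std(axis=1, ddof=0).to_numpy() - 1).max() < 1e-9

    def test_deletion_zero_handled_by_floor(self):
        z = T.standardize_activities(_tfa([[0.0, 1.0, 2.0]], ["A"], list("abc")))
        assert np.isfinite(z.z.to_numpy()).all()


class TestDirectionMetric:
    def test_all_deletions_at_zero_correct(self):
        key = T.PerturbationKey(
            {"k1": ("A", "deletion"), "k2": ("B", "deletion")}, ("wt",)
        )
        tfa = _tfa([[1.0, 0.0, 1.0], [1.0, 1.0, 0.0]], ["A", "B"], ["wt", "k1", "k2"])
        frac, p, _ = T.direction_metric(tfa, key)
        assert frac == 1.0

    def test_equal_activity_counts_incorrect(self):
        key = T.PerturbationKey({"k1": ("A", "deletion")}, ("wt",))
        tfa = _tfa([[1.0, 1.0]], ["A"], ["wt", "k1"])
        frac, _, _ = T.direction_metric(tfa, key)
        assert frac == 0.0

    def test_chance_fraction_gives_p_near_one(self):
        n = 40
        samples = ["wt"] + [f"k{i}" for i in range(n)]
        tfs = [f"T{i}" for i in range(n)]
        records = {f"k{i}": (tfs[i], "deletion") for i in range(n)}
        key = T.PerturbationKey(records, ("wt",))
        vals = np.ones((n, n + 1))
        for i in range(n):  # exactly half correct
            vals[i, i + 1] = 0.5 if i % 2 == 0 else 2.0
        frac, p, _ = T.direction_metric(_tfa(vals, tfs, samples), key)
        assert frac == 0.5
        assert p > 0.8


class TestRankPercentile:
    def _z(self, values, tfs, samples):
        return StandardizedActivityMatrix(
            pd.DataFrame(values, index=tfs, columns=samples)
        )

    def test_top_rank_scores_100(self):
        tfs = [f"T{i}" for i in range(10)]
        z = np.tile(np.linspace(-1, 1, 10)[:, None], (1, 1))
        key = T.PerturbationKey({"s": ("T0", "deletion")}, ())
        med, _, detail = T.rank_percentile_metric(self._z(z, tfs, ["s"]), key)
        assert med == 100.0

    def test_rank_26_of_50_is_50(self):
        tfs = [f"T{i}" for i in range(50)]
        col = np.arange(50, dtype=float)  # T0 lowest ... T49 highest
        key = T.PerturbationKey({"s": ("T25", "deletion")}, ())
        # T25 is the 26th lowest value
        med, _, _ = T.rank_percentile_metric(self._z(col[:, None], tfs, ["s"]), key)
        assert med == pytest.approx(50.0)

    def test_overexpression_ranks_descending(self):
        tfs = ["A", "B", "C"]
        key = T.PerturbationKey({"s": ("A", "overexpression")}, ())
        med, _, _ = T.rank_percentile_metric(
            self._z(np.array([[2.0], [0.0], [-2.0]]), tfs, ["s"]), key
        )
        assert med == 100.0

    def test_random_scores_center_on_50(self, rng):
        n_tfs, n_samp = 30, 200
        tfs = [f"T{i}" for i in range(n_tfs)]
        samples = [f"s{i}" for i in range(n_samp)]
        z = rng.standard_normal((n_tfs, n_samp))
        records = {
            samples[i]: (tfs[i % n_tfs], "deletion") for i in range(n_samp)
        }
        key = T.PerturbationKey(records, ())
        med, _, _ = T.rank_percentile_metric(self._z(z, tfs, samples), key)
        assert 40 < med < 60


class TestPositiveCorrelation:
    def test_identical_matrices_fraction_one(self, rng):
        vals = rng.lognormal(0, 0.5, size=(6, 20))
        tfs = [f"T{i}" for i in range(6)]
        samples = [f"s{i}" for i in range(20)]
        tfa = _tfa(vals, tfs, samples)
        mrna = T.ExpressionMatrix(pd.DataFrame(vals, index=tfs, columns=samples))
        med, p, _ = T.positive_correlation_metric(tfa, mrna, n_boot=100, seed=1)
        assert med == 1.0
        assert p < 0.05

    def test_independent_noise_near_half(self, rng):
        n_tf = 40
        tfs = [f"T{i}" for i in range(n_tf)]
        samples = [f"s{i}" for i in range(50)]
        tfa = _tfa(rng.lognormal(0, 0.5, size=(n_tf, 50)), tfs, samples)
        mrna = T.ExpressionMatrix(
            pd.DataFrame(rng.normal(7, 1, size=(n_tf, 50)), index=tfs, columns=samples)
        )
        med, _, _ = T.positive_correlation_metric(tfa, mrna, n_boot=200, seed=2)
        assert 0.3 < med < 0.7

    def test_fixed_seed_bitwise_reproducible(self, rng):
        vals = rng.lognormal(0, 0.5, size=(6, 20))
        tfs = [f"T{i}" for i in range(6)]
        samples = [f"s{i}" for i in range(20)]
        tfa = _tfa(vals, tfs, samples)
        mrna = T.ExpressionMatrix(
            pd.DataFrame(rng.normal(7, 1, size=(6, 20)), index=tfs, columns=samples)
        )
        a = T.positive_correlation_metric(tfa, mrna, n_boot=100, seed=7)
        b = T.positive_correlation_metric(tfa, mrna, n_boot=100, seed=7)
        assert a[0] == b[0] and a[1] == b[1]


class TestFisherCombine:
    def test_ones_give_one(self):
        assert T.fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_two_005_matches_closed_form(self):
        # chi2 = -2 ln(0.0025) = 11.9829; survival at df=4 is (1+x/2)e^{-x/2}
        assert T.fisher_combine([0.05, 0.05]) == pytest.approx(0.01746, abs=1e-4)

    def test_single_p_identity(self):
        assert T.fisher_combine([0.2]) == pytest.approx(0.2, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(T.ValidationError):
            T.fisher_combine([0.0, 0.5])


class TestAveraging:
    def _z_of(self, vals, tfs, samples):
        return T.standardize_activities(_tfa(vals, tfs, samples))

    def test_identical_inputs_unchanged(self, rng):
        z = self._z_of(rng.lognormal(0, 1, (4, 12)), list("ABCD"), [f"s{i}" for i in range(12)])
        out = T.average_standardized_tfas([z, z])
        pd.testing.assert_frame_equal(out.z, z.z, atol=1e-9, rtol=0)

    def test_unshared_tf_passes_through(self, rng):
        samples = [f"s{i}" for i in range(12)]
        z1 = self._z_of(rng.lognormal(0, 1, (2, 12)), ["A", "B"], samples)
        z2 = self._z_of(rng.lognormal(0, 1, (2, 12)), ["A", "C"], samples)
        out = T.average_standardized_tfas([z1, z2])
        np.testing.assert_allclose(out.z.loc["B"], z1.z.loc["B"], atol=1e-9)
        np.testing.assert_allclose(out.z.loc["C"], z2.z.loc["C"], atol=1e-9)

    def test_averaging_reduces_noise(self, rng):
        samples = [f"s{i}" for i in range(60)]
        truth = rng.standard_normal(60)
        def noisy():
            v = truth + rng.standard_normal(60) * 0.8
            return StandardizedActivityMatrix(
                pd.DataFrame(stats.zscore(v)[None, :], index=["A"], columns=samples)
            )
        z1, z2 = noisy(), noisy()
        out = T.average_standardized_tfas([z1, z2])
        c_avg = np.corrcoef(out.z.loc["A"], truth)[0, 1]
        c1 = np.corrcoef(z1.z.loc["A"], truth)[0, 1]
        c2 = np.corrcoef(z2.z.loc["A"], truth)[0, 1]
        assert c_avg > min(c1, c2)

    def test_disjoint_samples_error(self, rng):
        z1 = self._z_of(rng.lognormal(0, 1, (2, 5)), ["A", "B"], [f"a{i}" for i in range(5)])
        z2 = self._z_of(rng.lognormal(0, 1, (2, 5)), ["A", "B"], [f"b{i}" for i in range(5)])
        with pytest.raises(T.ValidationError):
            T.average_standardized_tfas([z1, z2])


class TestBootstrapCSCorrelation:
    def _setup(self, rng, n_targets=8):
        genes = [f"g{i}" for i in range(n_targets)]
        net = T.NetworkMap.from_edges([("F", g) for g in genes])
        cs = T.ControlStrengthMatrix(
            pd.DataFrame(rng.normal(size=(n_targets, 1)), index=genes, columns=["F"]),
            pd.Series(0.0, index=genes),
        )
        return net, cs, genes

    def test_self_covariate_scores_one(self, rng):
        net, cs, genes = self._setup(rng)
        per_tf, summary = T.bootstrap_cs_correlation(cs, cs, net, n_boot=50, seed=0)
        assert per_tf.loc["F"] == pytest.approx(1.0)
        assert summary["fraction_positive"] == 1.0

    def test_permuted_covariate_centers_on_zero(self, rng):
        genes = [f"g{i}" for i in range(30)]
        net = T.NetworkMap.from_edges([("F", g) for g in genes])
        vals = rng.normal(size=30)
        cs = T.ControlStrengthMatrix(
            pd.DataFrame(vals[:, None], index=genes, columns=["F"]),
            pd.Series(0.0, index=genes),
        )
        cov = pd.Series(rng.permutation(vals), index=genes)
        per_tf, _ = T.bootstrap_cs_correlation(cs, cov, net, n_boot=200, seed=1)
        assert abs(per_tf.loc["F"]) < 0.5

    def test_min_targets_excludes_small_tfs(self, rng):
        net, cs, genes = self._setup(rng, n_targets=3)
        per_tf, summary = T.bootstrap_cs_correlation(cs, cs, net, min_targets=5, n_boot=10, seed=0)
        assert summary["n_tfs"] == 0


class TestRegulatorRecovery:
    def test_top_target_recovered_everywhere(self):
        tfs = ["A", "B", "C", "D"]
        z = StandardizedActivityMatrix(
            pd.DataFrame(
                {"wt": [0.0, 0.0, 0.0, 0.0], "p1": [3.0, 0.1, 0.2, -0.1]},
                index=tfs,
            )
        )
        curve, cov = T.regulator_recovery_curve(
            z, "wt", {"REG": {"A"}}, {"p1": "REG"}
        )
        assert (curve["fraction_recovered"] == 1.0).all()
        assert cov["n_edges_missing"] == 0

    def test_threshold_zero_recovers_all_present(self):
        tfs = ["A", "B", "C"]
        z = StandardizedActivityMatrix(
            pd.DataFrame({"wt": [0.0] * 3, "p1": [0.1, 2.0, -1.0]}, index=tfs)
        )
        curve, cov = T.regulator_recovery_curve(
            z, "wt", {"REG": {"A", "ZZZ"}}, {"p1": "REG"}
        )
        assert curve.loc[curve["percentile_threshold"] == 0.0, "fraction_recovered"].iloc[0] == 1.0
        assert cov["n_edges_missing"] == 1
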