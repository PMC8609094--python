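import numpy as np
import pytest

from rishharm.stats import (
    adjusted_cohens_d,
    boxcox_transform,
    relative_effect_change,
    site_anova,
    voxelwise_group_test,
    wmh_metric_regression,
)


class TestAdjustedCohensD:
    def test_reduces_to_classical_pooled_d_without_covariates(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(0.0, 1.0, 30)
        x2 = rng.normal(0.7, 1.2, 40)
        values = np.concatenate([x1, x2])
        group = ["a"] * 30 + ["b"] * 40
        res = adjusted_cohens_d(values, group)
        sp = np.sqrt(((len(x1) - 1) * x1.var(ddof=1) + (len(x2) - 1) * x2.var(ddof=1))
                     / (len(x1) + len(x2) - 2))
        d_classical = (x2.mean() - x1.mean()) / sp
        assert res.d == pytest.approx(d_classical, abs=1e-10)
        assert res.ci_low < res.d < res.ci_high

    def test_recovers_one_sd_shift_at_n100(self):
        # averaged over replicates so the check probes estimator bias, not a
        # single draw (the single-draw SE at n=100/group is ~0.15 itself)
        rng = np.random.default_rng(1)
        n = 100
        estimates = []
        for _ in range(15):
            age = rng.uniform(60, 80, 2 * n)
            sex = rng.choice(["M", "F"], 2 * n)
            group = np.array(["control"] * n + ["patient"] * n)
            y = rng.normal(0, 1, 2 * n) + (group == "patient") * 1.0
            res = adjusted_cohens_d(y, group, age, sex, positive_label="patient")
            assert res.p_value < 1e-3
            estimates.append(res.d)
        assert np.mean(estimates) == pytest.approx(1.0, abs=0.15)

    def test_age_mediated_difference_is_adjusted_away(self):
        rng = np.random.default_rng(2)
        n = 300
        group = np.array(["control"] * n + ["patient"] * n)
        age = np.where(group == "patient", rng.normal(75, 5, 2 * n), rng.normal(65, 5, 2 * n))
        y = 0.01 * age + rng.normal(0, 0.005, 2 * n)  # depends only on age
        unadjusted = adjusted_cohens_d(y, group, positive_label="patient")
        adjusted = adjusted_cohens_d(y, group, age=age, positive_label="patient")
        assert abs(unadjusted.d) > 1.5
        assert abs(adjusted.d) < 0.25

    def test_null_effect_near_zero(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=120)
        group = ["a"] * 60 + ["b"] * 60
        res = adjusted_cohens_d(y, group, age=rng.uniform(60, 80, 120),
                                sex=rng.choice(["M", "F"], 120))
        assert abs(res.d) < 0.4

    def test_collinear_design_raises_with_column_name(self):
        y = np.arange(10.0)
        group = ["a"] * 5 + ["b"] * 5
        sex = ["M"] * 5 + ["F"] * 5  # identical to group indicator
        with pytest.raises(ValueError, match="sex|group"):
            adjusted_cohens_d(y, group, sex=sex)

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError, match="2 subjects"):
            adjusted_cohens_d([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestRelativeEffectChange:
    @pytest.mark.parametrize("before,after,expected", [
        (-1.0, -1.0, 0.0),
        (-2.0, -2.1, 5.0),
        (0.5, 0.4, 20.0),
        (-0.96, -1.0, 100 * 0.04 / 0.96),
    ])
    def test_arithmetic(self, before, after, expected):
        assert relative_effect_change(before, after) == pytest.approx(expected)

    def test_zero_baseline_is_missing(self):
        assert np.isnan(relative_effect_change(0.0, 0.3))


class TestBoxCox:
    def test_forced_lambda_one_is_shifted_identity(self):
        x = np.array([1.0, 2.0, 5.0])
        t, lam = boxcox_transform(x, lmbda=1.0)
        assert lam == 1.0
        np.testing.assert_allclose(t, x - 1.0)

    def test_lognormal_sample_gives_lambda_near_zero(self):
        rng = np.random.default_rng(4)
        x = np.exp(rng.normal(0.0, 1.0, 500))
        _, lam = boxcox_transform(x)
        assert abs(lam) <= 0.15

    def test_positive_normal_sample_gives_lambda_near_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10.0, 1.0, 500)
        assert (x > 0).all()
        _, lam = boxcox_transform(x)
        assert lam == pytest.approx(1.0, abs=0.45)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError, match="positive"):
            boxcox_transform(np.array([0.0, 1.0]))


class TestWMHRegression:
    def _covars(self, rng, n):
        return rng.uniform(60, 80, n), rng.choice(["M", "F"], n)

    def test_independent_metric_gives_near_zero_r2(self):
        rng = np.random.default_rng(6)
        n = 200
        age, sex = self._covars(rng, n)
        res = wmh_metric_regression(rng.normal(size=n), np.exp(rng.normal(size=n)), age, sex)
        assert res.r_squared < 0.08

    def test_exact_linear_relation_gives_r2_one(self):
        rng = np.random.default_rng(7)
        n = 100
        wmh = np.exp(rng.normal(size=n))
        t, _ = boxcox_transform(wmh, offset=1e-3)
        age, sex = self._covars(rng, n)
        res = wmh_metric_regression(2.0 * t + 1.0, wmh, age, sex)
        assert res.r_squared == pytest.approx(1.0, abs=1e-8)
        assert abs(res.beta["wmh"]) == pytest.approx(1.0, abs=1e-6)

    def test_simulated_population_r2_recovered(self):
        # design with analytic population R^2 = 0.6
        rng = np.random.default_rng(8)
        n = 300
        z = rng.normal(size=n)
        wmh = np.exp(z)
        noise_sd = np.sqrt(1.0 / 0.6 - 1.0)
        y = z + rng.normal(0, noise_sd, n)
        age, sex = self._covars(rng, n)
        res = wmh_metric_regression(y, wmh, age, sex)
        assert res.r_squared == pytest.approx(0.6, abs=0.05)

    def test_too_few_subjects_raises(self):
        with pytest.raises(ValueError, match="subjects"):
            wmh_metric_regression([1, 2, 3], [1, 1, 2], [60, 61, 62], ["M", "F", "M"])


class TestSiteAnova:
    def test_matches_hand_computed_table(self):
        # 3 sites x 3 subjects, classic textbook layout
        y = [1.0, 2.0, 3.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0]
        site = ["s1"] * 3 + ["s2"] * 3 + ["s3"] * 3
        # grand mean 30/9; SSB = 3*((2-10/3)^2+(3-10/3)^2+(5-10/3)^2) = 14
        # SSW = 2+2+2 = 6; F = (14/2)/(6/6) = 7
        F, dof, p = site_anova(y, site)
        assert F == pytest.approx(7.0, rel=1e-12)
        assert dof == (2, 6)
        assert 0 < p < 0.05

    def test_large_shift_is_detected(self):
        rng = np.random.default_rng(9)
        y = np.concatenate([rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(5, 1, 15)])
        site = ["a"] * 15 + ["b"] * 15 + ["c"] * 15
        F, _, p = site_anova(y, site)
        assert p < 1e-6

    def test_single_subject_site_raises(self):
        with pytest.raises(ValueError, match="2 subjects"):
            site_anova([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestVoxelwiseGroupTest:
    def _maps(self, rng, n_subj, shape=(6, 5, 2), effect=0.0, region=None):
        maps = rng.normal(size=(n_subj,) + shape)
        if region is not None:
            maps[n_subj // 2:, region] += effect
        return maps

    def test_identical_maps_give_zero_significant(self):
        rng = np.random.default_rng(10)
        one = rng.normal(size=(6, 5, 2))
        maps = np.stack([one] * 12)
        res = voxelwise_group_test(maps, ["a"] * 6 + ["b"] * 6,
                                   np.ones((6, 5, 2), bool), n_permutations=200, seed=1)
        assert res.n_significant == 0

    def test_injected_effect_is_localized(self):
        rng = np.random.default_rng(11)
        shape = (6, 5, 2)
        maps = rng.normal(size=(24,) + shape)
        maps[12:, :2, :2, :] += 3.0
        labels = ["a"] * 12 + ["b"] * 12
        res = voxelwise_group_test(maps, labels, np.ones(shape, bool),
                                   n_permutations=500, seed=2)
        sig = res.p_corrected < 0.05
        assert sig[:2, :2, :].sum() >= 6          # most affected voxels found
        assert sig[2:, :, :].sum() == 0           # nothing outside the region

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(12)
        maps = rng.normal(size=(12, 4, 4, 2))
        labels = ["a"] * 6 + ["b"] * 6
        r1 = voxelwise_group_test(maps, labels, np.ones((4, 4, 2), bool),
                                  n_permutations=200, seed=7)
        r2 = voxelwise_group_test(maps, labels, np.ones((4, 4, 2), bool),
                                  n_permutations=200, seed=7)
        np.testing.assert_array_equal(r1.p_corrected, r2.p_corrected)

    def test_fwer_calibrated_under_null(self):
        # repeated null simulations: familywise error within binomial bounds
        rng = np.random.default_rng(13)
        n_reps, alpha = 120, 0.05
        false_positives = 0
        for _ in range(n_reps):
            maps = rng.normal(size=(12, 50))
            res = voxelwise_group_test(maps, ["a"] * 6 + ["b"] * 6,
                                       np.ones(50, bool), n_permutations=199,
                                       alpha=alpha, seed=rng.integers(2 ** 31))
            false_positives += res.n_significant > 0
        fwer = false_positives / n_reps
        # binomial 2-sigma tolerance around alpha
        assert fwer <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / n_reps)

    def test_few_permutations_warn(self):
        rng = np.random.default_rng(14)
        maps = rng.normal(size=(12, 4, 4, 2))
        with pytest.warns(UserWarning, match="permutations"):
            voxelwise_group_test(maps, ["a"] * 6 + ["b"] * 6,
                                 np.ones((4, 4, 2), bool), n_permutations=50, seed=0)
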