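import numpy as np
import pandas as pd
import pytest
from scipy import linalg as sla
from scipy import stats as spstats

import betakin as bk


def brute_force_h2(y, sizes, n_zoom=3, n_grid=41):
    """Independent oracle: 2-D grid search of the exact Gaussian likelihood
    over (sigma2_g, sigma2_e), with the intercept profiled by GLS and the
    likelihood evaluated through scipy's multivariate normal on the full
    block-diagonal covariance. Zooms the grid to ~1e-3 resolution in h2.
    """
    y = np.asarray(y, dtype=float)
    v = y.var()
    blocks = []
    pos = 0
    for m in sizes:
        R = np.full((m, m), 0.5)
        np.fill_diagonal(R, 1.0)
        blocks.append((R, np.eye(m), y[pos:pos + m]))
        pos += m

    def loglik(sg, se):
        if sg + se <= 0:
            return -np.inf
        Sigma = sla.block_diag(*[sg * R + se * I for R, I, _ in blocks])
        Si = np.linalg.inv(Sigma)
        ones = np.ones(y.size)
        mu = (ones @ Si @ y) / (ones @ Si @ ones)
        return spstats.multivariate_normal.logpdf(y, mean=mu * ones, cov=Sigma,
                                                  allow_singular=True)

    lo_g, hi_g, lo_e, hi_e = 0.0, 2.5 * v, 0.0, 2.5 * v
    best = (-np.inf, 0.0, v)
    for _ in range(n_zoom):
        gs = np.linspace(lo_g, hi_g, n_grid)
        es = np.linspace(lo_e, hi_e, n_grid)
        for sg in gs:
            for se in es:
                ll = loglik(sg, se)
                if ll > best[0]:
                    best = (ll, sg, se)
        _, sg0, se0 = best
        dg, de = (hi_g - lo_g) / (n_grid - 1), (hi_e - lo_e) / (n_grid - 1)
        lo_g, hi_g = max(0.0, sg0 - 2 * dg), sg0 + 2 * dg
        lo_e, hi_e = max(0.0, se0 - 2 * de), se0 + 2 * de
    _, sg, se = best
    return sg / (sg + se) if sg + se > 0 else 0.0


class TestPreparePhenotype:
    def test_negative_offsets_are_flipped(self):
        vals = pd.Series([-22.9, -23.1, -23.0, -22.8, -23.3])
        out, record = bk.prepare_phenotype(vals, transform="flip")
        assert record.applied == "sign_flip"
        assert (out > 0).all()
        assert out.iloc[0] == pytest.approx(22.9)

    def test_all_positive_unchanged(self):
        vals = pd.Series([1.0, 2.0, 3.0, 4.0])
        out, record = bk.prepare_phenotype(vals, transform="flip")
        assert record.applied == "none"
        assert (out == vals).all()

    def test_inverse_normal_blom_scores(self):
        # closed form for n=5 distinct values: Phi^-1((i - 3/8) / 5.25)
        vals = pd.Series([10.0, 30.0, 20.0, 50.0, 40.0])
        out, record = bk.prepare_phenotype(vals, transform="invnorm")
        assert record.applied == "inverse_normal"
        expected = spstats.norm.ppf((np.array([1, 3, 2, 5, 4]) - 0.375) / 5.25)
        assert np.allclose(out.to_numpy(), expected)

    def test_mixed_sign_zero_median_min_shifted(self):
        vals = pd.Series([-2.0, -1.0, 0.0, 1.0, 2.0])
        with pytest.warns(UserWarning, match="min-shift"):
            out, record = bk.prepare_phenotype(vals, transform="flip")
        assert record.applied == "min_shift"
        assert out.min() == 0.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="non-missing"):
            bk.prepare_phenotype(pd.Series([1.0, 2.0, np.nan]), transform="flip")


class TestFitVarianceComponents:
    def test_null_phenotype_estimates_near_zero(self, study_pedigree):
        # boundary estimator is upward biased in the mean; check the median
        estimates = [
            bk.fit_variance_components(
                bk.simulate_phenotype(study_pedigree,
                                      bk.PhenoGenConfig(h2_true=0.0, seed=s)),
                study_pedigree).h2
            for s in range(100)
        ]
        assert np.median(estimates) < 0.1

    @pytest.mark.parametrize("sizes,values", [
        ([2, 2, 2], [1.21, 0.83, -0.45, -0.91, 0.12, 0.48]),
        ([3, 3, 2], [0.5, 0.9, 0.7, -1.2, -0.8, -1.0, 0.1, 1.4]),
        ([2] * 6, [0.3, 0.5, -1.1, -0.7, 2.0, 1.6, -0.2, 0.1, 0.9, 1.2, -1.5, -1.3]),
        ([4, 3, 2, 1], [0.4, 0.6, 0.2, 0.5, -1.0, -1.3, -0.6, 1.8, 2.1, -0.3]),
    ])
    def test_matches_brute_force_likelihood_grid(self, sizes, values):
        ped = bk.pedigree_from_sizes(sizes)
        fit = bk.fit_variance_components(np.array(values), ped)
        oracle = brute_force_h2(values, sizes)
        assert fit.h2 == pytest.approx(oracle, abs=1e-3)
        assert 0.0 <= fit.h2 <= 1.0
        assert fit.sigma2_g >= 0 and fit.sigma2_e >= 0
        assert fit.h2 * fit.total_variance == pytest.approx(fit.sigma2_g)

    def test_affine_and_sign_invariance(self, study_pedigree):
        y = bk.simulate_phenotype(study_pedigree,
                                  bk.PhenoGenConfig(h2_true=0.6, seed=9))
        h2 = bk.fit_variance_components(y, study_pedigree).h2
        assert bk.fit_variance_components(3.5 * y + 100.0, study_pedigree).h2 == \
            pytest.approx(h2, abs=1e-8)
        assert bk.fit_variance_components(-y, study_pedigree).h2 == \
            pytest.approx(h2, abs=1e-8)

    def test_matches_sib_icc_moment_estimator_in_expectation(self):
        # on balanced 2-sib designs h2_hat ~ 2 * ANOVA ICC
        ped = bk.pedigree_from_sizes([2] * 300)
        ml, icc2 = [], []
        for s in range(30):
            y = bk.simulate_phenotype(ped, bk.PhenoGenConfig(h2_true=0.5, seed=s))
            ml.append(bk.fit_variance_components(y, ped).h2)
            v = y.to_numpy().reshape(-1, 2)
            msb = 2 * v.mean(axis=1).var(ddof=1)
            msw = np.mean((v[:, 0] - v[:, 1]) ** 2) / 2
            icc2.append(np.clip(2 * (msb - msw) / (msb + msw), 0, 1))
        assert np.mean(ml) == pytest.approx(np.mean(icc2), abs=0.05)

    def test_missing_values_drop_subjects(self, study_pedigree):
        y = bk.simulate_phenotype(study_pedigree, bk.PhenoGenConfig(h2_true=0.5, seed=3))
        y.iloc[:10] = np.nan
        fit = bk.fit_variance_components(y, study_pedigree)
        assert fit.n_subjects == 200

    def test_constant_phenotype_flagged_degenerate(self, study_pedigree):
        fit = bk.fit_variance_components(
            np.full(study_pedigree.n_subjects, 3.0), study_pedigree)
        assert fit.degenerate
        assert np.isnan(fit.h2)

    def test_reml_close_to_ml_at_study_size(self, study_pedigree):
        y = bk.simulate_phenotype(study_pedigree, bk.PhenoGenConfig(h2_true=0.7, seed=4))
        ml = bk.fit_variance_components(y, study_pedigree).h2
        reml = bk.fit_variance_components(y, study_pedigree, reml=True).h2
        assert reml == pytest.approx(ml, abs=0.05)


class TestPermutationTest:
    def test_reproducible_and_in_range(self, study_pedigree):
        y = bk.simulate_phenotype(study_pedigree, bk.PhenoGenConfig(h2_true=0.8, seed=2))
        r1 = bk.permutation_test(y, study_pedigree, n_perm=300, seed=7)
        r2 = bk.permutation_test(y, study_pedigree, n_perm=300, seed=7)
        assert (r1.k, r1.p) == (r2.k, r2.p)
        assert 0 <= r1.p <= 1

    def test_zero_observed_heritability_gives_p_one(self, study_pedigree):
        # find a null cohort whose fitted h2 lands exactly on the boundary
        for s in range(30):
            y = bk.simulate_phenotype(study_pedigree,
                                      bk.PhenoGenConfig(h2_true=0.0, seed=s))
            if bk.fit_variance_components(y, study_pedigree).h2 == 0.0:
                res = bk.permutation_test(y, study_pedigree, n_perm=200, seed=1)
                assert res.observed_h2 == 0.0
                assert res.k == res.n_perm
                assert res.p == 1.0
                return
        pytest.fail("no boundary-null cohort found in 30 seeds")

    def test_high_heritability_gives_small_p(self, study_pedigree):
        y = bk.simulate_phenotype(study_pedigree, bk.PhenoGenConfig(h2_true=0.9, seed=1))
        res = bk.permutation_test(y, study_pedigree, n_perm=500, seed=3)
        assert res.p < 0.02

    def test_invalid_n_perm_rejected(self, study_pedigree):
        y = bk.simulate_phenotype(study_pedigree, bk.PhenoGenConfig(seed=0))
        with pytest.raises(ValueError, match="n_perm"):
            bk.permutation_test(y, study_pedigree, n_perm=0)

    def test_null_p_values_are_valid_and_conditionally_uniform(self, study_pedigree):
        """Calibration under h2_true = 0.

        The one-tailed p cannot be exactly uniform: the estimator sits on
        the h2 = 0 boundary for about half of null cohorts, and with ties
        counted as exceedances those cohorts get p = 1 exactly. The correct
        calibration facts are (a) validity — P(p <= x) <= x up to sampling
        noise (superuniformity), and (b) uniformity of p/(1 - q) given a
        nonzero estimate, q being the boundary mass of the permutation null.
        """
        ps, cond = [], []
        for s in range(100):
            y = bk.simulate_phenotype(study_pedigree,
                                      bk.PhenoGenConfig(h2_true=0.0, seed=500 + s))
            res = bk.permutation_test(y, study_pedigree, n_perm=200, seed=s)
            ps.append(res.p)
            if res.observed_h2 > 0:
                cond.append(res.p)
        ps = np.array(ps)
        # (a) not anticonservative: one-sided KS in the liberal direction
        ks_valid = spstats.ks_1samp(ps, spstats.uniform.cdf, alternative="greater")
        assert ks_valid.pvalue > 0.01
        # (b) continuous part is uniform on (0, 1-q)
        cond = np.array(cond)
        scaled = cond / cond.max()
        ks_cond = spstats.ks_1samp(scaled, spstats.uniform.cdf)
        assert ks_cond.pvalue > 0.01


class TestBonferroni:
    def test_threshold_at_thirty_tests(self):
        sig, adj = bk.bonferroni([0.0005, 0.0035, 0.0], n_tests=30)
        assert sig.tolist() == [True, False, True]
        assert adj[0] == pytest.approx(0.015)
        assert adj[2] == 0.0

    def test_adjusted_p_capped_at_one(self):
        _, adj = bk.bonferroni([0.5], n_tests=30)
        assert adj[0] == 1.0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bk.bonferroni([1.5])


class TestCohensD:
    @pytest.mark.parametrize("mean,sd,expected", [(276.0, 374.0, 0.74),
                                                  (133.0, 173.0, 0.77)])
    def test_single_group_effect_size(self, mean, sd, expected):
        # three points with exact sample mean and SD: (m - s, m, m + s)
        vals = [mean - sd, mean, mean + sd]
        assert round(bk.cohens_d(vals), 2) == expected

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            bk.cohens_d([5.0, 5.0, 5.0])


class TestBattery:
    def test_toy_phenotypes_produce_valid_rows(self, toy_bundle):
        table = toy_bundle["phenotypes"]
        res = bk.run_heritability_battery(table, toy_bundle["pedigree"],
                                          n_perm=100, seed=0)
        assert len(res) == len(table.columns)
        assert res["h2"].between(0, 1).all()
        assert res["p"].between(0, 1).all()
        # toy_b is centred at -5, so the sign-flip convention must fire
        assert res.set_index("phenotype").at["toy_b", "transform"] == "sign_flip"

    def test_missing_columns_reported_by_name(self, toy_bundle):
        with pytest.raises(ValueError, match="absent_pheno"):
            bk.run_heritability_battery(toy_bundle["phenotypes"],
                                        toy_bundle["pedigree"],
                                        phenotypes=["toy_a", "absent_pheno"])

    def test_degenerate_column_flagged_not_fatal(self, toy_bundle):
        table = toy_bundle["phenotypes"].copy()
        table["flat"] = 1.0
        res = bk.run_heritability_battery(table, toy_bundle["pedigree"],
                                          n_perm=50, seed=0)
        row = res.set_index("phenotype").loc["flat"]
        assert row["degenerate"]
        assert row["p"] == 1.0
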