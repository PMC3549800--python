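import numpy as np
import pandas as pd
import pytest

import tshrinkplus as tp
from tshrinkplus.datatypes import CommonVarianceModel, GeneMoments
from tshrinkplus.moderation import estimate_df, lambda_from_ratios, moderate_variances


def _moments_and_model(s2, common, mu=None, nu=4):
    idx = pd.Index([f"g{i}" for i in range(len(s2))], name="gene_id")
    mu = np.ones(len(s2)) if mu is None else np.asarray(mu, float)
    moments = GeneMoments(
        pd.DataFrame({"mu_hat": mu, "s2": np.asarray(s2, float)}, index=idx),
        nu_gene=nu,
        n1=nu // 2 + 1,
        n2=nu // 2 + 1,
    )
    model = CommonVarianceModel(
        sigma2_common=pd.Series(np.asarray(common, float), index=idx),
        smoother=None,
        span=0.5,
    )
    return moments, model


class TestLambda:
    def test_perfect_common_variance(self):
        assert lambda_from_ratios(np.ones(100), nu_gene=4) == 1.0

    def test_hand_evaluation(self):
        # K=2, nu=4, ratios (2, 0): sum (r-1)^2 = 2, numerator 2*2/4 = 1
        assert lambda_from_ratios([2.0, 0.0], nu_gene=4) == pytest.approx(0.5)

    def test_chi2_ratios_concentrate_at_one(self):
        # when the common variance is the truth, ratios are chi2_nu / nu and
        # the sum of squared deviations concentrates at 2K/nu
        rng = np.random.default_rng(47)
        r = rng.chisquare(6, 10_000) / 6
        assert 0.9 <= lambda_from_ratios(r, nu_gene=6) <= 1.0

    def test_duplication_invariance(self):
        rng = np.random.default_rng(48)
        r = rng.chisquare(6, 500) / 6
        lam = lambda_from_ratios(r, 6)
        assert lambda_from_ratios(np.concatenate([r, r]), 6) == pytest.approx(lam)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(49)
        s2 = np.exp(rng.normal(0, 1, 300))
        common = np.exp(rng.normal(0, 1, 300))
        m1, mod1 = _moments_and_model(s2, common)
        perm = rng.permutation(300)
        m2, mod2 = _moments_and_model(s2[perm], common[perm])
        assert tp.estimate_lambda(m1, mod1) == pytest.approx(
            tp.estimate_lambda(m2, mod2)
        )

    def test_degenerate_genes_excluded_but_moderated(self):
        moments, model = _moments_and_model(
            s2=[1.0, 0.0, 2.0], common=[1.0, 1.5, 2.0], mu=[5.0, 0.0, 5.0]
        )
        res = tp.moderate(moments, model)
        assert res.n_lambda_genes == 2  # zero-s2 and zero-mu genes dropped
        assert len(res.sigma2_shrink) == 3  # but every gene is moderated

    def test_no_participating_genes_rejected(self):
        moments, model = _moments_and_model(s2=[0.0], common=[1.0], mu=[0.0])
        with pytest.raises(ValueError, match="no genes"):
            tp.estimate_lambda(moments, model)


class TestModerateVariances:
    @pytest.mark.parametrize(
        "lam,expected", [(1.0, 4.0), (0.0, 2.0), (0.5, 3.0)]
    )
    def test_convex_combination(self, lam, expected):
        moments, model = _moments_and_model(s2=[2.0], common=[4.0])
        assert moderate_variances(lam, moments, model).iloc[0] == pytest.approx(
            expected
        )

    def test_result_between_endpoints(self):
        rng = np.random.default_rng(50)
        s2 = np.exp(rng.normal(0, 1, 200))
        common = np.exp(rng.normal(0, 1, 200))
        moments, model = _moments_and_model(s2, common)
        shrunk = moderate_variances(0.3, moments, model).to_numpy()
        lo = np.minimum(s2, common)
        hi = np.maximum(s2, common)
        assert ((shrunk >= lo - 1e-12) & (shrunk <= hi + 1e-12)).all()

    def test_lambda_out_of_range_rejected(self):
        moments, model = _moments_and_model(s2=[1.0], common=[1.0])
        with pytest.raises(ValueError, match="lambda"):
            moderate_variances(1.2, moments, model)


class TestDegreesOfFreedom:
    def test_lambda_zero_collapses_to_nu_gene(self):
        moments, model = _moments_and_model(s2=[1.0, 3.0], common=[2.0, 2.0], nu=4)
        nu_k, nu_shrink = estimate_df(0.0, moments, model)
        assert np.allclose(nu_k.to_numpy(), 4.0)
        assert nu_shrink == pytest.approx(4.0)

    def test_equal_variances_quadruple_df_at_half(self):
        # symbolic: lambda = 1/2 and common = s2 makes nu_k = 4 nu_gene
        moments, model = _moments_and_model(s2=[2.0, 5.0], common=[2.0, 5.0], nu=4)
        nu_k, nu_shrink = estimate_df(0.5, moments, model)
        assert np.allclose(nu_k.to_numpy(), 16.0)
        assert nu_shrink == pytest.approx(16.0)

    def test_lambda_one_gives_infinite_df(self):
        moments, model = _moments_and_model(s2=[1.0, 2.0], common=[1.5, 1.5])
        nu_k, nu_shrink = estimate_df(1.0, moments, model)
        assert np.isinf(nu_k.to_numpy()).all()
        assert np.isinf(nu_shrink)

    def test_df_never_below_nu_gene(self):
        rng = np.random.default_rng(51)
        s2 = np.exp(rng.normal(0, 1, 500))
        common = np.exp(rng.normal(0, 1, 500))
        moments, model = _moments_and_model(s2, common, nu=6)
        for lam in (0.0, 0.3, 0.7, 0.95):
            nu_k, nu_shrink = estimate_df(lam, moments, model)
            assert (nu_k.to_numpy() >= 6.0 - 1e-9).all()
            assert nu_shrink >= 6.0 - 1e-9


class TestShrinkageQuality:
    def test_shrinkage_dominates_raw_variance(self):
        # when the surface family is the generative truth, moderated
        # variances must beat raw s2 in MSE against the true variances
        mse_shrink, mse_raw = [], []
        for seed in range(20):
            moments, sigma2 = tp.simulate_moments(2000, 6, seed=seed)
            model = tp.fit_common_variance(moments)
            res = tp.moderate(moments, model)
            rel_shrink = (res.sigma2_shrink / sigma2 - 1.0) ** 2
            rel_raw = (moments.s2 / sigma2 - 1.0) ** 2
            mse_shrink.append(rel_shrink.mean())
            mse_raw.append(rel_raw.mean())
        assert np.mean(mse_shrink) <= np.mean(mse_raw)

    def test_permuting_covariate_does_not_raise_lambda(self, de_dataset, de_covariate):
        # degrading the external information can only hurt the surface
        moments = tp.compute_moments(de_dataset.cm)
        lam_good = tp.estimate_lambda(
            moments, tp.fit_common_variance(moments, covariate=de_covariate)
        )
        rng = np.random.default_rng(52)
        lams_perm = []
        for _ in range(3):
            shuffled = pd.Series(
                rng.permutation(de_covariate.to_numpy()), index=de_covariate.index
            )
            lams_perm.append(
                tp.estimate_lambda(
                    moments, tp.fit_common_variance(moments, covariate=shuffled)
                )
            )
        assert np.mean(lams_perm) <= lam_good + 0.02
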