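import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tshrinkplus as tp
from tshrinkplus.datatypes import ModerationResult


def _identity_moderation(moments):
    """lambda = 0: the Wald test collapses to the pooled t-test."""
    return ModerationResult(
        lambda_=0.0,
        sigma2_shrink=moments.s2.rename("sigma2_shrink"),
        nu_k=pd.Series(float(moments.nu_gene), index=moments.table.index),
        nu_shrink=float(moments.nu_gene),
        nu_gene=moments.nu_gene,
    )


class TestWaldTest:
    def test_equal_means_give_null_result(self, small_cm):
        moments = tp.compute_moments(small_cm)
        res = tp.wald_test(small_cm, _identity_moderation(moments))
        assert res.table.loc["gC", "statistic"] == 0.0
        assert res.table.loc["gC", "p_value"] == 1.0

    def test_statistic_arithmetic(self):
        # diff 2, sigma2 4, n1 = n2 = 2 -> 2 / sqrt(4 * 1) = 1
        counts = pd.DataFrame(
            {"a1": [3.0], "a2": [3.0], "b1": [1.0], "b2": [1.0]},
            index=pd.Index(["g1"], name="gene_id"),
        )
        cm = tp.CountMatrix(counts, pd.Series({"a1": "1", "a2": "1", "b1": "2", "b2": "2"}))
        moments = tp.compute_moments(cm)
        mod = _identity_moderation(moments)
        mod.sigma2_shrink = pd.Series([4.0], index=cm.gene_ids)
        res = tp.wald_test(cm, mod)
        assert res.table.loc["g1", "statistic"] == pytest.approx(1.0)

    def test_lambda_zero_equals_pooled_t_test(self, null_dataset):
        # independent oracle: scipy's equal-variance two-sample t-test
        cm = null_dataset.cm
        moments = tp.compute_moments(cm)
        res = tp.wald_test(cm, _identity_moderation(moments))
        g1, g2 = cm.groups
        y1 = cm.counts[cm.group_samples(g1)].to_numpy()
        y2 = cm.counts[cm.group_samples(g2)].to_numpy()
        t_ref, p_ref = stats.ttest_ind(y1, y2, axis=1, equal_var=True)
        ok = np.isfinite(t_ref)
        assert np.allclose(res.table["statistic"].to_numpy()[ok], t_ref[ok], atol=1e-10)
        assert np.allclose(res.table["p_value"].to_numpy()[ok], p_ref[ok], atol=1e-10)

    def test_group_swap_negates_statistics(self, null_dataset):
        cm = null_dataset.cm
        res = tp.run_method(cm, "Tshrink")
        swapped = tp.CountMatrix(
            cm.counts, cm.conditions.map({"1": "2", "2": "1"})
        )
        res_sw = tp.run_method(swapped, "Tshrink")
        assert np.allclose(
            res.table["statistic"].to_numpy(),
            -res_sw.table["statistic"].to_numpy(),
            atol=1e-9,
        )
        assert np.allclose(
            res.table["p_value"].to_numpy(),
            res_sw.table["p_value"].to_numpy(),
            atol=1e-12,
        )

    def test_zero_variance_conflict_flagged(self):
        counts = pd.DataFrame(
            {"a1": [5.0], "a2": [5.0], "b1": [9.0], "b2": [9.0]},
            index=pd.Index(["g1"], name="gene_id"),
        )
        cm = tp.CountMatrix(counts, pd.Series({"a1": "1", "a2": "1", "b1": "2", "b2": "2"}))
        moments = tp.compute_moments(cm)
        res = tp.wald_test(cm, _identity_moderation(moments))
        assert res.table.loc["g1", "p_value"] == 0.0
        assert res.n_zero_variance_conflicts == 1

    def test_gene_set_mismatch_rejected(self, small_cm, null_dataset):
        moments = tp.compute_moments(null_dataset.cm)
        with pytest.raises(ValueError, match="gene set"):
            tp.wald_test(small_cm, _identity_moderation(moments))


class TestRunMethod:
    def test_t_equals_wald_with_lambda_zero(self, null_dataset):
        cm = null_dataset.cm
        res = tp.run_method(cm, "T")
        moments = tp.compute_moments(cm)
        direct = tp.wald_test(cm, _identity_moderation(moments))
        pd.testing.assert_frame_equal(res.table, direct.table)

    def test_constant_covariate_degenerates_to_mean_only(self, null_dataset):
        cm = null_dataset.cm
        flat = pd.Series(0.0, index=cm.gene_ids, name="flat")
        res_plus = tp.run_method(cm, "Tshrink+", covariate=flat)
        res_mean = tp.run_method(cm, "Tshrink")
        assert np.allclose(
            res_plus.table["p_value"].to_numpy(),
            res_mean.table["p_value"].to_numpy(),
            atol=1e-6,
        )

    def test_tshrink_plus_requires_covariate(self, null_dataset):
        with pytest.raises(ValueError, match="covariate"):
            tp.run_method(null_dataset.cm, "Tshrink+")

    def test_unknown_method_rejected(self, null_dataset):
        with pytest.raises(ValueError, match="unknown method"):
            tp.run_method(null_dataset.cm, "edgeR")

    def test_poisson_null_p_values_uniform(self):
        # with many replicates all three methods approach calibrated tests;
        # KS distance to uniform stays small
        cfg = tp.SimulationConfig(
            genes=2000, n1=20, n2=20, dispersion=0.0, de_fraction=0.0, seed=53
        )
        ds = tp.simulate_counts(cfg)
        track = tp.simulate_external_track(ds, rho=0.8, m_replicates=6, seed=54)
        cov = tp.standardize_external(track, ds.cm.gene_ids)
        for method, kwargs in (
            ("T", {}),
            ("Tshrink", {}),
            ("Tshrink+", {"covariate": cov}),
        ):
            res = tp.run_method(ds.cm, method, **kwargs)
            ks = stats.kstest(res.table["p_value"], "uniform").statistic
            assert ks < 0.05, f"{method} p-values deviate from uniform (KS={ks:.3f})"


class TestAdjustment:
    def test_bonferroni_examples(self):
        table = pd.DataFrame(
            {
                "statistic": [1.0] * 10,
                "p_value": [0.05 / 10] + [0.5] * 9,
            },
            index=pd.Index([f"g{i}" for i in range(10)], name="gene_id"),
        )
        out = tp.adjust_bonferroni(
            tp.de.DEOutcome(table=table, method="T", lambda_=0.0, nu_shrink=4.0)
        )
        assert out.table["p_adjusted"].iloc[0] == pytest.approx(0.05)
        assert (out.table["p_adjusted"].iloc[1:] == 1.0).all()

    def test_adjustment_is_monotone(self, null_dataset):
        res = tp.run_method(null_dataset.cm, "T")
        order_p = np.argsort(res.table["p_value"].to_numpy(), kind="stable")
        order_adj = np.argsort(res.table["p_adjusted"].to_numpy(), kind="stable")
        # equal ordering up to ties: adjusted values must be a monotone map
        p = res.table["p_value"].to_numpy()[order_p]
        adj = res.table["p_adjusted"].to_numpy()[order_p]
        assert (np.diff(adj) >= -1e-15).all()
        assert np.all(adj >= p - 1e-15)
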