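"""Variance stabilization, batch removal, moderated testing, score FDR."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest
import scipy.stats as st

from conftest import make_matrix, simple_channels
from thermoshift.io_filters import DesignError
from thermoshift.stats_norm import (
    DegenerateDistributionError,
    fit_variance_prior,
    glog2,
    glog2_inverse,
    mean_sd_spearman,
    moderated_one_sample,
    moderated_ttest,
    remove_batch_effects,
    score_fdr,
    variance_stabilize,
)


def two_component_data(rng, n=2000, scales=(1.0, 2.5, 0.7, 1.4), cv=0.2, background=1024.0):
    """Multiplicative log-normal noise on a log-normal proteome plus a noisy
    additive floor — the error model the glog transform is built for.  The
    abundance scale is chosen so a tangible fraction of proteins sits near
    the floor, where plain log2 stops stabilizing."""
    base = np.exp2(rng.normal(14, 2, size=(n, 1)))
    sigma = np.sqrt(np.log(1 + cv ** 2))
    mult = np.exp(rng.normal(0, sigma, size=(n, len(scales))))
    floor = np.clip(rng.normal(background, background / 2, size=(n, len(scales))), 0, None)
    return base * np.asarray(scales) * mult + floor


class TestVarianceStabilize:
    def test_identical_channels_transform_identically(self):
        channels = simple_channels(2)
        x = np.tile(np.exp2(np.linspace(10, 24, 50))[:, None], (1, 2))
        matrix = make_matrix(x, channels)
        transformed, _ = variance_stabilize(matrix)
        np.testing.assert_allclose(transformed.intensities[:, 0],
                                   transformed.intensities[:, 1], atol=1e-9)

    def test_pure_scale_factors_removed(self, rng):
        channels = simple_channels(4)
        base = np.exp2(rng.normal(18, 2, size=(1000, 1)))
        x = base * np.array([1.0, 2.5, 0.7, 1.4])
        transformed, params = variance_stabilize(make_matrix(x, channels))
        spread = transformed.intensities - transformed.intensities.mean(axis=1, keepdims=True)
        assert np.abs(spread).max() < 1e-6
        assert params.scales[1] / params.scales[0] == pytest.approx(2.5, rel=1e-3)

    def test_channel_medians_equalized(self, rng):
        channels = simple_channels(4)
        x = two_component_data(rng)
        transformed, _ = variance_stabilize(make_matrix(x, channels))
        med = np.median(transformed.intensities, axis=0)
        assert np.ptp(med) < 1e-6

    def test_stabilizes_where_raw_log_fails(self, rng):
        channels = simple_channels(4)
        x = two_component_data(rng)
        transformed, _ = variance_stabilize(make_matrix(x, channels))
        assert abs(mean_sd_spearman(transformed.intensities)) <= 0.1
        assert abs(mean_sd_spearman(np.log2(x))) > 0.1

    def test_invariant_to_channel_order(self, rng):
        channels = simple_channels(4)
        x = two_component_data(rng, n=400)
        t1, _ = variance_stabilize(make_matrix(x, channels))
        perm = [2, 0, 3, 1]
        mperm = make_matrix(x[:, perm], tuple(channels[j] for j in perm))
        t2, _ = variance_stabilize(mperm)
        np.testing.assert_allclose(t1.intensities[:, perm], t2.intensities, atol=1e-6)

    def test_groups_normalized_independently(self, rng):
        channels = simple_channels(4)
        x = two_component_data(rng, n=400)
        x[:, 2:] *= 50.0  # a dim/bright split the groups should absorb
        groups = {"lo": (0, 1), "hi": (2, 3)}
        transformed, params = variance_stabilize(make_matrix(x, channels), groups=groups)
        med = np.median(transformed.intensities, axis=0)
        assert abs(med[0] - med[1]) < 1e-6
        assert abs(med[2] - med[3]) < 1e-6

    def test_single_channel_group_rejected(self, rng):
        channels = simple_channels(3)
        matrix = make_matrix(two_component_data(rng, n=100, scales=(1, 1, 1)), channels)
        with pytest.raises(DesignError, match="solo"):
            variance_stabilize(matrix, groups={"solo": (0,), "pair": (1, 2)})

    def test_glog_inverse_round_trip(self, rng):
        y = rng.normal(0, 100, size=50)
        np.testing.assert_allclose(glog2_inverse(glog2(y)), y, rtol=1e-12, atol=1e-9)


class TestRemoveBatchEffects:
    def make(self, rng, offset=0.0, cond_effect=0.0):
        channels = simple_channels(8)
        x = rng.normal(20, 1, size=(300, 8))
        conditions = np.array(["treated"] * 4 + ["untreated"] * 4)
        batches = np.array([1, 1, 2, 2, 1, 1, 2, 2])
        x[:, batches == 2] += offset
        x[:, conditions == "treated"] += cond_effect
        return make_matrix(x, channels, scale="glog2"), batches, conditions

    def test_single_batch_identity(self, rng):
        matrix, _, conditions = self.make(rng)
        out = remove_batch_effects(matrix, np.ones(8), conditions)
        np.testing.assert_array_equal(out.intensities, matrix.intensities)

    def test_balanced_offset_removed_exactly_noise_free(self, rng):
        # closed-form balanced case: protein level + condition effect + batch
        # offset, no noise -> the batch term is removed exactly
        channels = simple_channels(8)
        conditions = np.array(["treated"] * 4 + ["untreated"] * 4)
        batches = np.array([1, 1, 2, 2, 1, 1, 2, 2])
        level = rng.normal(20, 2, size=(300, 1))
        x = np.repeat(level, 8, axis=1)
        x[:, conditions == "treated"] += 1.5
        x[:, batches == 2] += 3.0
        matrix = make_matrix(x, channels, scale="glog2")
        out = remove_batch_effects(matrix, batches, conditions)
        for cond in ("treated", "untreated"):
            sel = conditions == cond
            m1 = out.intensities[:, sel & (batches == 1)].mean(axis=1)
            m2 = out.intensities[:, sel & (batches == 2)].mean(axis=1)
            np.testing.assert_allclose(m1, m2, atol=1e-9)

    def test_noisy_balanced_overall_batch_means_equalized(self, rng):
        matrix, batches, conditions = self.make(rng, offset=3.0)
        out = remove_batch_effects(matrix, batches, conditions)
        m1 = out.intensities[:, batches == 1].mean(axis=1)
        m2 = out.intensities[:, batches == 2].mean(axis=1)
        np.testing.assert_allclose(m1, m2, atol=1e-9)

    def test_condition_contrast_preserved(self, rng):
        matrix, batches, conditions = self.make(rng, offset=3.0, cond_effect=1.5)
        out = remove_batch_effects(matrix, batches, conditions)
        before = (matrix.intensities[:, conditions == "treated"].mean(axis=1)
                  - matrix.intensities[:, conditions == "untreated"].mean(axis=1))
        after = (out.intensities[:, conditions == "treated"].mean(axis=1)
                 - out.intensities[:, conditions == "untreated"].mean(axis=1))
        np.testing.assert_allclose(before, after, atol=1e-9)

    def test_confounded_design_rejected(self, rng):
        matrix, _, _ = self.make(rng)
        batches = np.array([1, 1, 1, 1, 2, 2, 2, 2])  # batch == condition
        conditions = np.array(["treated"] * 4 + ["untreated"] * 4)
        with pytest.raises(DesignError, match="confounded"):
            remove_batch_effects(matrix, batches, conditions)


class TestModeratedTtest:
    def test_identical_groups_null(self, rng):
        x = np.tile(rng.normal(20, 1, size=(100, 3)), (1, 2))
        res = moderated_ttest(x, [0, 1, 2], [3, 4, 5])
        np.testing.assert_allclose(res.log2fc, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.p, 1.0, atol=1e-9)

    def test_prior_df_zero_is_ordinary_t(self, rng):
        x = rng.normal(20, 1, size=(200, 6))
        x[:50, :3] += 1.0
        res = moderated_ttest(x, [0, 1, 2], [3, 4, 5], prior_df=0)
        t_ref, p_ref = st.ttest_ind(x[:, :3], x[:, 3:], axis=1, equal_var=True)
        np.testing.assert_allclose(res.t, t_ref, atol=1e-9)
        np.testing.assert_allclose(res.p, p_ref, atol=1e-9)

    def test_shrinkage_direction(self, rng):
        x = rng.normal(0, 1, size=(2000, 6))
        mod = moderated_ttest(x, [0, 1, 2], [3, 4, 5])
        plain = moderated_ttest(x, [0, 1, 2], [3, 4, 5], prior_df=0)
        assert np.isfinite(mod.df_prior)
        small_var = mod.s2 < mod.s2_prior
        nonzero = np.abs(plain.t) > 1e-8
        sel = small_var & nonzero
        assert np.all(np.abs(mod.t[sel]) <= np.abs(plain.t[sel]) + 1e-9)
        sel2 = (~small_var) & nonzero
        assert np.all(np.abs(mod.t[sel2]) >= np.abs(plain.t[sel2]) - 1e-9)

    def test_type_one_error_near_nominal(self):
        fracs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, size=(2000, 6))
            res = moderated_ttest(x, [0, 1, 2], [3, 4, 5])
            fracs.append(float(np.mean(res.p < 0.05)))
        assert 0.03 < np.mean(fracs) < 0.07

    def test_bh_properties(self, rng):
        x = rng.normal(0, 1, size=(500, 6))
        x[:20, :3] += 2.0
        res = moderated_ttest(x, [0, 1, 2], [3, 4, 5])
        assert np.all(res.p_adj >= res.p - 1e-15)
        assert np.all((res.p >= 0) & (res.p <= 1))
        order = np.argsort(res.p, kind="stable")
        assert np.all(np.diff(res.p_adj[order]) >= -1e-15)

    def test_one_sample_matches_two_sided_t(self, rng):
        x = rng.normal(0.3, 1, size=(300, 4))
        res = moderated_one_sample(x, prior_df=0)
        t_ref, p_ref = st.ttest_1samp(x, 0.0, axis=1)
        np.testing.assert_allclose(res.t, t_ref, atol=1e-9)
        np.testing.assert_allclose(res.p, p_ref, atol=1e-9)

    def test_too_few_replicates_rejected(self, rng):
        with pytest.raises(DesignError):
            moderated_ttest(rng.normal(size=(10, 3)), [0], [1, 2])
        with pytest.raises(DesignError):
            moderated_one_sample(rng.normal(size=(10, 1)))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_moderated_t_matches_limma_oracle(tmp_path, rng):
    """Dual-route check: our empirical-Bayes machinery against limma eBayes."""
    x = rng.normal(20, 1, size=(80, 6))
    x[:10, :3] += 1.5
    x *= rng.lognormal(0, 0.2, size=(80, 1))  # heterogeneous variances
    np.savetxt(tmp_path / "x.tsv", x, delimiter="\t")
    script = textwrap.dedent("""
        suppressMessages(library(limma))
        x <- as.matrix(read.table(commandArgs(TRUE)[1], sep="\t"))
        design <- cbind(Intercept=1, Treated=c(1,1,1,0,0,0))
        fit <- eBayes(lmFit(x, design))
        out <- cbind(fit$coefficients[,"Treated"], fit$t[,"Treated"],
                     fit$p.value[,"Treated"], fit$df.prior, fit$s2.prior)
        write.table(out, commandArgs(TRUE)[2], sep="\t",
                    row.names=FALSE, col.names=FALSE)
    """)
    (tmp_path / "oracle.R").write_text(script)
    subprocess.run(["Rscript", str(tmp_path / "oracle.R"), str(tmp_path / "x.tsv"),
                    str(tmp_path / "out.tsv")], check=True, capture_output=True)
    ref = np.loadtxt(tmp_path / "out.tsv")
    res = moderated_ttest(x, [0, 1, 2], [3, 4, 5])
    np.testing.assert_allclose(res.log2fc, ref[:, 0], atol=1e-8)
    assert res.df_prior == pytest.approx(ref[0, 3], rel=1e-4)
    assert float(res.s2_prior[0]) == pytest.approx(ref[0, 4], rel=1e-4)
    np.testing.assert_allclose(res.t, ref[:, 1], rtol=1e-6, atol=1e-8)
    np.testing.assert_allclose(res.p, ref[:, 2], rtol=1e-5, atol=1e-12)


class TestScoreFdr:
    def test_null_center_near_one_and_monotone(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=2000)
        fdr = score_fdr(z)
        assert np.median(fdr[np.abs(z) < 1]) > 0.8
        az = np.abs(z - np.median(z))
        order = np.argsort(az)
        assert np.all(np.diff(fdr[order]) <= 1e-12)

    def test_spiked_scores_detected(self):
        rng = np.random.default_rng(11)
        z = rng.normal(size=2000)
        z[:10] = 6.0 + rng.normal(0, 0.1, 10)
        fdr = score_fdr(z)
        assert fdr[:10].max() < 0.01

    def test_concordance_with_bh_on_well_separated_spikes(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=2000)
        z[:10] = 7.0
        fdr = score_fdr(z)
        p = 2 * st.norm.sf(np.abs((z - np.median(z)) / (1.4826 * np.median(np.abs(z - np.median(z))))))
        order = np.argsort(p, kind="stable")
        p_adj = np.minimum.accumulate((p[order] * z.size / (np.arange(z.size) + 1))[::-1])[::-1]
        bh = np.empty_like(p)
        bh[order] = p_adj
        assert set(np.flatnonzero(fdr < 0.01)) == set(np.flatnonzero(bh < 0.01))

    def test_degenerate_and_small_inputs_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            score_fdr(np.zeros(100))
        with pytest.raises(ValueError):
            score_fdr(np.random.default_rng(0).normal(size=30))


class TestVariancePrior:
    def test_recovers_known_prior(self):
        rng = np.random.default_rng(5)
        d0_true, s0_true, df = 8.0, 0.04, 4
        s2_pop = s0_true * d0_true / rng.chisquare(d0_true, size=5000)
        s2_obs = s2_pop * rng.chisquare(df, size=5000) / df
        d0, s0 = fit_variance_prior(s2_obs, df)
        assert d0 == pytest.approx(d0_true, rel=0.25)
        assert float(np.mean(s0)) == pytest.approx(s0_true, rel=0.1)

    def test_homogeneous_variances_give_infinite_prior(self):
        rng = np.random.default_rng(6)
        s2 = 0.02 * rng.chisquare(4, size=5000) / 4
        d0, _ = fit_variance_prior(s2, 4)
        assert d0 > 50 or np.isinf(d0)
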