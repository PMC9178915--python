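"""Random-intercept REML: closed forms, oracles and shrinkage behaviour."""

import numpy as np
import pandas as pd
import pytest

from conftest import simulate_pass_means
from oracles import dense_reml_fit
from segmap.mixed import blup, fit_mixed, fit_mixed_from_lur, predict_map
from segmap.synthetic import CampaignConfig, generate_network


def toy_frame():
    return pd.DataFrame(
        {"segment_id": ["A", "A", "B", "B"], "mean_concentration": [1.0, 3.0, 5.0, 7.0]}
    )


def toy_cov():
    return pd.DataFrame(index=pd.Index(["A", "B"], name="segment_id"))


class TestBalancedClosedForm:
    """Balanced one-way REML equals the ANOVA estimators."""

    def test_toy_estimates(self):
        fit = fit_mixed(toy_frame(), toy_cov(), [])
        assert fit.beta["intercept"] == pytest.approx(4.0, abs=1e-8)
        assert fit.sigma2_e == pytest.approx(2.0, rel=1e-6)
        assert fit.sigma2_b == pytest.approx(7.0, rel=1e-6)

    def test_toy_blup_shrinkage(self):
        fit = fit_mixed(toy_frame(), toy_cov(), [])
        w = fit.segments.loc["A", "shrink_w"]
        assert w == pytest.approx(2 * 7 / (2 + 2 * 7), rel=1e-6)
        assert blup(fit, "A") == pytest.approx(-1.75, rel=1e-6)
        assert blup(fit, "B") == pytest.approx(+1.75, rel=1e-6)

    def test_statsmodels_cross_check(self, rng):
        """Independent REML fit (statsmodels MixedLM) on a random dataset."""
        sm = pytest.importorskip("statsmodels.api")
        pm, cov, names = simulate_pass_means(rng, 40, 4, [10.0, 2.0], 4.0, 9.0)
        fit = fit_mixed(pm, cov, names)
        df = pm.merge(cov, on="segment_id")
        md = sm.MixedLM(
            df["mean_concentration"],
            sm.add_constant(df[names]),
            groups=df["segment_id"],
        ).fit(reml=True)
        assert fit.beta["intercept"] == pytest.approx(md.params["const"], rel=1e-4)
        assert fit.beta[names[0]] == pytest.approx(md.params[names[0]], rel=1e-4)
        assert fit.sigma2_e == pytest.approx(md.scale, rel=1e-3)
        assert fit.sigma2_b == pytest.approx(float(md.cov_re.iloc[0, 0]), rel=1e-3)


class TestOracleEquivalence:
    def test_dense_grid_oracle(self, rng):
        """Profiled REML matches the dense grid+golden maximiser."""
        pm, cov, names = simulate_pass_means(rng, 30, 5, [20.0, 3.0, -1.0, 0.5], 16.0, 25.0)
        fit = fit_mixed(pm, cov, names)
        df = pm.merge(cov, on="segment_id")
        X = np.column_stack([np.ones(len(df))] + [df[n] for n in names])
        o = dense_reml_fit(
            df["mean_concentration"].to_numpy(), df["segment_id"].to_numpy(), X
        )
        assert fit.sigma2_b == pytest.approx(o["sigma2_b"], rel=1e-4)
        assert fit.sigma2_e == pytest.approx(o["sigma2_e"], rel=1e-4)
        np.testing.assert_allclose(fit.beta.to_numpy(), o["beta"], rtol=1e-4)
        assert fit.loglik == pytest.approx(o["loglik"], rel=1e-6)

    def test_ml_matches_dense_oracle(self, rng):
        pm, cov, names = simulate_pass_means(rng, 25, 4, [15.0, 2.0], 9.0, 16.0)
        fit = fit_mixed(pm, cov, names, method="ml")
        df = pm.merge(cov, on="segment_id")
        X = np.column_stack([np.ones(len(df))] + [df[n] for n in names])
        o = dense_reml_fit(
            df["mean_concentration"].to_numpy(),
            df["segment_id"].to_numpy(),
            X,
            method="ml",
        )
        assert fit.sigma2_b == pytest.approx(o["sigma2_b"], rel=1e-4, abs=1e-8)
        assert fit.sigma2_e == pytest.approx(o["sigma2_e"], rel=1e-4)


class TestShrinkage:
    def test_no_between_variance_collapses_to_regression(self, rng):
        """With b == 0 the between-segment variance estimate hits the
        boundary and every prediction equals the regression surface."""
        pm, cov, names = simulate_pass_means(rng, 150, 5, [20.0, 2.0], 0.0, 4.0)
        fit = fit_mixed(pm, cov, names)
        assert fit.sigma2_b <= 0.05 * fit.sigma2_e
        if fit.lam == 0.0:
            assert (fit.segments["blup"] == 0.0).all()
            assert (fit.segments["pred"] == fit.segments["fixed_pred"]).all()

    def test_many_passes_trust_the_data(self, rng):
        """At 200 passes with known variances the prediction sits within
        1% of the way from the segment mean toward the surface."""
        pm, cov, names = simulate_pass_means(rng, 30, 199, [20.0, 2.0], 16.0, 25.0)
        pm = pm.groupby("segment_id").head(200)
        fit = fit_mixed(pm, cov, names, fix_variance_components=(16.0, 25.0))
        seg = fit.segments
        gap_data = (seg["pred"] - seg["ybar"]).abs()
        gap_lur = (seg["fixed_pred"] - seg["ybar"]).abs()
        assert (gap_data <= 0.01 * gap_lur + 1e-12).all()

    def test_convex_combination_and_monotone_weights(self, rng):
        pm, cov, names = simulate_pass_means(rng, 80, 6, [20.0, 2.0], 16.0, 25.0)
        fit = fit_mixed(pm, cov, names)
        seg = fit.segments
        lo = np.minimum(seg["ybar"], seg["fixed_pred"]) - 1e-9
        hi = np.maximum(seg["ybar"], seg["fixed_pred"]) + 1e-9
        assert ((seg["pred"] >= lo) & (seg["pred"] <= hi)).all()
        assert ((seg["shrink_w"] >= 0) & (seg["shrink_w"] < 1)).all()
        by_n = seg.sort_values("n_passes")
        w = by_n.groupby("n_passes")["shrink_w"].first()
        assert w.is_monotonic_increasing

    def test_blup_formula(self, rng):
        pm, cov, names = simulate_pass_means(rng, 40, 4, [20.0, 2.0], 9.0, 16.0)
        fit = fit_mixed(pm, cov, names)
        seg = fit.segments
        expect = (
            seg["n_passes"] * fit.sigma2_b
            / (fit.sigma2_e + seg["n_passes"] * fit.sigma2_b)
            * (seg["ybar"] - seg["fixed_pred"])
        )
        np.testing.assert_allclose(seg["blup"], expect, rtol=1e-10)

    def test_gls_normal_equations(self, rng):
        """GLS residual orthogonality: sum_i w_i x_i (ybar_i - x_i'beta) = 0."""
        pm, cov, names = simulate_pass_means(rng, 60, 5, [20.0, 2.0, 1.0], 9.0, 16.0)
        fit = fit_mixed(pm, cov, names)
        seg = fit.segments
        X = np.column_stack(
            [np.ones(len(seg))] + [cov.loc[seg.index, n] for n in names]
        )
        w = seg["n_passes"] / (1.0 + seg["n_passes"] * fit.lam)
        resid = seg["ybar"] - seg["fixed_pred"]
        score = X.T @ (w * resid)
        scale = np.abs(X.T @ (w * seg["ybar"])).max()
        assert np.abs(score).max() <= 1e-8 * scale


class TestErrorsAndModes:
    def test_all_single_pass_unidentifiable(self):
        pm = pd.DataFrame(
            {"segment_id": ["A", "B", "C"], "mean_concentration": [1.0, 2.0, 3.0]}
        )
        cov = pd.DataFrame(index=pd.Index(["A", "B", "C"], name="segment_id"))
        with pytest.raises(ValueError, match="identifiable"):
            fit_mixed(pm, cov, [])

    def test_unknown_segment_lookup(self):
        fit = fit_mixed(toy_frame(), toy_cov(), [])
        with pytest.raises(KeyError):
            blup(fit, "nope")

    def test_freeze_beta_estimates_variances_only(self, rng):
        pm, cov, names = simulate_pass_means(rng, 60, 5, [20.0, 2.0], 9.0, 16.0)
        frozen = pd.Series({"intercept": 20.0, names[0]: 2.0})
        fit = fit_mixed(pm, cov, names, freeze_beta=frozen)
        assert fit.beta["intercept"] == 20.0
        assert fit.beta[names[0]] == 2.0
        assert fit.sigma2_e == pytest.approx(16.0, rel=0.5)
        assert fit.sigma2_b == pytest.approx(9.0, rel=0.8)


class TestPredictMap:
    def test_unmeasured_segments_fall_back_to_lur(self, rng):
        from segmap.lur import fit_lur, predict_lur

        net = generate_network(60, rng)
        cfg = CampaignConfig(n_segments=60, seed=5)
        # pass means only for the first 40 segments
        pm, cov, names = simulate_pass_means(rng, 40, 5, [20.0, 2.0], 9.0, 16.0)
        cov_full = pd.concat(
            [cov, pd.DataFrame(
                rng.normal(size=(20, 1)), columns=names,
                index=pd.Index(range(40, 60), name="segment_id"),
            )]
        )
        net.covariates = cov_full
        net.segments = net.segments.iloc[:60]
        fit = fit_mixed(pm, cov_full, names)
        out = predict_map(fit, net).set_index("segment_id")
        assert out.loc[40:, "lur_only"].all()
        assert not out.loc[:39, "lur_only"].any()
        # flagged rows equal the fixed-effects surface exactly
        unm = out.loc[40:]
        np.testing.assert_array_equal(unm["mixed_pred"], unm["lur_pred"])
        assert (unm["blup"] == 0.0).all()

    def test_facade_adjust_scales_predictions(self, rng):
        pm, cov, names = simulate_pass_means(rng, 30, 4, [20.0, 2.0], 9.0, 16.0)
        net = generate_network(30, rng)
        net.covariates = cov
        fit = fit_mixed(pm, cov, names)
        raw = predict_map(fit, net)
        adj = predict_map(fit, net, facade_adjust=0.8)
        np.testing.assert_allclose(adj["mixed_pred"], 0.8 * raw["mixed_pred"])
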