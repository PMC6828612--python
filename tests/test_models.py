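"""Mixed models, LRT, ANOVA, t-tests and power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from peritheta import models as md


def simulate_lmm(rng, n_groups=10, n_per=20, beta=(1.0, 0.5), sd_b=0.6,
                 sd_e=1.0):
    subj = np.repeat(np.arange(n_groups), n_per)
    x = rng.normal(size=subj.size)
    b = rng.normal(0, sd_b, n_groups)[subj]
    y = beta[0] + beta[1] * x + b + rng.normal(0, sd_e, subj.size)
    return pd.DataFrame({"y": y, "x": x, "subject": subj})


def direct_loglike(df, beta, psi, sigma2):
    """Straight evaluation of the marginal Gaussian log-likelihood,
    independent of the profiled fitting code."""
    ll = 0.0
    for _, sub in df.groupby("subject"):
        r = sub["y"].to_numpy() - beta[0] - beta[1] * sub["x"].to_numpy()
        n = r.size
        V = sigma2 * (np.eye(n) + psi * np.ones((n, n)))
        sign, logdet = np.linalg.slogdet(V)
        ll += -0.5 * (n * np.log(2 * np.pi) + logdet
                      + r @ np.linalg.solve(V, r))
    return ll


class TestRandomInterceptLM:
    def test_matches_statsmodels_ml(self, rng):
        import statsmodels.api as sm
        df = simulate_lmm(rng)
        ours = md.RandomInterceptLM.from_dataframe(df, "y", ["x"],
                                                   "subject").fit()
        ref = sm.MixedLM.from_formula("y ~ x", groups="subject",
                                      data=df).fit(reml=False)
        assert ours.llf == pytest.approx(ref.llf, abs=1e-5)
        assert ours.params.to_numpy() == pytest.approx(ref.fe_params.to_numpy(),
                                                       abs=1e-5)
        assert ours.sigma2_resid == pytest.approx(ref.scale, rel=1e-4)
        assert ours.sigma2_group == pytest.approx(float(ref.cov_re.iloc[0, 0]),
                                                  rel=1e-3, abs=1e-4)

    def test_no_group_variance_reduces_to_ols(self, rng):
        import statsmodels.api as sm
        df = simulate_lmm(rng, sd_b=0.0, n_groups=8, n_per=40)
        ours = md.RandomInterceptLM.from_dataframe(df, "y", ["x"],
                                                   "subject").fit()
        ols = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
        assert ours.params.to_numpy() == pytest.approx(ols.params.to_numpy(),
                                                       abs=1e-3)
        assert ours.psi < 0.02

    def test_optimizer_matches_grid_oracle(self, rng):
        """Profiled optimizer reaches the best log-likelihood found by a
        dense 2-D grid over (psi, sigma2) on a 5-subject toy set."""
        df = simulate_lmm(rng, n_groups=5, n_per=8)
        fit = md.RandomInterceptLM.from_dataframe(df, "y", ["x"],
                                                  "subject").fit()
        beta = fit.params.to_numpy()
        best = -np.inf
        for psi in np.geomspace(1e-4, 50, 120):
            for s2 in np.geomspace(0.05, 10, 120):
                best = max(best, direct_loglike(df, beta, psi, s2))
        assert fit.llf >= best - 1e-4
        # and the fit's own (psi, sigma2) reproduce its reported llf
        assert direct_loglike(df, beta, fit.psi, fit.sigma2_resid) \
            == pytest.approx(fit.llf, abs=1e-6)

    def test_balanced_closed_form(self, rng):
        """Balanced one-way layout: ML variance components have the
        closed forms sigma2_e = SSW/(N-G), sigma2_b = SSB/G/n - SSW/((N-G) n)."""
        G, n = 12, 15
        subj = np.repeat(np.arange(G), n)
        y = rng.normal(0, 1.0, G * n) + rng.normal(0, 0.8, G)[subj]
        df = pd.DataFrame({"y": y, "subject": subj})
        fit = md.RandomInterceptLM.from_dataframe(df, "y", [],
                                                  "subject").fit()
        gm = y.mean()
        means = df.groupby("subject")["y"].mean().to_numpy()
        ssw = ((y - means[subj]) ** 2).sum()
        ssb = n * ((means - gm) ** 2).sum()
        sig_e = ssw / (G * n - G)
        sig_b = ssb / G / n - sig_e / n
        assert fit.params["Intercept"] == pytest.approx(gm, abs=1e-8)
        assert fit.sigma2_resid == pytest.approx(sig_e, rel=1e-5)
        assert fit.sigma2_group == pytest.approx(sig_b, rel=1e-4)

    def test_singular_design_rejected(self, rng):
        df = simulate_lmm(rng)
        df["x2"] = 2 * df["x"]
        with pytest.raises(ValueError, match="singular"):
            md.RandomInterceptLM.from_dataframe(df, "y", ["x", "x2"],
                                                "subject")

    def test_summary_mentions_variances(self, rng):
        fit = md.RandomInterceptLM.from_dataframe(
            simulate_lmm(rng), "y", ["x"], "subject").fit()
        s = fit.summary()
        assert "var(subject)" in s and "Intercept" in s


class TestLRT:
    def test_identical_models(self, rng):
        df = simulate_lmm(rng)
        full = md.RandomInterceptLM.from_dataframe(df, "y", ["x"],
                                                   "subject").fit()
        reduced = md.RandomInterceptLM.from_dataframe(df, "y", [],
                                                      "subject").fit()
        t = md.lrt(full, reduced)
        assert t.chi2 >= 0 and t.df == 1 and 0 <= t.pvalue <= 1

    def test_adding_effects_never_lowers_llf(self, rng):
        for _ in range(10):
            df = simulate_lmm(rng, n_groups=6, n_per=10)
            df["z"] = rng.normal(size=len(df))
            small = md.RandomInterceptLM.from_dataframe(df, "y", ["x"],
                                                        "subject").fit()
            big = md.RandomInterceptLM.from_dataframe(df, "y", ["x", "z"],
                                                      "subject").fit()
            assert big.llf >= small.llf - 1e-6

    def test_non_nested_rejected(self, rng):
        df = simulate_lmm(rng)
        df["z"] = rng.normal(size=len(df))
        a = md.RandomInterceptLM.from_dataframe(df, "y", ["x"],
                                                "subject").fit()
        b = md.RandomInterceptLM.from_dataframe(df, "y", ["z"],
                                                "subject").fit()
        with pytest.raises(ValueError, match="nested"):
            md.lrt(a, b)


class TestRandomInterceptLogit:
    def test_zero_variance_matches_plain_logit(self, rng):
        import statsmodels.api as sm
        n = 1500
        subj = np.repeat(np.arange(30), n // 30)
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.4 + 0.8 * x)))).astype(float)
        df = pd.DataFrame({"y": y, "x": x, "subject": subj})
        ours = md.RandomInterceptLogit.from_dataframe(df, "y", ["x"],
                                                      "subject").fit()
        ref = sm.Logit(df["y"], sm.add_constant(df["x"])).fit(disp=0)
        assert ours.params.to_numpy() == pytest.approx(ref.params.to_numpy(),
                                                       abs=0.05)
        assert ours.tau < 0.25

    def test_matches_lme4_adaptive_quadrature_fixture(self):
        """Frozen oracle: fit of glmer(y ~ g + (1|subject), binomial,
        nAGQ=21) on the identical simulated dataset."""
        rng = np.random.default_rng(42)
        G, n = 30, 40
        subj = np.repeat(np.arange(G), n)
        b = rng.normal(0, 1.0, G)[subj]
        g = (np.arange(G) >= 15).astype(float)[subj]
        eta = 0.8 - 0.7 * g + b
        y = (rng.random(G * n) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame({"y": y, "g": g, "subject": subj})
        fit = md.RandomInterceptLogit.from_dataframe(df, "y", ["g"],
                                                     "subject").fit()
        assert fit.params["Intercept"] == pytest.approx(0.8916439, abs=2e-4)
        assert fit.params["g"] == pytest.approx(-0.7836716, abs=2e-4)
        assert fit.tau == pytest.approx(0.6771677, abs=2e-4)
        assert fit.llf == pytest.approx(-757.0137, abs=2e-3)

    def test_quadrature_node_stability(self, rng):
        df = simulate_lmm(rng, n_groups=20, n_per=30)
        df["y"] = (df["y"] > df["y"].median()).astype(float)
        m21 = md.RandomInterceptLogit.from_dataframe(df, "y", ["x"],
                                                     "subject").fit(n_quad=21)
        ll41 = md.RandomInterceptLogit.from_dataframe(
            df, "y", ["x"], "subject")._loglike(
                m21.params.to_numpy(), m21.tau,
                *np.polynomial.hermite.hermgauss(41))
        assert abs(m21.llf - ll41) < 1e-4

    def test_group_rate_difference_recovery(self):
        """Generator-style error rates 0.097 vs 0.068: the recovered
        group log-odds difference matches logit(p1)-logit(p2)."""
        rng = np.random.default_rng(3)
        G, n = 160, 288
        subj = np.repeat(np.arange(G), n)
        adhd = (np.arange(G) >= G // 2).astype(float)[subj]
        p = np.where(adhd == 1, 0.097, 0.068)
        y = (rng.random(G * n) < p).astype(float)   # "error" indicator
        df = pd.DataFrame({"y": y, "adhd": adhd, "subject": subj})
        fit = md.RandomInterceptLogit.from_dataframe(df, "y", ["adhd"],
                                                     "subject").fit()
        expected = (np.log(0.097 / 0.903) - np.log(0.068 / 0.932))
        assert fit.params["adhd"] == pytest.approx(expected, abs=0.08)


class TestMixedAnova:
    def _subject_means(self, rng, n0=26, n1=14, inter=0.0):
        rows = []
        for i in range(n0 + n1):
            grp = "ADHD" if i < n0 else "TD"
            base = rng.normal(0, 1)
            for j, pos in enumerate(("er_m1", "er_p1")):
                eff = inter * j * (grp == "TD")
                rows.append({"subject": f"s{i}", "group": grp,
                             "position": pos,
                             "value": base + eff + rng.normal(0, 0.5)})
        return pd.DataFrame(rows)

    def test_identical_cells_give_zero_F(self, rng):
        sm_ = self._subject_means(rng)
        sm_["value"] = 1.0
        out = md.mixed_anova_2x2(sm_)
        assert np.allclose(out["F"], 0.0)

    def test_denominator_df_is_n_minus_2(self, rng):
        out = md.mixed_anova_2x2(self._subject_means(rng))
        assert (out["df2"] == 38).all()
        assert (out["df1"] == 1).all()

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        sm_ = self._subject_means(rng, inter=0.6)
        ours = md.mixed_anova_2x2(sm_).set_index("effect")
        ref = pingouin.mixed_anova(data=sm_, dv="value", within="position",
                                   between="group", subject="subject")
        ref = ref.set_index("Source")
        assert ours.loc["group", "F"] == pytest.approx(
            ref.loc["group", "F"], rel=1e-6)
        assert ours.loc["position", "F"] == pytest.approx(
            ref.loc["position", "F"], rel=1e-6)
        assert ours.loc["group*position", "F"] == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-6)

    def test_agrees_with_lmm_route(self):
        """The ANOVA interaction decision matches the mixed-model
        group x position LRT decision in >= 95% of replicates."""
        rng = np.random.default_rng(99)
        agree = 0
        n_rep = 40
        for rep in range(n_rep):
            inter = 0.0 if rep % 2 == 0 else 0.7
            sm_ = self._subject_means(rng, inter=inter)
            a = md.mixed_anova_2x2(sm_).set_index("effect")
            sm_ = sm_.copy()
            sm_["pos"] = (sm_["position"] == "er_p1").astype(float)
            sm_["td"] = (sm_["group"] == "TD").astype(float)
            sm_["td_pos"] = sm_["td"] * sm_["pos"]
            full = md.RandomInterceptLM.from_dataframe(
                sm_, "value", ["pos", "td", "td_pos"], "subject").fit()
            red = md.RandomInterceptLM.from_dataframe(
                sm_, "value", ["pos", "td"], "subject").fit()
            t = md.lrt(full, red)
            agree += ((t.pvalue < 0.05)
                      == (a.loc["group*position", "p"] < 0.05))
        assert agree / n_rep >= 0.95

    def test_missing_cells_rejected(self, rng):
        sm_ = self._subject_means(rng).iloc[1:]
        with pytest.raises(ValueError):
            md.mixed_anova_2x2(sm_)


class TestTTests:
    def test_equal_samples_t_zero(self):
        t, df, p = md.two_sample_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0 and df == 4

    def test_hand_computed_pooled_t(self):
        # x: mean 2.5, SS 5; y: mean 5, SS 20; sp2 = 25/6
        # t = -2.5 / sqrt(25/6 * 1/2) = -1.73205
        t, df, p = md.two_sample_t([1, 2, 3, 4], [2, 4, 6, 8])
        assert df == 6
        assert t == pytest.approx(-np.sqrt(3), rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(np.sqrt(3), 6), rel=1e-12)

    def test_paired_df(self, rng):
        x = rng.normal(size=26)
        y = x + rng.normal(0.3, 1, 26)
        t, df, p = md.two_sample_t(x, y, paired=True)
        assert df == 25

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            md.two_sample_t([1.0], [2.0, 3.0])


class TestPower:
    def test_null_effect_gives_alpha(self):
        assert md.ttest_power(0.0, 26, 14).power == pytest.approx(0.05,
                                                                  abs=1e-9)

    def test_two_sided_symmetry(self):
        assert md.ttest_power(-0.42, 26, 14).power \
            == md.ttest_power(0.42, 26, 14).power

    def test_monotone_in_d_and_n(self):
        ds = [0.1, 0.3, 0.5, 1.0, 2.0]
        powers = [md.ttest_power(d, 26, 14).power for d in ds]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        assert md.ttest_power(0.5, 52, 28).power \
            > md.ttest_power(0.5, 26, 14).power
        assert md.ttest_power(8.0, 26, 14).power > 0.9999

    def test_matches_statsmodels(self):
        import statsmodels.stats.power as smp
        ref = smp.TTestIndPower().power(effect_size=0.42, nobs1=26,
                                        ratio=14 / 26, alpha=0.05)
        assert md.ttest_power(0.42, 26, 14).power == pytest.approx(ref,
                                                                   abs=1e-10)

    def test_min_detectable_d_round_trip(self):
        d = md.min_detectable_d(0.80, 26, 14)
        assert md.ttest_power(d, 26, 14).power >= 0.80
        assert md.ttest_power(d - 2e-4, 26, 14).power < 0.80
        # larger samples detect smaller effects
        assert md.min_detectable_d(0.80, 52, 28) < d
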