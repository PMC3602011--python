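"""Mixed models, repeatability, decomposition, effect sizes, FDR, VIF."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from trillgauge import stats as st
from trillgauge.stats import ModelSpec


def _grouped(seed=0, ng=40, nper=15, s_u=1.0, s_e=1.0, slope=2.0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(ng), nper)
    x = rng.normal(size=ng * nper)
    y = slope * x + rng.normal(0, s_u, ng)[g] + rng.normal(0, s_e, ng * nper)
    return pd.DataFrame({"y": y, "x": x, "g": g.astype(str)})


class TestFitMixed:
    def test_matches_statsmodels_mixedlm(self):
        """Dual route: the profiled-REML fitter must agree with MixedLM."""
        d = _grouped(seed=5)
        fast = st.fit_mixed(ModelSpec("y", ["x"], group="g"), d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = smf.mixedlm("y ~ x", d, groups=d["g"]).fit(reml=True)
        assert np.allclose(fast.params.estimate, ref.params[:2], atol=1e-5)
        assert np.allclose(fast.params.se, ref.bse[:2], atol=1e-4)
        assert fast.sigma2_between == pytest.approx(float(ref.cov_re.iloc[0, 0]), abs=1e-3)
        assert fast.sigma2_within == pytest.approx(float(ref.scale), abs=1e-3)

    def test_one_observation_per_group_equals_ols(self):
        rng = np.random.default_rng(1)
        d = pd.DataFrame(
            {"y": rng.normal(size=40), "x": rng.normal(size=40),
             "g": [str(i) for i in range(40)]}
        )
        mix = st.fit_mixed(ModelSpec("y", ["x"], group="g"), d)
        ols = smf.ols("y ~ x", d).fit()
        assert np.allclose(mix.params.estimate, ols.params, atol=1e-8)

    def test_satterthwaite_df_between_vs_within(self):
        """A within-group covariate gets ~observation-level df, a
        between-group covariate ~group-level df."""
        rng = np.random.default_rng(2)
        ng, nper = 50, 20
        g = np.repeat(np.arange(ng), nper)
        x = rng.normal(size=ng * nper)
        xg = rng.normal(size=ng)[g]
        y = x + xg + rng.normal(0, 1, ng)[g] + rng.normal(0, 1, ng * nper)
        d = pd.DataFrame({"y": y, "x": x, "xg": xg, "g": g.astype(str)})
        res = st.fit_mixed(ModelSpec("y", ["x", "xg"], group="g"), d)
        df_within = res.term("x").df
        df_between = res.term("xg").df
        assert df_within > 700
        assert 30 < df_between < 120

    def test_slope_ci_coverage(self):
        hits = 0
        for s in range(100):
            d = _grouped(seed=s, ng=50, nper=20)
            res = st.fit_mixed(ModelSpec("y", ["x"], group="g"), d)
            row = res.term("x")
            import scipy.stats as sps

            half = sps.t.ppf(0.975, row.df) * row.se
            hits += abs(row.estimate - 2.0) < half
        assert hits >= 93

    def test_constant_response_returns_zero_variance_result(self):
        d = _grouped()
        d["y"] = 3.0
        res = st.fit_mixed(ModelSpec("y", ["x"], group="g"), d)
        assert res.sigma2_between == 0.0 and res.sigma2_within == 0.0

    def test_singular_design_names_aliased_terms(self):
        d = _grouped()
        d["x2"] = d.x
        with pytest.raises(ValueError, match="aliased"):
            st.fit_mixed(ModelSpec("y", ["x", "x2"], group="g"), d)

    def test_binomial_family_runs_and_is_calibrated_shape(self):
        rng = np.random.default_rng(3)
        n = 120
        d = pd.DataFrame(
            {"x": rng.normal(size=n), "g": [str(i % 60) for i in range(n)]}
        )
        d["y"] = (rng.random(n) < 1 / (1 + np.exp(-d.x))).astype(float)
        res = st.fit_mixed(ModelSpec("y", ["x"], group="g", family="binomial"), d)
        assert res.family == "binomial"
        assert res.term("x").estimate > 0
        assert 0 <= res.term("x").p <= 1


class TestRepeatability:
    def test_zero_within_variance_gives_r_one(self):
        d = pd.DataFrame({"y": np.repeat([1.0, 2.0, 5.0], 10),
                          "g": np.repeat(list("abc"), 10)})
        rep = st.repeatability(d, "y", [], "g")
        assert rep.r > 0.999

    def test_single_group_errors(self):
        d = pd.DataFrame({"y": np.arange(10.0), "g": ["a"] * 10})
        with pytest.raises(ValueError):
            st.repeatability(d, "y", [], "g")

    def test_shuffled_labels_remove_repeatability(self):
        rng = np.random.default_rng(0)
        d = _grouped(seed=9, ng=30, nper=20, s_u=1.0, s_e=1.0)
        rep = st.repeatability(d, "y", ["x"], "g")
        assert rep.r > 0.3 and rep.p < 1e-6
        sh = d.copy()
        sh["g"] = rng.permutation(sh.g.to_numpy())
        rep0 = st.repeatability(sh, "y", ["x"], "g")
        assert rep0.r < 0.05

    def test_permutation_null_p_roughly_uniform(self):
        rng = np.random.default_rng(4)
        d = _grouped(seed=13, ng=25, nper=8, s_u=0.0, s_e=1.0)
        ps = []
        for _ in range(60):
            sh = d.copy()
            sh["g"] = rng.permutation(sh.g.to_numpy())
            ps.append(st.repeatability(sh, "y", [], "g").p)
        ps = np.asarray(ps)
        # boundary-corrected LRT p is 0.5 at r_hat = 0, so check no excess
        # of small p-values rather than exact uniformity
        assert (ps < 0.05).mean() <= 0.15
        assert (ps < 0.25).mean() <= 0.45


class TestReversalAndConsistency:
    def test_reversing_response_and_predictor_preserves_association(self):
        """Regressing the trait on success (trait as response, controlling
        male pseudoreplication) and success on the male-mean trait agree in
        sign and significance classification."""
        rng = np.random.default_rng(17)
        ng, nper = 50, 20
        u = rng.normal(0, 1.0, ng)
        s = (rng.random(ng) < 1 / (1 + np.exp(-1.5 * u))).astype(float)
        g = np.repeat(np.arange(ng), nper)
        y = u[g] + rng.normal(0, 1.0, ng * nper)
        d = pd.DataFrame({"y": y, "s": s[g], "g": g.astype(str)})
        fwd = st.fit_mixed(ModelSpec("y", ["s"], group="g"), d).term("s")
        mm = d.groupby("g", as_index=False).agg(ymean=("y", "mean"), s=("s", "first"))
        mm["g"] = mm.g
        rev = st.fit_mixed(
            ModelSpec("s", ["ymean"], group="g", family="binomial"), mm
        ).term("ymean")
        assert np.sign(fwd.estimate) == np.sign(rev.estimate) == 1.0
        assert (fwd.p < 0.05) == (rev.p < 0.05) == True  # noqa: E712

    def test_repeatability_spread_shrinks_as_groups_double(self):
        """Monte Carlo spread of the repeatability estimator falls when the
        number of groups (and replicates) doubles."""
        def spread(ng, nper):
            ests = []
            for seed in range(15):
                rng = np.random.default_rng(seed)
                g = np.repeat(np.arange(ng), nper)
                y = rng.normal(0, 1, ng)[g] + rng.normal(0, np.sqrt(3), ng * nper)
                d = pd.DataFrame({"y": y, "g": g.astype(str)})
                ests.append(st.repeatability(d, "y", [], "g").r)
            return np.std(ests)

        assert spread(60, 16) < spread(15, 8)


class TestDecomposition:
    def test_mean_plus_deviation_reconstructs_covariate(self, rng):
        d = _grouped(seed=21)
        d["k"] = rng.integers(0, 3, len(d))
        gm = d.groupby(["g", "k"]).x.transform("mean")
        assert np.abs((gm + (d.x - gm)) - d.x).max() < 1e-12

    def test_recovers_distinct_slopes(self):
        rng = np.random.default_rng(8)
        ng, nper = 59, 60
        g = np.repeat(np.arange(ng), nper)
        xg = rng.normal(0, 0.5, ng)[g]
        xd = rng.normal(0, 0.5, ng * nper)
        y = -5.0 * xg - 3.0 * xd + rng.normal(0, 1, ng)[g] + rng.normal(0, 2, ng * nper)
        d = pd.DataFrame({"y": y, "x": xg + xd, "g": g.astype(str), "k": 0})
        dec = st.within_between_decompose(d, "y", "x", ["g", "k"], "g")
        assert abs(dec.beta_between - (-5.0)) < 3 * dec.se_between
        assert abs(dec.beta_within - (-3.0)) < 3 * dec.se_within

    def test_constant_within_groups_errors(self):
        d = _grouped()
        d["xc"] = d.groupby("g").x.transform("mean")
        with pytest.raises(ValueError, match="within"):
            st.within_between_decompose(d, "y", "xc", ["g"], "g")


class TestPaired:
    def test_identical_pairs_give_zero_t(self):
        res = st.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0 and res["p"] == 1.0 and res["cohens_d"] == 0.0

    def test_role_model_runs_with_duplicated_males(self):
        rng = np.random.default_rng(6)
        rows = []
        for p in range(8):
            for role, male in (("WP", f"M{p}"), ("EP", f"M{(p + 1) % 8}")):
                for _ in range(6):
                    rows.append({"y": rng.normal(), "role": role, "male": male,
                                 "pair": f"P{p}"})
        d = pd.DataFrame(rows)
        res = st.paired_role_model(d, "y", "role", "male", "pair")
        assert res.n_obs == len(d)
        assert np.isfinite(res.term("role").estimate)

    def test_incomplete_pair_dropped_with_warning(self):
        d = pd.DataFrame({
            "y": np.arange(12.0),
            "role": ["WP"] * 4 + ["EP"] * 4 + ["WP"] * 4,
            "male": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
            "pair": ["P0"] * 8 + ["P1"] * 4,
        })
        with pytest.warns(UserWarning, match="missing a role"):
            res = st.paired_role_model(d, "y", "role", "male", "pair")
        assert res.n_obs == 8


class TestEffectSizes:
    def test_zero_t_gives_zero_r_with_ci_spanning_zero(self):
        es = st.effect_partial_r(0.0, 50)
        assert es.value == 0.0
        assert es.ci_low < 0 < es.ci_high

    def test_partial_r_formula(self):
        es = st.effect_partial_r(2.0, 100)
        assert es.value == pytest.approx(2.0 / np.sqrt(4.0 + 100.0), abs=1e-12)
        assert es.value == pytest.approx(0.1961, abs=1e-4)

    def test_ci_consistent_with_noncentral_t(self):
        import scipy.stats as sps

        t, df = 2.5, 60.0
        es = st.effect_partial_r(t, df)
        nc_low = es.ci_low * np.sqrt(df) / np.sqrt(1 - es.ci_low**2)
        nc_high = es.ci_high * np.sqrt(df) / np.sqrt(1 - es.ci_high**2)
        assert sps.nct.cdf(t, df, nc_high) == pytest.approx(0.025, abs=1e-6)
        assert sps.nct.cdf(t, df, nc_low) == pytest.approx(0.975, abs=1e-6)

    def test_equal_groups_give_zero_d(self):
        es = st.cohens_d(mean1=5.0, sd1=1.0, n1=20, mean2=5.0, sd2=1.2, n2=25)
        assert es.value == 0.0

    def test_invalid_df_errors(self):
        with pytest.raises(ValueError):
            st.effect_partial_r(1.0, 0)


def brute_force_bh(p, q=0.05):
    """Independent O(m^2) step-up: find the largest k with p_(k) <= k q / m."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    adj = np.empty(m)
    prev = 1.0
    for i in range(m - 1, -1, -1):
        prev = min(prev, p[order[i]] * m / (i + 1))
        adj[order[i]] = prev
    return adj, reject


class TestBhFdr:
    def test_single_small_p_rejected(self):
        out = st.bh_fdr([0.01])
        assert bool(out.reject.iloc[0])

    def test_four_ascending_all_rejected(self):
        out = st.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert out.reject.all()

    def test_all_ones_none_rejected(self):
        out = st.bh_fdr([1.0, 1.0, 1.0])
        assert not out.reject.any()
        assert (out.p_adjusted == 1.0).all()

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 8))
            p = np.round(rng.integers(0, 101, m) * 0.01, 2)
            out = st.bh_fdr(p)
            adj, rej = brute_force_bh(p)
            assert np.allclose(out.p_adjusted, adj, atol=1e-12)
            assert np.array_equal(out.reject, rej)

    def test_families_corrected_separately(self):
        p = [0.04, 0.9, 0.04, 0.9]
        fam = ["a", "a", "b", "b"]
        out = st.bh_fdr(p, families=fam)
        single = st.bh_fdr([0.04, 0.9])
        assert np.allclose(out.p_adjusted[:2], single.p_adjusted)

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            st.bh_fdr([0.5, 1.5])


class TestVif:
    def test_orthogonal_predictors_are_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(500, 3)), columns=list("abc"))
        assert (st.vif(X) < 1.1).all()

    def test_near_collinear_exceeds_five(self, rng):
        a = rng.normal(size=200)
        X = pd.DataFrame({"a": a, "b": a + rng.normal(0, 0.05, 200)})
        assert st.vif(X)["b"] > 5

    def test_exact_collinearity_reports_inf(self, rng):
        a = rng.normal(size=100)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        assert np.isinf(st.vif(X)["a"])
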