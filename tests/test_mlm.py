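"""Mixed-model likelihood exactness, fitting, ICs, LRT and Wald tests."""

import numpy as np
import pytest
from scipy import stats

from conftest import balanced_panel
from esmar import mlm
from esmar.dgp import ThreeLevelARParams, TwoLevelARParams, simulate_ar2, simulate_empty3
from esmar.lagging import build_predictors
from esmar.mlm import ConvergenceError, ModelSpec, fit, lrt, marginal_loglik, wald
from esmar.panel_io import StudyDesign


class TestModelSpec:
    @pytest.mark.parametrize(
        "family,correlated,k",
        [
            ("empty2", False, 3),
            ("empty3", False, 4),
            ("ar2", False, 5),
            ("ar2", True, 6),
            ("ar3_nobeta", False, 6),
            ("ar3_fixedbeta", False, 7),
            ("ar3_randombeta", False, 8),
            ("ar3_randombeta", True, 11),
            ("ar3_fixedonly", False, 6),
        ],
    )
    def test_parameter_counts(self, family, correlated, k):
        assert ModelSpec(family, correlated=correlated).k_params == k

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("ar9")

    def test_correlation_switch_restricted(self):
        with pytest.raises(ValueError):
            ModelSpec("empty3", correlated=True)


def _dense_loglik(df, mean, cov):
    ok = df["y"].notna()
    return float(
        stats.multivariate_normal.logpdf(df.loc[ok, "y"], mean=mean[ok.to_numpy()],
                                         cov=cov[np.ix_(ok.to_numpy(), ok.to_numpy())])
    )


class TestMarginalLoglik:
    def test_degenerate_random_effect_is_iid_normal(self):
        panel = balanced_panel(4, 2, 3)
        params = {"fixed": {"intercept": 20.0}, "sd": {"intercept": 0.0}, "sd_e": 5.0}
        ll = marginal_loglik(ModelSpec("empty2"), panel, params)
        expected = stats.norm.logpdf(panel.data["y"], 20.0, 5.0).sum()
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_matches_dense_mvn_oracle_empty3(self, small_3l_panel):
        df = small_3l_panel.data
        params = {"fixed": {"intercept": 49.0},
                  "sd": {"intercept": 7.5, "day": 4.0}, "sd_e": 11.0}
        ll = marginal_loglik(ModelSpec("empty3"), small_3l_panel, params)
        n = len(df)
        pid = df["person"].to_numpy()
        did = (df["person"].astype(str) + "_" + df["day"].astype(str)).to_numpy()
        cov = (7.5**2) * (pid[:, None] == pid[None, :]).astype(float)
        cov += (4.0**2) * (did[:, None] == did[None, :]).astype(float)
        cov += (11.0**2) * np.eye(n)
        assert ll == pytest.approx(_dense_loglik(df, np.full(n, 49.0), cov), abs=1e-8)

    def test_matches_dense_mvn_oracle_ar2_correlated(self, small_3l_lagged):
        df = small_3l_lagged.data
        params = {
            "fixed": {"intercept": 49.0, "lev1pred": 0.3},
            "sd": {"intercept": 7.0, "lev1pred": 0.12},
            "corr": {"intercept:lev1pred": -0.4},
            "sd_e": 10.5,
        }
        spec = ModelSpec("ar2", correlated=True)
        ll = marginal_loglik(spec, df, params)
        sub = df.dropna(subset=["y", "lev1pred"])
        n = len(sub)
        Z = np.column_stack([np.ones(n), sub["lev1pred"].to_numpy()])
        G = np.array([
            [7.0**2, -0.4 * 7.0 * 0.12],
            [-0.4 * 7.0 * 0.12, 0.12**2],
        ])
        pid = sub["person"].to_numpy()
        cov = (Z @ G @ Z.T) * (pid[:, None] == pid[None, :]) + 10.5**2 * np.eye(n)
        mean = 49.0 + 0.3 * sub["lev1pred"].to_numpy()
        expected = stats.multivariate_normal.logpdf(sub["y"], mean=mean, cov=cov)
        assert ll == pytest.approx(float(expected), abs=1e-8)

    def test_scale_equivariance(self, small_3l_panel):
        c = 3.7
        base = {"fixed": {"intercept": 49.0}, "sd": {"intercept": 7.5, "day": 4.0},
                "sd_e": 11.0}
        scaled = {"fixed": {"intercept": 49.0 * c},
                  "sd": {"intercept": 7.5 * c, "day": 4.0 * c}, "sd_e": 11.0 * c}
        ll = marginal_loglik(ModelSpec("empty3"), small_3l_panel, base)
        df = small_3l_panel.data.copy()
        df["y"] = df["y"] * c
        ll_c = marginal_loglik(ModelSpec("empty3"), df, scaled)
        n = df["y"].notna().sum()
        assert ll_c == pytest.approx(ll - n * np.log(c), abs=1e-8)


class TestFit:
    def test_empty3_recovers_dataset_a_parameters(self):
        panel = simulate_empty3(58.0, 12.3, 7.9, 15.0, StudyDesign(90, 21, 10),
                                np.random.default_rng(40))
        res = fit(ModelSpec("empty3"), panel)
        assert res.converged
        assert res.sds["day"] == pytest.approx(7.9, abs=0.5)
        assert res.sds["resid"] == pytest.approx(15.0, abs=0.3)
        assert res.sds["intercept"] == pytest.approx(12.3, abs=2.0)

    def test_ar2_recovers_study_parameters(self):
        params = TwoLevelARParams(58.0, 0.37, 12.0, 0.14, 15.0, -0.44)
        panel = simulate_ar2(params, StudyDesign(90, 14, 11), np.random.default_rng(41))
        lf = build_predictors(panel, three_level=False)
        res = fit(ModelSpec("ar2"), lf)
        assert res.fixed["lev1pred"] == pytest.approx(0.37, abs=0.03)
        assert res.sds["lev1pred"] == pytest.approx(0.14, abs=0.04)

    def test_constant_outcome_boundary(self):
        panel = balanced_panel(4, 2, 3, values=[5.0] * 24)
        res = fit(ModelSpec("empty2"), panel)
        assert res.fixed["intercept"] == pytest.approx(5.0, abs=1e-6)
        assert res.sds["intercept"] == pytest.approx(0.0, abs=1e-4)
        assert res.boundary

    def test_insufficient_cases_rejected(self):
        panel = balanced_panel(1, 1, 3)
        with pytest.raises(ValueError):
            fit(ModelSpec("empty2"), panel)

    def test_aic_bic_identities(self, small_3l_lagged):
        for spec in (ModelSpec("empty2"), ModelSpec("ar3_fixedbeta")):
            r = fit(spec, small_3l_lagged)
            assert r.aic == pytest.approx(2 * r.k_params - 2 * r.loglik)
            assert r.bic == pytest.approx(r.k_params * np.log(r.n_obs) - 2 * r.loglik)
            assert all(v >= 0 for v in r.sds.values())

    def test_loglik_monotone_under_nesting(self, small_3l_lagged):
        sub = small_3l_lagged.data.dropna(subset=["y", "lev1predfor3l", "lev2pred"])
        lls = [fit(ModelSpec(f), sub).loglik
               for f in ("ar3_nobeta", "ar3_fixedbeta", "ar3_randombeta")]
        assert lls[1] >= lls[0] - 1e-4
        assert lls[2] >= lls[1] - 1e-4

    def test_deterministic(self, small_3l_lagged):
        a = fit(ModelSpec("ar2"), small_3l_lagged)
        b = fit(ModelSpec("ar2"), small_3l_lagged)
        assert a.loglik == b.loglik and a.fixed == b.fixed


class TestStatsmodelsCrossCheck:
    """Spot agreement with an independent mixed-model implementation."""

    def test_empty2_and_ar2(self, small_3l_lagged):
        import statsmodels.formula.api as smf

        df = small_3l_lagged.data
        ours = fit(ModelSpec("empty2"), df)
        sm = smf.mixedlm("y ~ 1", df, groups=df["person"]).fit(reml=False)
        assert ours.loglik == pytest.approx(sm.llf, abs=1e-6)
        assert ours.fixed["intercept"] == pytest.approx(sm.fe_params.iloc[0], abs=1e-6)

        sub = df.dropna(subset=["y", "lev1pred"])
        ours2 = fit(ModelSpec("ar2", correlated=True), sub)
        sm2 = smf.mixedlm("y ~ 1 + lev1pred", sub, groups=sub["person"],
                          re_formula="1 + lev1pred").fit(reml=False, method="lbfgs",
                                                         maxiter=500)
        assert ours2.loglik >= sm2.llf - 1e-4


class TestTests:
    def test_lrt_identical_models(self, small_3l_lagged):
        a = fit(ModelSpec("ar2"), small_3l_lagged)
        chi2, df, p = lrt(a, a)
        assert (chi2, df, p) == (0.0, 0, 1.0)

    def test_lrt_correlation_df(self, small_3l_lagged):
        sub = small_3l_lagged.data.dropna(subset=["y", "lev1pred"])
        full = fit(ModelSpec("ar2", correlated=True), sub)
        constrained = fit(ModelSpec("ar2"), sub)
        chi2, df, p = lrt(full, constrained)
        assert df == 1
        assert chi2 >= -1e-9

    def test_lrt_df_from_parameter_counts(self, small_3l_lagged):
        sub = small_3l_lagged.data.dropna(subset=["y", "lev1predfor3l", "lev2pred"])
        full = fit(ModelSpec("ar3_randombeta"), sub)  # k = 8
        constrained = fit(ModelSpec("ar3_nobeta"), sub)  # k = 6
        assert lrt(full, constrained)[1] == 2

    def test_lrt_row_mismatch_rejected(self, small_3l_lagged):
        full = fit(ModelSpec("ar3_nobeta"), small_3l_lagged)
        other = fit(ModelSpec("empty2"), small_3l_lagged)
        with pytest.raises(ValueError):
            lrt(other, full)

    def test_wald(self, small_3l_lagged):
        r = fit(ModelSpec("ar2"), small_3l_lagged)
        z, p = wald(r, "lev1pred")
        assert z == pytest.approx(r.fixed["lev1pred"] / r.se["lev1pred"])
        assert 0 <= p <= 1

    def test_wald_z_magnitude(self):
        # direct arithmetic check: estimate 0.33, SE 0.02 -> z = 16.5
        fr = mlm.FitResult(
            spec=ModelSpec("ar2"), fixed={"lev1pred": 0.33}, se={"lev1pred": 0.02},
            sds={}, corrs={}, loglik=0.0, n_obs=10, k_params=5, aic=0.0, bic=0.0,
            eb_person=None, eb_day=None, converged=True, boundary=False,
        )
        z, p = wald(fr, "lev1pred")
        assert z == pytest.approx(16.5)
        assert p < 0.001

    def test_wald_degenerate_se(self):
        fr = mlm.FitResult(
            spec=ModelSpec("ar2"), fixed={"lev1pred": 0.1}, se={"lev1pred": 0.0},
            sds={}, corrs={}, loglik=0.0, n_obs=10, k_params=5, aic=0.0, bic=0.0,
            eb_person=None, eb_day=None, converged=True, boundary=False,
        )
        with pytest.raises(ConvergenceError):
            wald(fr, "lev1pred")
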