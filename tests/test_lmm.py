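import numpy as np
import pandas as pd
import pytest

from sociovar import (
    ModelSpec,
    SimulationConfig,
    build_design,
    compare_aic,
    fit,
    fit_gxe_models,
    profile_ci,
    simulate_cohort,
    variance_shares,
)
from sociovar.lmm import _Workspace, _round_half_away
from sociovar.lmm import test_indicator_association as indicator_association

from conftest import make_one_way, one_way_design


def dense_reml_neg2ll(design, theta, reml=True):
    """Brute-force criterion via the explicit marginal covariance
    V = sum(theta_t^2 Z_t Z_t') + I, profiled over beta and the residual
    variance.  Independent of the sparse penalized-least-squares path."""
    X, y = design.X, design.y
    n, p = X.shape
    V = np.eye(n)
    for t, Z in zip(theta, design.Z_blocks):
        Zd = Z.toarray()
        V += t**2 * Zd @ Zd.T
    _, logdetV = np.linalg.slogdet(V)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    r2 = r @ Vi @ r
    nu = n - p if reml else n
    val = logdetV + nu * (1.0 + np.log(2.0 * np.pi * r2 / nu))
    if reml:
        val += np.linalg.slogdet(XtViX)[1]
    return val


@pytest.fixture(scope="module")
def tiny_design():
    obs, _, _ = simulate_cohort(SimulationConfig(n_individuals=4, seed=7, missing_rate=0.3))
    obs = obs.iloc[:60]
    spec = ModelSpec()
    return build_design(obs, None, spec), spec


class TestBuildDesign:
    def test_crossed_block_column_counts(self):
        obs, _, _ = simulate_cohort(
            SimulationConfig(
                n_individuals=2,
                waves=(1997, 2001),
                indicators={"EAS-Sociability": (1997, 2001), "TCI-RD4-Dependence": (1997, 2001)},
                seed=0,
            )
        )
        design = build_design(obs, None, ModelSpec())
        assert [b.shape[1] for b in design.Z_blocks] == [2, 4, 4]

    def test_plain_blocks_have_one_unit_entry_per_row(self, tiny_design):
        design, _ = tiny_design
        for Z in design.Z_blocks:
            Zd = Z.toarray()
            assert np.all(Zd.sum(axis=1) == 1)
            assert np.all((Zd == 0) | (Zd == 1))

    def test_gxe_block_carries_covariate_values(self):
        obs, geno, _ = simulate_cohort(SimulationConfig(n_individuals=10, seed=2))
        spec = ModelSpec(
            fixed_terms=("intercept", "age", "gender", "wave", "risk_score"),
            gxe_terms=(("risk_score", "individual_wave"),),
        )
        design = build_design(obs, geno, spec)
        gxe = design.Z_blocks[-1].toarray()
        merged = obs.merge(geno[["individual_id", "risk_score"]], on="individual_id")
        assert np.allclose(gxe.sum(axis=1), merged["risk_score"].to_numpy())
        # all-zero covariate -> all-zero block
        geno0 = geno.copy()
        geno0["risk_score"] = 0.0
        design0 = build_design(obs, geno0, spec)
        assert design0.Z_blocks[-1].nnz == 0 or not design0.Z_blocks[-1].toarray().any()

    def test_missing_genotypes_dropped_with_count(self):
        obs, geno, _ = simulate_cohort(
            SimulationConfig(n_individuals=30, seed=3, genotype_missing_rate=0.3)
        )
        spec = ModelSpec(fixed_terms=("intercept", "age", "gender", "wave", "risk_score"))
        design = build_design(obs, geno, spec)
        n_missing_ids = geno["risk_score"].isna().sum()
        assert design.n_individuals == 30 - n_missing_ids
        assert design.n_dropped == len(obs) - design.X.shape[0] > 0

    def test_genotype_covariate_without_table_errors(self, small_cohort):
        obs, _, _ = small_cohort
        spec = ModelSpec(fixed_terms=("intercept", "risk_score"))
        with pytest.raises(ValueError, match="genotype"):
            build_design(obs, None, spec)

    def test_collinear_fixed_column_dropped_with_warning(self, small_cohort):
        obs, _, _ = small_cohort
        obs = obs.copy()
        obs["age2"] = obs["age"] * 2.0
        spec = ModelSpec(fixed_terms=("intercept", "age", "age2", "gender", "wave"))
        with pytest.warns(UserWarning, match="collinear"):
            design = build_design(obs, None, spec)
        assert "age2" not in design.fixed_names or "age" not in design.fixed_names


class TestCriterionAgainstDenseOracle:
    @pytest.mark.parametrize(
        "theta",
        [np.array([1.0, 1.0, 1.0]), np.array([0.5, 2.0, 0.1]), np.array([3.0, 0.01, 1.5])],
    )
    @pytest.mark.parametrize("reml", [True, False])
    def test_profiled_criterion_matches_dense(self, tiny_design, theta, reml):
        design, _ = tiny_design
        ws = _Workspace(design)
        sparse_val = ws.profiled_neg2ll(theta, reml=reml)
        dense_val = dense_reml_neg2ll(design, theta, reml=reml)
        assert sparse_val == pytest.approx(dense_val, abs=1e-8)

    def test_optimum_matches_dense_polish(self, tiny_design):
        from scipy import optimize

        design, spec = tiny_design
        res = fit(design, spec, n_restarts=3, seed=0)
        polished = optimize.minimize(
            lambda e: dense_reml_neg2ll(design, np.exp(e)),
            np.log(np.maximum(res._theta, 1e-6)),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        dense_theta = np.exp(polished.x)
        dense_vars = dense_theta**2 * res._sigma2
        for name, dv in zip(res.spec.random_terms, dense_vars):
            assert res.components.variances[name] == pytest.approx(dv, abs=1e-4)


class TestFit:
    def test_balanced_one_way_closed_form(self):
        df = pd.DataFrame(
            {
                "individual_id": [1, 1, 2, 2],
                "indicator": "a",
                "wave_year": [1997, 2001] * 2,
                "age": 0.0,
                "gender": 0,
                "score_std": [0.0, 2.0, 4.0, 6.0],
            }
        )
        design, spec = one_way_design(df)
        res = fit(design, spec, seed=0)
        assert res.components.variances["individual"] == pytest.approx(7.0, abs=1e-5)
        assert res.components.variances["residual"] == pytest.approx(2.0, abs=1e-5)

    def test_matches_statsmodels_on_one_way(self):
        import statsmodels.formula.api as smf

        df = make_one_way(99, n_groups=25, per_group=4)
        design, spec = one_way_design(df)
        res = fit(design, spec, seed=0)
        sm_fit = smf.mixedlm("score_std ~ 1", df, groups=df["individual_id"]).fit(reml=True)
        assert res.components.variances["individual"] == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), abs=1e-4
        )
        assert res.components.variances["residual"] == pytest.approx(
            float(sm_fit.scale), abs=1e-4
        )
        assert res.betas["estimate"].iloc[0] == pytest.approx(
            float(sm_fit.params["Intercept"]), abs=1e-5
        )

    def test_row_permutation_invariance(self, small_cohort, base_spec):
        obs, _, _ = small_cohort
        design = build_design(obs, None, base_spec)
        shuffled = obs.sample(frac=1.0, random_state=5).reset_index(drop=True)
        design_perm = build_design(shuffled, None, base_spec)
        # the profiled criterion itself is exactly row-order invariant
        theta = np.array([0.8, 1.1, 0.4])
        for reml in (True, False):
            c = _Workspace(design).profiled_neg2ll(theta, reml=reml)
            c_perm = _Workspace(design_perm).profiled_neg2ll(theta, reml=reml)
            assert c_perm == pytest.approx(c, abs=1e-10 * abs(c))
        # fitted quantities agree up to optimizer argmin resolution
        res = fit(design, base_spec, n_restarts=1, seed=0)
        res_perm = fit(design_perm, base_spec, n_restarts=1, seed=0)
        assert res_perm.loglik == pytest.approx(res.loglik, abs=1e-10 * abs(res.loglik))
        assert np.allclose(
            res_perm.betas["estimate"], res.betas["estimate"], atol=1e-6
        )
        for k, v in res.components.variances.items():
            assert res_perm.components.variances[k] == pytest.approx(v, abs=1e-6)

    def test_constant_response_degenerates_cleanly(self):
        df = pd.DataFrame(
            {
                "individual_id": [1, 1, 2, 2],
                "indicator": ["a", "b"] * 2,
                "wave_year": 1997,
                "age": 0.0,
                "gender": 0,
                "score_std": 4.2,
            }
        )
        spec = ModelSpec(fixed_terms=("intercept",), random_terms=("individual",))
        res = fit(build_design(df, None, spec), spec)
        assert all(v == 0.0 for v in res.components.variances.values())
        assert res.betas["estimate"].iloc[0] == pytest.approx(4.2)

    def test_too_few_observations_errors(self):
        df = make_one_way(0, n_groups=1, per_group=2)
        design, spec = one_way_design(df)
        with pytest.raises(ValueError, match="n_obs"):
            fit(design, spec)


class TestVarianceShares:
    def test_printed_model1_residual_share(self):
        comps = {"trait": 0.212, "indicator": 0.387, "state": 0.048, "residual": 0.298}
        shares = variance_shares(comps, decimals=1)
        assert shares["residual"] == 31.5

    def test_model2_share_includes_moderation_terms(self):
        comps = {
            "trait": 0.212, "indicator": 0.370, "state": 0.048, "residual": 0.298,
            "gxe_trait": 0.000, "gxe_indicator": 0.004, "gxe_state": 0.000,
        }
        assert variance_shares(comps, decimals=1)["indicator"] == 39.7

    def test_equal_components_symmetric(self):
        shares = variance_shares({c: 0.3 for c in "abcd"})
        assert all(s == pytest.approx(25.0) for s in shares.values())

    @pytest.mark.parametrize("decimals", [0, 1, 2])
    def test_shares_sum_to_100(self, decimals):
        rng = np.random.default_rng(3)
        for _ in range(20):
            comps = {f"c{i}": v for i, v in enumerate(rng.uniform(0, 2, size=5))}
            shares = variance_shares(comps, decimals=decimals)
            assert sum(shares.values()) == pytest.approx(100.0, abs=0.5 * 10.0**-decimals * 5)
            assert sum(variance_shares(comps).values()) == pytest.approx(100.0, abs=1e-9)

    def test_all_zero_signalled(self):
        with pytest.raises(ZeroDivisionError):
            variance_shares({"a": 0.0, "b": 0.0})

    def test_rounding_half_away_from_zero(self):
        assert _round_half_away(31.45, 1) == 31.5
        assert _round_half_away(22.5, 0) == 23.0
        assert _round_half_away(-22.5, 0) == -23.0


class TestCompareAic:
    def test_identical_models_tie_and_definition_holds(self, small_cohort, base_spec):
        obs, _, _ = small_cohort
        design = build_design(obs, None, base_spec)
        a = fit(design, base_spec, criterion="ml", n_restarts=1, seed=0)
        _, delta = compare_aic(a, a)
        assert delta == 0.0
        assert a.aic == pytest.approx(-2.0 * a.loglik + 2.0 * a.n_params)

    def test_noise_covariate_mostly_rejected(self):
        wins = 0
        for s in range(9):
            obs, _, _ = simulate_cohort(SimulationConfig(n_individuals=60, seed=500 + s))
            obs = obs.copy()
            obs["noise"] = np.random.default_rng(s).normal(size=len(obs))
            true_spec = ModelSpec()
            noisy_spec = ModelSpec(fixed_terms=("intercept", "age", "gender", "wave", "noise"))
            d_true = build_design(obs, None, true_spec)
            d_noisy = build_design(obs, None, noisy_spec)
            f_true = fit(d_true, true_spec, criterion="ml", n_restarts=1, seed=s)
            f_noisy = fit(d_noisy, noisy_spec, criterion="ml", n_restarts=1, seed=s)
            preferred, _ = compare_aic(f_true, f_noisy)
            wins += preferred is true_spec
        assert wins >= 5

    def test_requires_ml_and_identical_observations(self, small_cohort, base_spec):
        obs, _, _ = small_cohort
        design = build_design(obs, None, base_spec)
        reml_fit = fit(design, base_spec, criterion="reml", n_restarts=1, seed=0)
        with pytest.raises(ValueError, match="ML"):
            compare_aic(reml_fit, reml_fit)
        a = fit(design, base_spec, criterion="ml", n_restarts=1, seed=0)
        other = build_design(obs.iloc[:-10], None, base_spec)
        b = fit(other, base_spec, criterion="ml", n_restarts=1, seed=0)
        with pytest.raises(ValueError, match="incomparable"):
            compare_aic(a, b)


class TestProfileCI:
    def test_bounds_nonnegative_and_cover_estimate(self, small_cohort, base_spec):
        obs, _, _ = small_cohort
        res = fit(build_design(obs, None, base_spec), base_spec, n_restarts=1, seed=0)
        for comp in ("individual", "individual_wave", "residual"):
            lo, hi = profile_ci(res, comp)
            assert 0.0 <= lo <= res.components.variances[comp] <= hi

    def test_width_shrinks_with_sample_size(self):
        widths = {}
        for n in (30, 120):
            w = []
            for s in range(5):
                df = make_one_way(700 + s, n_groups=n, per_group=4)
                design, spec = one_way_design(df)
                res = fit(design, spec, n_restarts=1, seed=s)
                lo, hi = profile_ci(res, "individual")
                w.append(hi - lo)
            widths[n] = np.mean(w)
        assert widths[120] < widths[30]

    def test_bootstrap_interval_contains_estimate(self):
        df = make_one_way(42, n_groups=40, per_group=4)
        design, spec = one_way_design(df)
        res = fit(design, spec, n_restarts=1, seed=0)
        lo, hi = profile_ci(res, "individual", method="boot", n_boot=60, seed=1)
        assert 0.0 <= lo < hi
        assert lo <= res.components.variances["individual"] * 1.5


class TestGxeModels:
    def test_null_moderation_variances_near_zero(self):
        obs, geno, _ = simulate_cohort(SimulationConfig(n_individuals=150, seed=21))
        fits = fit_gxe_models(obs, geno, covariates=("risk_score",), n_restarts=1, seed=0)
        res = fits["risk_score"]
        for name, v in res.components.variances.items():
            if name.startswith("gxe_"):
                assert v < 0.01

    def test_carrier_only_indicator_variance_detected(self):
        cfg = SimulationConfig(
            n_individuals=250,
            seed=22,
            gxe=(("rs2254298_risk", "individual_indicator", 0.30),),
        )
        obs, geno, _ = simulate_cohort(cfg)
        fits = fit_gxe_models(obs, geno, covariates=("rs2254298_risk",), n_restarts=1, seed=0)
        v = fits["rs2254298_risk"].components.variances
        assert v["gxe_rs2254298_risk_individual_indicator"] > 0.1
        assert v["gxe_rs2254298_risk_individual"] < 0.05
        assert v["gxe_rs2254298_risk_individual_wave"] < 0.05

    def test_degenerate_covariate_skips_moderation(self):
        obs, geno, _ = simulate_cohort(SimulationConfig(n_individuals=40, seed=23))
        geno = geno.copy()
        geno["rs53576_risk"] = 1.0
        with pytest.warns(UserWarning, match="degenerate"):
            fits = fit_gxe_models(obs, geno, covariates=("rs53576_risk",), n_restarts=1)
        assert not any(
            n.startswith("gxe_") for n in fits["rs53576_risk"].components.variances
        )

    def test_sparse_covariate_skipped_when_below_threshold(self, caplog):
        obs, geno, _ = simulate_cohort(SimulationConfig(n_individuals=40, seed=24))
        geno = geno.copy()
        geno.loc[geno.index[:20], "risk_score"] = np.nan  # 50 % defined
        with caplog.at_level("WARNING", logger="sociovar"):
            fits = fit_gxe_models(obs, geno, covariates=("risk_score",), n_restarts=1)
        assert "risk_score" not in fits


class TestIndicatorAssociation:
    def test_deviations_sum_to_zero(self, small_cohort):
        obs, geno, _ = small_cohort
        a = indicator_association(obs, geno, "rs53576", "EAS-Sociability", n_restarts=1)
        ests = [est for est, _ in a.deviations.values()]
        assert sum(ests) == pytest.approx(0.0, abs=1e-12)
        assert a.ddf == a.n_obs - 5
        assert 0.0 <= a.p_value <= 1.0

    def test_targeted_effect_found_on_right_indicator(self):
        # inject an additive carrier effect on one indicator only
        hits = 0
        for s in range(5):
            obs, geno, _ = simulate_cohort(SimulationConfig(n_individuals=150, seed=600 + s))
            obs = obs.merge(geno[["individual_id", "rs3796863_risk"]], on="individual_id")
            target = obs["indicator"] == "TCI-RD1-Sentimentality"
            obs.loc[target, "score_std"] += 0.4 * obs.loc[target, "rs3796863_risk"]
            obs = obs.drop(columns="rs3796863_risk")
            fs = {
                ind: indicator_association(obs, geno, "rs3796863", ind, n_restarts=1).f_value
                for ind in obs["indicator"].unique()
            }
            hits += max(fs, key=fs.get) == "TCI-RD1-Sentimentality"
        assert hits >= 4

    def test_small_group_warning(self):
        obs, geno, _ = simulate_cohort(SimulationConfig(n_individuals=25, seed=9))
        geno = geno.copy()
        # force a near-empty risk group
        geno["rs2254298"] = ["AA"] * 24 + ["GG"]
        geno = geno.drop(columns=[c for c in geno.columns if c.endswith("_risk") or c == "risk_score"])
        from sociovar import code_genotype_frame

        geno = code_genotype_frame(geno)
        a = indicator_association(obs, geno, "rs2254298", "EAS-Sociability", n_restarts=1)
        assert any("individuals" in w for w in a.warnings)
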