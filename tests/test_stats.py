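import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy import stats as sps

from dazzletrack.stats import (
    FULL_TERMS,
    MAIN_EFFECTS,
    ModelSpec,
    build_design,
    fit_lmm,
    lrt,
    model_ladder,
    orthogonal_poly,
    tukey_posthoc,
    within_subject_ci,
)
from conftest import lmm_dataset


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def joint_loglik(beta, s2b, s2e, X, y, g, q):
    """Direct evaluation of the full joint Gaussian log-likelihood."""
    n = len(y)
    Z = np.zeros((n, q))
    Z[np.arange(n), g] = 1.0
    V = s2e * np.eye(n) + s2b * (Z @ Z.T)
    return sps.multivariate_normal(mean=X @ beta, cov=V).logpdf(y)


def brute_force_ml(X, y, g, q):
    """Generic-optimizer maximization of the joint likelihood (oracle)."""
    p = X.shape[1]
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    v0 = max(resid.var(), 1e-3)

    def neg(theta):
        return -joint_loglik(theta[:p], np.exp(theta[p]), np.exp(theta[p + 1]),
                             X, y, g, q)

    start = np.concatenate([beta0, [np.log(v0 / 2), np.log(v0 / 2)]])
    best = None
    for method in ("Nelder-Mead", "Powell"):
        res = optimize.minimize(neg, start, method=method,
                                options={"maxiter": 20000, "xatol": 1e-12,
                                         "fatol": 1e-12}
                                if method == "Nelder-Mead" else
                                {"maxiter": 20000, "xtol": 1e-12, "ftol": 1e-12})
        if best is None or res.fun < best:
            best = res.fun
    return -best


def balanced_oneway_ml(y, q, m):
    """Closed-form ML for the balanced one-way random-effects model.

    Interior solution: sigma_e^2 = SSW / (q(m-1)), tau = SSB/q with
    tau = sigma_e^2 + m sigma_b^2 evaluated around the grand mean.
    """
    y = y.reshape(q, m)
    gm = y.mean()
    group_means = y.mean(axis=1)
    ssw = ((y - group_means[:, None]) ** 2).sum()
    ssb = m * ((group_means - gm) ** 2).sum()
    s2e = ssw / (q * (m - 1))
    tau = ssb / q
    s2b = max((tau - s2e) / m, 0.0)
    return gm, s2b, s2e


# --------------------------------------------------------------------------
# orthogonal polynomial coding
# --------------------------------------------------------------------------

class TestOrthogonalPoly:
    X = np.repeat([1, 10, 20, 30, 40, 50, 60], 12)

    def test_columns_orthonormal_and_centred(self):
        P = orthogonal_poly(self.X, 2)
        assert abs(P[:, 0] @ P[:, 1]) < 1e-10
        assert np.allclose(np.linalg.norm(P, axis=0), 1.0)
        assert np.allclose(P.sum(axis=0), 0.0, atol=1e-10)

    def test_linear_column_matches_centred_x(self):
        P = orthogonal_poly(self.X, 1)
        r = np.corrcoef(P[:, 0], self.X - self.X.mean())[0, 1]
        assert abs(abs(r) - 1.0) < 1e-12
        assert r > 0  # sign convention: increasing with x

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            orthogonal_poly([5, 5, 5, 5], 1)
        with pytest.raises(ValueError):
            orthogonal_poly([1, 2, 1, 2], 2)

    def test_fit_invariant_to_raw_vs_orthogonal_coding(self, paper_cells):
        spec = ModelSpec(terms=MAIN_EFFECTS, poly_degree=2)
        a = fit_lmm(paper_cells, spec, raw_poly=False)
        b = fit_lmm(paper_cells, spec, raw_poly=True)
        assert abs(a.loglik - b.loglik) < 1e-8


# --------------------------------------------------------------------------
# profiled-ML fitting
# --------------------------------------------------------------------------

class TestFitLmm:
    def test_matches_balanced_oneway_closed_form(self, rng):
        q, m = 6, 8
        y = (1.5 + 0.8 * rng.normal(size=q).repeat(m) + 0.5 * rng.normal(size=q * m))
        data = pd.DataFrame({"participant": np.repeat(np.arange(q), m),
                             "log_error": y})
        fit = fit_lmm(data, X=np.ones((q * m, 1)), names=["(Intercept)"])
        mu, s2b, s2e = balanced_oneway_ml(y, q, m)
        assert fit.params[0] == pytest.approx(mu, abs=1e-8)
        assert fit.var_participant == pytest.approx(s2b, rel=1e-5)
        assert fit.var_resid == pytest.approx(s2e, rel=1e-5)

    def test_matches_brute_force_joint_likelihood(self):
        # 20 random small datasets: profiled fit vs generic-optimizer
        # maximization of the same joint Gaussian likelihood.
        rng = np.random.default_rng(77)
        for _ in range(20):
            data, X, names = lmm_dataset(rng, n_groups=6, per_group=6)
            fit = fit_lmm(data, X=X, names=names)
            g = data["participant"].to_numpy()
            oracle = brute_force_ml(X, data["log_error"].to_numpy(), g, 6)
            assert fit.loglik >= oracle - 1e-6
            assert abs(fit.loglik - oracle) < 1e-5

    def test_zero_variance_ratio_reduces_to_ols(self, rng):
        data, X, names = lmm_dataset(rng)
        fit = fit_lmm(data, X=X, names=names, var_ratio=0.0)
        y = data["log_error"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = ((y - X @ beta) ** 2).sum()
        n = len(y)
        ols_loglik = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
        assert fit.loglik == pytest.approx(ols_loglik, abs=1e-10)
        assert fit.singular and fit.var_participant == 0.0

    def test_matches_statsmodels_mixedlm(self, paper_cells):
        import statsmodels.api as sm

        spec = ModelSpec(terms=MAIN_EFFECTS, poly_degree=2)
        fit = fit_lmm(paper_cells, spec)
        X, _ = build_design(paper_cells, spec)
        ref = sm.MixedLM(paper_cells["log_error"].to_numpy(), X,
                         groups=paper_cells["participant"]).fit(reml=False)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)
        assert np.allclose(fit.params, ref.fe_params, atol=1e-4)

    def test_aic_identity(self, paper_cells):
        fit = fit_lmm(paper_cells, ModelSpec(terms=MAIN_EFFECTS))
        assert fit.aic == -2.0 * fit.loglik + 2.0 * fit.n_params

    def test_degenerate_inputs_rejected(self, rng):
        data, X, names = lmm_dataset(rng)
        with pytest.raises(ValueError, match="participants"):
            fit_lmm(data.assign(participant=0), X=X, names=names)
        with pytest.raises(ValueError):
            fit_lmm(data.iloc[:3], X=X[:3], names=names)
        with pytest.raises(ValueError):
            fit_lmm(data)  # neither spec nor design


# --------------------------------------------------------------------------
# likelihood-ratio tests
# --------------------------------------------------------------------------

class TestLrt:
    def test_identical_models_give_chi2_zero_p_one(self, rng):
        data, X, names = lmm_dataset(rng)
        fit = fit_lmm(data, X=X, names=names)
        res = lrt(fit, fit)
        assert res.chi2 == 0.0 and res.p == 1.0 and res.df == 0

    def test_chi2_invariant_to_affine_predictor_recoding(self, rng):
        data, X, names = lmm_dataset(rng, n_covariates=1)
        X2 = X.copy()
        X2[:, 1] = 2.0 * X2[:, 1] + 3.0
        red = fit_lmm(data, X=X[:, :1], names=names[:1])
        a = lrt(fit_lmm(data, X=X, names=names), red)
        b = lrt(fit_lmm(data, X=X2, names=names), red)
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-8)
        assert a.df == b.df == 1

    def test_non_nested_rejected(self, rng):
        data, X, names = lmm_dataset(rng, n_covariates=1)
        a = fit_lmm(data, X=X, names=["(Intercept)", "a"])
        b = fit_lmm(data, X=X[:, :1], names=["b"])
        with pytest.raises(ValueError, match="nested"):
            lrt(a, b)

    def test_mismatched_rows_rejected(self, rng):
        data, X, names = lmm_dataset(rng)
        a = fit_lmm(data, X=X, names=names)
        b = fit_lmm(data.iloc[:-6], X=X[:-6], names=names)
        with pytest.raises(ValueError, match="rows"):
            lrt(a, b)


class TestModelLadder:
    def test_df_sequence_matches_design(self, paper_cells):
        ladder, fits = model_ladder(paper_cells)
        assert ladder["df"].tolist() == [6, 4, 2, 2, 4, 2, 2, 1]
        assert (ladder["chi2"] >= 0).all()
        assert ladder["label"].iloc[0] == "number quadratic vs linear"
        for f in fits.values():
            assert f.aic == -2 * f.loglik + 2 * f.n_params

    def test_recovers_injected_effects(self, paper_cells):
        # The generator injects a coloration ordering and a strong group-
        # size effect but no contrast effect; the ladder should agree.
        ladder, _ = model_ladder(paper_cells)
        p = dict(zip(ladder["label"], ladder["p"]))
        assert p["coloration main effect"] < 0.01
        assert p["number main effect"] < 0.01
        assert p["contrast main effect"] > 0.05

    def test_trial_level_granularity_runs(self, paper_trials):
        from dazzletrack.metrics import trial_log_table

        ladder, _ = model_ladder(trial_log_table(paper_trials))
        assert ladder["df"].tolist() == [6, 4, 2, 2, 4, 2, 2, 1]
        assert dict(zip(ladder["label"], ladder["p"]))["coloration main effect"] < 0.01


# --------------------------------------------------------------------------
# post hoc contrasts
# --------------------------------------------------------------------------

def null_cells(rng, effect=0.0):
    rows = []
    for p in range(14):
        off = 0.2 * rng.normal()
        for c in ("binary", "orthogonal", "parallel"):
            for k in ("high", "low"):
                for s in (1, 10, 20, 30, 40, 50, 60):
                    mu = off + 0.01 * s + (effect if c == "parallel" else 0.0)
                    rows.append({"participant": f"P{p:02d}", "coloration": c,
                                 "contrast": k, "set_size": s,
                                 "log_error": mu + 0.3 * rng.normal()})
    return pd.DataFrame(rows)


class TestTukeyPosthoc:
    def test_three_contrasts_with_sane_adjustment(self, paper_cells):
        _, fits = model_ladder(paper_cells)
        res = tukey_posthoc(fits["main_effects"])
        assert [c.label for c in res] == ["orthogonal - binary",
                                          "parallel - binary",
                                          "parallel - orthogonal"]
        for c in res:
            assert c.z == pytest.approx(c.estimate / c.se)
            assert c.p_adjusted >= c.p_unadjusted - 1e-12
            assert c.p_adjusted <= min(1.0, 3 * c.p_unadjusted) + 1e-6

    def test_null_factor_gives_small_z(self, rng):
        fit = fit_lmm(null_cells(rng), ModelSpec(terms=MAIN_EFFECTS))
        res = tukey_posthoc(fit)
        assert all(abs(c.z) < 3 for c in res)

    def test_injected_effect_detected_with_correct_sign(self, rng):
        fit = fit_lmm(null_cells(rng, effect=0.3), ModelSpec(terms=MAIN_EFFECTS))
        res = {c.label: c for c in tukey_posthoc(fit)}
        assert res["parallel - binary"].z > 3
        assert res["parallel - binary"].p_adjusted < 0.01

    def test_missing_factor_rejected(self, rng):
        fit = fit_lmm(null_cells(rng), ModelSpec(terms=("N", "K")))
        with pytest.raises(ValueError, match="coloration"):
            tukey_posthoc(fit)

    def test_adjustment_is_deterministic(self, paper_cells):
        _, fits = model_ladder(paper_cells)
        a = tukey_posthoc(fits["main_effects"])
        b = tukey_posthoc(fits["main_effects"])
        assert [c.p_adjusted for c in a] == [c.p_adjusted for c in b]


# --------------------------------------------------------------------------
# within-subject confidence intervals
# --------------------------------------------------------------------------

class TestWithinSubjectCI:
    def grid(self, values):
        rows = []
        for p, off in enumerate(values):
            for c in ("binary", "parallel"):
                for s in (1, 10):
                    rows.append({"participant": p, "coloration": c,
                                 "contrast": "high", "set_size": s,
                                 "mean_error_px": off + (s == 10) * 2.0
                                 + (c == "parallel") * 1.0})
        return pd.DataFrame(rows)

    def test_identical_participants_give_zero_halfwidth(self):
        ci = within_subject_ci(self.grid([5.0, 5.0, 5.0, 5.0]))
        assert np.allclose(ci["ci_halfwidth"], 0.0)

    def test_additive_offsets_removed(self):
        # Same within-participant pattern, wildly different offsets:
        # normalization leaves identical half-widths.
        base = self.grid([5.0, 5.1, 4.9, 5.05])
        shifted = base.copy()
        shifted["mean_error_px"] += shifted["participant"].map(
            {0: 0.0, 1: 100.0, 2: 200.0, 3: 1000.0})
        a = within_subject_ci(base)["ci_halfwidth"]
        b = within_subject_ci(shifted)["ci_halfwidth"]
        assert np.allclose(a, b)

    def test_single_condition_rejected(self):
        df = self.grid([1.0, 2.0])
        df = df[(df.coloration == "binary") & (df.set_size == 1)]
        with pytest.raises(ValueError, match="single condition"):
            within_subject_ci(df)

    def test_incomplete_cells_rejected(self):
        df = self.grid([1.0, 2.0, 3.0]).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            within_subject_ci(df)

    def test_paper_design_shape(self, paper_cells):
        ci = within_subject_ci(paper_cells)
        assert len(ci) == 42
        assert (ci["ci_halfwidth"] > 0).all()
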