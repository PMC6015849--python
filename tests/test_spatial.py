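"""Spatial realm mixed model: scaling, subsampling, correlation structures,
REML against closed forms and a frozen nlme oracle, simultaneous intervals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichetime import spatial as sp
from nichetime.synthdata import simulate_assemblage_scenario


# ---------------------------------------------------------------------------
# scaling and subsampling
# ---------------------------------------------------------------------------

def test_zscore_basic():
    z, (mu, sd) = sp.zscore([1.0, 2.0, 3.0])
    assert mu == 2.0 and sd == 1.0
    assert np.allclose(z, [-1.0, 0.0, 1.0])
    z2, _ = sp.zscore(z)
    assert np.allclose(z2, z, atol=1e-12)
    with pytest.raises(ValueError, match="constant"):
        sp.zscore(np.ones(5))


def test_subsample_by_realm():
    df = pd.DataFrame({"realm": ["a"] * 10 + ["b"] * 5,
                       "v": np.arange(15)})
    assert len(sp.subsample_by_realm(df, 1.0, seed=0)) == 15
    sub = sp.subsample_by_realm(df, 0.4, seed=0)
    assert (sub["realm"] == "a").sum() == 4  # round(0.4 * 10)
    assert (sub["realm"] == "b").sum() == 2
    again = sp.subsample_by_realm(df, 0.4, seed=0)
    assert list(sub.index) == list(again.index)
    other = sp.subsample_by_realm(df, 0.4, seed=1)
    assert list(sub.index) != list(other.index)
    with pytest.raises(ValueError, match="fraction"):
        sp.subsample_by_realm(df, 0.0, seed=0)


# ---------------------------------------------------------------------------
# correlation structures
# ---------------------------------------------------------------------------

def test_correlation_matrix_values():
    D = np.array([[0.0, 100.0], [100.0, 0.0]])
    R = sp.correlation_matrix(D, "exponential", range_=100.0, nugget=0.0)
    assert R[0, 0] == 1.0
    assert R[0, 1] == pytest.approx(np.exp(-1.0))
    R = sp.correlation_matrix(D, "exponential", range_=100.0, nugget=1.0)
    assert np.allclose(R, np.eye(2))  # pure nugget
    R = sp.correlation_matrix(D, "none")
    assert np.allclose(R, np.eye(2))


def test_correlation_matrix_guards():
    D = np.array([[0.0, 1.0], [1.0, 0.0]])
    with pytest.raises(ValueError, match="range"):
        sp.correlation_matrix(D, "exponential", range_=0.0)
    with pytest.raises(ValueError, match="nugget"):
        sp.correlation_matrix(D, "exponential", range_=1.0, nugget=1.5)
    with pytest.raises(ValueError, match="unknown"):
        sp.correlation_matrix(D, "cauchy", range_=1.0)
    with pytest.raises(ValueError, match="diagonal"):
        sp.correlation_matrix(np.ones((2, 2)), "exponential", range_=1.0)


def test_correlation_matrices_positive_semidefinite(rng):
    pts = rng.uniform(0, 1000, (30, 2))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    for family in ("exponential", "gaussian", "spherical"):
        for range_ in (50.0, 300.0, 2000.0):
            for c in (0.0, 0.3, 0.9):
                R = sp.correlation_matrix(D, family, range_, c)
                assert np.allclose(R, R.T)
                assert np.linalg.eigvalsh(R).min() > -1e-9


# ---------------------------------------------------------------------------
# REML/GLS against closed forms
# ---------------------------------------------------------------------------

def test_pure_nugget_no_re_equals_ols():
    df = simulate_assemblage_scenario(21, n_realms=2, cells_per_realm=49,
                                      realm_intercept_sd=0.0, realm_slope_sd=0.0,
                                      nugget=1.0)
    m = sp.SpatialRichnessModel(df, "response",
                                ["interference", "exploitation", "time_length"],
                                random_slope=None, random_intercept=False,
                                correlation="none", nugget=False,
                                scale=False, scale_response=False)
    res = m.fit(method="ML", n_starts=1)
    X = np.column_stack([np.ones(len(df)),
                         df[["interference", "exploitation",
                             "time_length"]].to_numpy()])
    y = df["response"].to_numpy()
    beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(res.params, beta_ols, atol=1e-8)


def test_single_realm_fixed_params_matches_gls_algebra():
    """With variance parameters held fixed, beta must equal the direct GLS
    solve with the same covariance."""
    df = simulate_assemblage_scenario(22, n_realms=1, cells_per_realm=36,
                                      realm_intercept_sd=0.0, realm_slope_sd=0.0,
                                      rho=250.0, nugget=0.2)
    m = sp.SpatialRichnessModel(df, "response",
                                ["interference", "exploitation", "time_length"],
                                random_slope=None, random_intercept=False,
                                correlation="exponential", nugget=True,
                                scale=False, scale_response=False)
    rho, c = 300.0, 0.25
    theta = np.array([np.log(rho), np.log(c / (1 - c))])
    _, beta, _, _, _ = m._profile(theta, reml=True)
    xy = df[["x", "y"]].to_numpy()
    D = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
    V = sp.correlation_matrix(D, "exponential", rho, c)
    X = np.column_stack([np.ones(len(df)),
                         df[["interference", "exploitation",
                             "time_length"]].to_numpy()])
    y = df["response"].to_numpy()
    Vi = np.linalg.inv(V)
    beta_direct = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    assert np.allclose(beta, beta_direct, atol=1e-8)


# Frozen outputs of R nlme (gls/lme with corExp + nugget, REML) on the
# deterministic fixtures below — the independent reference implementation.
NLME_GLS = {  # simulate_assemblage_scenario(11, 1 realm, 64 cells, no RE)
    "beta": [-0.1937262, 0.4000493, 0.2469536, -0.2047678],
    "se": [0.4743545, 0.08739292, 0.08485975, 0.09103616],
    "loglik": -77.74877, "range": 331.4855502, "nugget": 0.2037605,
    "sigma2": 1.09461,
}
NLME_LMM = {  # simulate_assemblage_scenario(12, 3 realms, 49 cells, RE 0.4/0.3)
    "beta": [-0.1672811, 0.4310081, 0.343423, -0.2029253],
    "se": [0.7475588, 0.05188382, 0.3820145, 0.04977005],
    "loglik": -167.8055,
}


def test_gls_matches_nlme_oracle():
    df = simulate_assemblage_scenario(11, n_realms=1, cells_per_realm=64,
                                      realm_intercept_sd=0.0,
                                      realm_slope_sd=0.0, rho=250.0, nugget=0.2)
    m = sp.SpatialRichnessModel(df, "response",
                                ["interference", "exploitation", "time_length"],
                                random_slope=None, random_intercept=False,
                                scale=False, scale_response=False,
                                correlation="exponential", nugget=True)
    res = m.fit(method="REML", n_starts=3)
    assert np.allclose(res.params, NLME_GLS["beta"], atol=1e-5)
    assert np.allclose(res.bse, NLME_GLS["se"], atol=1e-5)
    assert res.loglik == pytest.approx(NLME_GLS["loglik"], abs=1e-4)
    assert res.rho == pytest.approx(NLME_GLS["range"], rel=1e-3)
    assert res.nugget == pytest.approx(NLME_GLS["nugget"], rel=1e-3)
    assert res.sigma2 == pytest.approx(NLME_GLS["sigma2"], rel=1e-3)


def test_lmm_matches_nlme_oracle():
    df = simulate_assemblage_scenario(12, n_realms=3, cells_per_realm=49,
                                      realm_intercept_sd=0.4,
                                      realm_slope_sd=0.3, rho=250.0, nugget=0.2)
    m = sp.SpatialRichnessModel(df, "response",
                                ["interference", "exploitation", "time_length"],
                                random_slope="exploitation",
                                scale=False, scale_response=False,
                                correlation="exponential", nugget=True)
    res = m.fit(method="REML", n_starts=3)
    assert np.allclose(res.params, NLME_LMM["beta"], atol=2e-3)
    assert np.allclose(res.bse, NLME_LMM["se"], rtol=5e-3)
    # our optimum must be at least as good as the reference's
    assert res.loglik >= NLME_LMM["loglik"] - 0.01


def test_reml_optimum_beats_truth(rng):
    df = simulate_assemblage_scenario(23)
    m = sp.SpatialRichnessModel(df, "response",
                                ["interference", "exploitation", "time_length"],
                                random_slope="exploitation",
                                scale=False, scale_response=False)
    res = m.fit(n_starts=1)
    true = df.attrs["true"]
    theta_true = np.array([
        np.log(true["rho"]), np.log(true["nugget"] / (1 - true["nugget"])),
        np.log(true["realm_intercept_sd"]), 0.0,
        np.log(true["realm_slope_sd"]),
    ])
    assert res.loglik >= -0.5 * m._neg2crit(theta_true, True) - 1e-6


def test_fit_invariant_to_affine_predictor_transforms():
    df = simulate_assemblage_scenario(24, n_realms=2, cells_per_realm=49)
    kwargs = dict(random_slope="exploitation", correlation="exponential",
                  nugget=True)
    fe = ["interference", "exploitation", "time_length"]
    res1 = sp.SpatialRichnessModel(df, "response", fe, **kwargs).fit(n_starts=1)
    df2 = df.copy()
    df2["interference"] = df2["interference"] * 7.0 - 3.0
    df2["exploitation"] = df2["exploitation"] / 5.0 + 100.0
    res2 = sp.SpatialRichnessModel(df2, "response", fe, **kwargs).fit(n_starts=1)
    assert np.allclose(res1.params, res2.params, atol=1e-5)


def test_model_guards():
    df = simulate_assemblage_scenario(25, n_realms=1, cells_per_realm=36)
    with pytest.raises(ValueError, match="2 realms"):
        sp.SpatialRichnessModel(df, "response", ["interference"],
                                random_slope=None)
    with pytest.raises(ValueError, match="correlation"):
        sp.SpatialRichnessModel(df, "response", ["interference"],
                                correlation="cauchy")
    df2 = df.copy()
    df2["dup"] = df2["interference"]
    with pytest.raises(ValueError, match="rank deficient"):
        sp.SpatialRichnessModel(df2, "response", ["interference", "dup"],
                                random_intercept=False, scale=False)


# ---------------------------------------------------------------------------
# simultaneous confidence intervals
# ---------------------------------------------------------------------------

def test_simultaneous_critical_single_coefficient():
    crit = sp.simultaneous_critical_value(np.array([[2.0]]), seed=0)
    assert crit == pytest.approx(stats.norm.ppf(0.975), abs=1e-6)


def test_simultaneous_critical_independent_matches_sidak():
    crit = sp.simultaneous_critical_value(np.eye(3), n_draws=400_000, seed=1)
    sidak = stats.norm.ppf(0.5 + 0.95 ** (1 / 3) / 2)
    assert crit == pytest.approx(sidak, abs=0.01)


def test_simultaneous_critical_perfect_correlation_collapses():
    cov = np.full((4, 4), 1.0)
    crit = sp.simultaneous_critical_value(cov, n_draws=200_000, seed=2)
    assert crit == pytest.approx(stats.norm.ppf(0.975), abs=0.02)


def test_simultaneous_ci_contains_wald():
    df = simulate_assemblage_scenario(26, n_realms=2, cells_per_realm=49)
    res = sp.SpatialRichnessModel(
        df, "response", ["interference", "exploitation", "time_length"],
        random_slope="exploitation").fit(n_starts=1)
    simul = res.simultaneous_ci(seed=3)
    wald = res.conf_int()
    assert (simul["lower"] <= wald["lower"] + 1e-9).all()
    assert (simul["upper"] >= wald["upper"] - 1e-9).all()
    assert (simul["lower"] <= res.params).all()
    assert (simul["upper"] >= res.params).all()


# ---------------------------------------------------------------------------
# structure comparison
# ---------------------------------------------------------------------------

def test_compare_structures_identical_variants_tie():
    df = simulate_assemblage_scenario(27, n_realms=2, cells_per_realm=36)
    tab = sp.compare_structures(
        df, "response", ["interference", "exploitation", "time_length"],
        variants=(("exponential", True), ("exponential", True)),
        random_slope="exploitation", n_starts=1)
    assert tab["AIC"].iloc[0] == pytest.approx(tab["AIC"].iloc[1], abs=1e-6)


def test_compare_structures_extra_params_cost_on_independent_data():
    """On spatially independent data the spatial variants pay their AIC
    penalty: the none-structure should win most of the time."""
    wins = 0
    for rep in range(10):
        df = simulate_assemblage_scenario(400 + rep, n_realms=2,
                                          cells_per_realm=36, nugget=1.0,
                                          realm_intercept_sd=0.0,
                                          realm_slope_sd=0.0)
        tab = sp.compare_structures(
            df, "response", ["interference", "exploitation", "time_length"],
            variants=(("none", False), ("exponential", True)),
            random_slope=None, random_intercept=False, n_starts=1)
        if tab["family"].iloc[0] == "none":
            wins += 1
        # AIC difference is bounded by twice the parameter-count difference
        d = tab.set_index("family")
        # extra params cannot raise AIC by more than their penalty
        # (small slack for optimizer termination noise)
        assert (d.loc["exponential", "AIC"] - d.loc["none", "AIC"]) <= \
            2 * (d.loc["exponential", "k"] - d.loc["none", "k"]) + 0.01
    assert wins >= 6
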