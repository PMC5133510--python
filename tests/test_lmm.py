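"""Null-model REML fitting and score statistics.

The REML path (eigendecomposition + 1-D heritability profile) is
checked against an independent dense restricted-likelihood evaluation,
against ordinary least squares in the unrelated-cohort degenerate case,
and against Monte-Carlo null calibration of the scores.
"""

import numpy as np
import pytest

from pathstep import CohortConfig, FamilialLMM, compute_kinship, \
    simulate_pedigrees
from pathstep.lmm import _profile_reml_ll


def dense_restricted_loglik(h2, y, X, phi2):
    """Independent REML evaluation by dense solves (no rotation)."""
    n, p = X.shape
    D = h2 * phi2 + (1 - h2) * np.eye(n)
    Dinv = np.linalg.inv(D)
    XtDX = X.T @ Dinv @ X
    beta = np.linalg.solve(XtDX, X.T @ Dinv @ y)
    r = y - X @ beta
    s2 = float(r @ Dinv @ r) / (n - p)
    sign, logdet_d = np.linalg.slogdet(D)
    sign2, logdet_x = np.linalg.slogdet(XtDX)
    return -0.5 * ((n - p) * (np.log(s2) + 1) + logdet_d + logdet_x)


@pytest.fixture(scope="module")
def family_data():
    cfg = CohortConfig(seed=5, n_families=10)
    ped = simulate_pedigrees(cfg)
    kin = compute_kinship(ped)
    rng = np.random.default_rng(9)
    n = ped.n
    X = np.column_stack([np.ones(n), rng.standard_normal(n),
                         rng.binomial(1, 0.5, n)])
    y = X @ [3.0, 1.0, -0.5] + \
        np.sqrt(6.0) * (kin.chol2() @ rng.standard_normal(n)) + \
        np.sqrt(4.0) * rng.standard_normal(n)
    return ped, kin, X, y


def test_unrelated_cohort_reduces_to_ols():
    rng = np.random.default_rng(2)
    n = 150
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = X @ [1.0, 2.0] + rng.standard_normal(n)
    with pytest.warns(UserWarning, match="unidentifiable"):
        res = FamilialLMM(y, X, 0.5 * np.eye(n)).fit()
    # OLS coefficients and residual variance
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(res.params, beta_ols, atol=1e-10)
    assert res.h2 == 0.0
    r = y - X @ beta_ols
    assert res.sigma2 == pytest.approx(float(r @ r) / (n - 2), rel=1e-10)


def test_reml_matches_dense_oracle_on_grid(family_data):
    ped, kin, X, y = family_data
    res = FamilialLMM(y, X, kin).fit()
    grid = np.linspace(0.0, 0.99, 34)
    dense = [dense_restricted_loglik(h, y, X, kin.phi2) for h in grid]
    # profile path equals the dense evaluation pointwise...
    lam, Q = kin.eig()
    rotated = [_profile_reml_ll(h, lam, Q.T @ y, Q.T @ X)[0] for h in grid]
    np.testing.assert_allclose(rotated, dense, rtol=1e-8)
    # ...and the optimiser beats every grid point
    assert res.reml_loglik >= max(dense) - 1e-7


def test_reml_optimum_is_local_max(family_data):
    ped, kin, X, y = family_data
    res = FamilialLMM(y, X, kin).fit()
    lam, Q = kin.eig()
    yt, Xt = Q.T @ y, Q.T @ X
    at_opt = _profile_reml_ll(res.h2, lam, yt, Xt)[0]
    for dh in (-0.01, 0.01):
        h = res.h2 + dh
        if 0.0 <= h < 1.0:
            assert _profile_reml_ll(h, lam, yt, Xt)[0] <= at_opt + 1e-10


def test_vinverse_contract_and_residual_orthogonality(family_data):
    ped, kin, X, y = family_data
    res = FamilialLMM(y, X, kin).fit()
    n = ped.n
    V = res.sigma2_g * kin.phi2 + res.sigma2_e * np.eye(n)
    np.testing.assert_allclose(res.solve_v(V), np.eye(n), atol=1e-8)
    # GLS residuals orthogonal to X under the V^-1 inner product
    np.testing.assert_allclose(X.T @ res.solve_v(res.resid),
                               0.0, atol=1e-8)


def test_rotation_equals_dense_solve(family_data):
    ped, kin, X, y = family_data
    res = FamilialLMM(y, X, kin).fit()
    V = res.sigma2_g * kin.phi2 + res.sigma2_e * np.eye(ped.n)
    b = np.linalg.solve(V, y)
    np.testing.assert_allclose(res.solve_v(y), b, atol=1e-6)


def test_rank_deficient_design_names_columns():
    n = 50
    X = np.column_stack([np.ones(n), np.arange(n), 2.0 * np.arange(n)])
    with pytest.raises(ValueError, match="rank deficient"):
        FamilialLMM(np.zeros(n), X, 0.5 * np.eye(n),
                    exog_names=["intercept", "a", "a_times_two"])


def test_misaligned_genotype_ids_rejected(family_data):
    ped, kin, X, y = family_data
    res = FamilialLMM(y, X, kin, ids=ped.ids).fit()
    with pytest.raises(ValueError, match="missing individual"):
        res.score_statistics(np.zeros((ped.n, 1)),
                             ids=["nobody"] * ped.n)


def test_monomorphic_variant_zero_score(family_data):
    ped, kin, X, y = family_data
    res = FamilialLMM(y, X, kin).fit()
    G = np.column_stack([np.random.default_rng(0).binomial(2, 0.2, ped.n),
                         np.full(ped.n, 2.0)])
    U, C = res.score_statistics(G)
    assert abs(U[1]) < 1e-8
    np.testing.assert_allclose(C[1, :], 0.0, atol=1e-8)


def test_single_variant_score_matches_classical(family_data):
    """With unrelated individuals the score test is the OLS score test."""
    rng = np.random.default_rng(4)
    n = 300
    g = rng.binomial(2, 0.25, n).astype(float)
    y = 1.0 + rng.standard_normal(n)
    with pytest.warns(UserWarning):
        res = FamilialLMM(y, np.ones((n, 1)), 0.5 * np.eye(n)).fit()
    U, C = res.score_statistics(g)
    gc = g - g.mean()
    u_ols = float(gc @ (y - y.mean())) / res.sigma2
    v_ols = float(gc @ gc) / res.sigma2
    assert U[0] == pytest.approx(u_ols, rel=1e-10)
    assert C[0, 0] == pytest.approx(v_ols, rel=1e-10)


def test_scores_calibrated_under_null(family_data):
    """E[U] = 0 and var(U_j) = C_jj over simulated null phenotypes."""
    ped, kin, X, _ = family_data
    rng = np.random.default_rng(8)
    n = ped.n
    G = rng.binomial(2, rng.uniform(0.05, 0.4, 5), size=(n, 5)).astype(float)
    L = kin.chol2()
    s2g, s2e = 6.0, 4.0
    n_reps = 500
    Us, Cs = [], []
    for _ in range(n_reps):
        y = X @ [3.0, 1.0, -0.5] + np.sqrt(s2g) * (L @ rng.standard_normal(n)) \
            + np.sqrt(s2e) * rng.standard_normal(n)
        res = FamilialLMM(y, X, kin).fit()
        U, C = res.score_statistics(G)
        Us.append(U)
        Cs.append(np.diag(C))
    Us, Cs = np.array(Us), np.array(Cs)
    mean_se = Us.std(axis=0) / np.sqrt(n_reps)
    assert np.all(np.abs(Us.mean(axis=0)) <= 4 * mean_se)
    ratio = Us.var(axis=0) / Cs.mean(axis=0)
    # var of a variance estimate ~ sqrt(2/n) relative
    assert np.all(np.abs(ratio - 1) <= 4 * np.sqrt(2.0 / n_reps))


def test_missing_genotypes_mean_imputed(family_data):
    ped, kin, X, y = family_data
    res = FamilialLMM(y, X, kin).fit()
    rng = np.random.default_rng(3)
    g = rng.binomial(2, 0.3, ped.n).astype(float)
    g_missing = g.copy()
    miss = rng.random(ped.n) < 0.1
    g_missing[miss] = np.nan
    g_imputed = g.copy()
    g_imputed[miss] = g[~miss].mean()
    U1, C1 = res.score_statistics(g_missing)
    U2, C2 = res.score_statistics(g_imputed)
    assert U1[0] == pytest.approx(U2[0], rel=1e-10)


def test_from_dataframe_roundtrip(small_cohort):
    from pathstep import prepare_analysis_table, simulate_phenotypes

    c = small_cohort
    exams = simulate_phenotypes(c["ped"], c["genotypes"], c["catalog"],
                                c["config"], 0, kin=c["kin"])
    coll = prepare_analysis_table(exams)
    res = FamilialLMM.from_dataframe(
        coll, "mean_MAP", ["sex", "mean_age", "ever_smoked"],
        c["kin"]).fit()
    assert res.fe_names == ["intercept", "sex", "mean_age", "ever_smoked"]
    assert res.sigma2_g >= 0 and res.sigma2_e > 0
    assert np.isfinite(res.summary().count("sigma2"))
    tab = res.to_frame()
    assert list(tab["coef"]) == res.fe_names
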