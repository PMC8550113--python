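"""Starting values, GLS updates, PSD projection and the five fitting methods."""

import numpy as np
import pytest

from conftest import DenseOracle, make_design, random_params, rng_for

from fslmm.derivatives import fisher_information, score
from fslmm.estimators import (
    FitConfig,
    fit,
    gls_update,
    initial_values,
    project_psd,
)
from fslmm.matcalc import duplication_matrix, vec
from fslmm.model import CovarianceParams, build_design, core_solves, product_forms
from fslmm.simulate import generate_dataset, preset_setting


def test_initial_values_hand_ols():
    Y = np.array([1.0, 2.0, 3.0])
    X = np.ones((3, 1))
    d = build_design(Y, X, [(np.array([0, 0, 1]), np.ones((3, 1)))])
    beta0, s20, Dk0, warns = initial_values(product_forms(d))
    assert beta0 == pytest.approx([2.0])
    assert s20 == pytest.approx(2.0 / 3.0)


def test_initial_values_exact_fit_floored():
    rng = rng_for(50)
    n = 12
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    beta = np.array([1.0, -2.0])
    lev = np.concatenate([np.arange(3), rng.integers(0, 3, n - 3)])
    d = build_design(X @ beta, X, [(lev, np.ones((n, 1)))])
    beta0, s20, Dk0, warns = initial_values(product_forms(d))
    assert s20 == pytest.approx(1e-10)
    assert any("floor" in w for w in warns)


def test_initial_values_match_dense_formula():
    """The moment-style D start equals its dense-matrix evaluation."""
    rng = rng_for(51)
    d = make_design(rng, 25, 2, [(2, 3)])
    pf = product_forms(d)
    beta0, s20, Dk0, _ = initial_values(pf, psd_project=False)
    X, Y, Z = d.X, d.Y, d.Z()
    b_ols = np.linalg.solve(X.T @ X, X.T @ Y)
    e0 = Y - X @ b_ols
    s2_dense = e0 @ e0 / d.n
    assert s20 == pytest.approx(s2_dense)
    gram = np.zeros((4, 4))
    rhs = np.zeros((2, 2))
    M = np.outer(e0, e0) / s2_dense - np.eye(d.n)
    for j in range(3):
        Zkj = Z[:, 2 * j : 2 * j + 2]
        gram += np.kron(Zkj.T @ Zkj, Zkj.T @ Zkj)
        rhs += Zkj.T @ M @ Zkj
    v = np.linalg.solve(gram, vec(rhs))
    D_dense = 0.5 * (v.reshape(2, 2, order="F") + v.reshape(2, 2, order="F").T)
    assert np.allclose(Dk0[0], D_dense, atol=1e-10)


def test_gls_reduces_to_ols_at_D_zero():
    rng = rng_for(52)
    d = make_design(rng, 20, 2, [(1, 3)])
    pf = product_forms(d)
    params = CovarianceParams(1.0, [np.zeros((1, 1))])
    beta, s2 = gls_update(pf, params)
    b_ols = np.linalg.solve(d.X.T @ d.X, d.X.T @ d.Y)
    e = d.Y - d.X @ b_ols
    assert np.allclose(beta, b_ols)
    assert s2 == pytest.approx(float(e @ e) / d.n)


@pytest.mark.parametrize("reml", [False, True])
def test_gls_matches_dense_oracle(medium_crossed_design, reml):
    d = medium_crossed_design
    rng = rng_for(53)
    params = random_params(rng, d)
    pf = product_forms(d)
    beta, s2 = gls_update(pf, params, reml=reml)
    b_dense, s2_dense = DenseOracle(d, params).gls(reml=reml)
    assert np.allclose(beta, b_dense, rtol=1e-10)
    assert s2 == pytest.approx(s2_dense, rel=1e-10)


def test_gls_idempotent_at_convergence(medium_crossed_design):
    pf = product_forms(medium_crossed_design)
    res = fit(pf, FitConfig(method="sfs"))
    params = res.cov_params()
    beta2, s22 = gls_update(pf, params)
    assert np.max(np.abs(beta2 - res.beta)) < 1e-10
    assert s22 == pytest.approx(res.sigma2, abs=1e-8)


def test_project_psd():
    assert np.allclose(project_psd(np.diag([1.0, -0.5])), np.diag([1.0, 0.0]))
    rng = rng_for(54)
    A = rng.standard_normal((3, 3))
    spd = A @ A.T + 0.1 * np.eye(3)
    assert np.array_equal(project_psd(spd), 0.5 * (spd + spd.T))


def test_project_psd_is_frobenius_nearest():
    """Compare against a direct numerical projection onto the PSD cone."""
    from scipy.optimize import minimize

    rng = rng_for(55)
    S = rng.standard_normal((3, 3))
    S = S + S.T - 1.5 * np.eye(3)
    P = project_psd(S)
    assert np.linalg.eigvalsh(P).min() >= -1e-12

    def dist(vl):
        L = np.zeros((3, 3))
        L[np.tril_indices(3)] = vl
        return np.sum((L @ L.T - S) ** 2)

    best = np.inf
    for s in range(5):
        x0 = rng_for(100 + s).standard_normal(6)
        out = minimize(dist, x0, method="Nelder-Mead",
                       options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12})
        best = min(best, out.fun)
    assert np.sum((P - S) ** 2) <= best + 1e-6


@pytest.mark.parametrize("reml", [False, True])
def test_all_methods_agree_on_one_dataset(reml):
    """FS/FFS/SFS/FSFS (and CSFS) reach the same optimum on shared data."""
    design, _ = generate_dataset(preset_setting(1, n=400), seed=123)
    pf = product_forms(design)
    results = {
        m: fit(pf, FitConfig(method=m, reml=reml))
        for m in ("fs", "ffs", "sfs", "fsfs", "csfs")
    }
    ref = results["fs"]
    for m, res in results.items():
        assert res.converged, m
        tol_ll = 1e-5 if m != "csfs" else 1e-4
        assert abs(res.llf - ref.llf) < tol_ll, m
        if m != "csfs":
            assert np.allclose(res.beta, ref.beta, rtol=1e-4, atol=1e-6), m
            assert res.sigma2 == pytest.approx(ref.sigma2, rel=1e-3), m
            for Dg, Dr in zip(res.Dk_list, ref.Dk_list):
                assert np.allclose(Dg, Dr, rtol=1e-3, atol=1e-4), m


def test_balanced_one_way_matches_closed_form_ml():
    """Balanced random-intercept ANOVA: ML variance components in closed form.

    For y_ij = mu + b_i + e_ij with l groups of m observations, the interior
    ML solution is mu = grand mean, s2_e = SSW/(n-l), s2_e + m s2_b = SSB/l.
    """
    rng = rng_for(56)
    l, m = 8, 6
    n = l * m
    mu, s_b, s_e = 2.0, 1.2, 0.8
    b = s_b * rng.standard_normal(l)
    y = mu + np.repeat(b, m) + s_e * rng.standard_normal(n)
    lev = np.repeat(np.arange(l), m)
    d = build_design(y, np.ones((n, 1)), [(lev, np.ones((n, 1)))])
    res = fit(product_forms(d), FitConfig(method="fs", tol=1e-10))
    gm = y.mean()
    means = y.reshape(l, m).mean(axis=1)
    ssw = float(np.sum((y.reshape(l, m) - means[:, None]) ** 2))
    ssb = float(m * np.sum((means - gm) ** 2))
    s2e_hat = ssw / (n - l)
    tau_hat = ssb / l
    assert tau_hat > s2e_hat  # interior solution holds for this draw
    assert res.beta[0] == pytest.approx(gm, rel=1e-6)
    assert res.sigma2 == pytest.approx(s2e_hat, rel=1e-5)
    s2b_hat = (tau_hat - s2e_hat) / m
    assert res.sigma2 * res.Dk_list[0][0, 0] == pytest.approx(s2b_hat, rel=1e-4)


def test_parameter_recovery_over_replicates():
    """Mean estimates over replicates sit within 3 MC SEs of the truth."""
    setting = preset_setting(1)
    n_reps = 200
    betas, s2Ds = [], []
    children = np.random.SeedSequence(97).spawn(n_reps)
    for child in children:
        design, truth = generate_dataset(setting, np.random.default_rng(child))
        res = fit(product_forms(design), FitConfig(method="fsfs"))
        betas.append(res.beta)
        s2Ds.append((res.sigma2 * res.Dk_list[0]).ravel())
    betas = np.array(betas)
    s2Ds = np.array(s2Ds)
    se_b = betas.std(axis=0, ddof=1) / np.sqrt(n_reps)
    assert np.all(np.abs(betas.mean(axis=0) - setting.beta_true) <= 3 * se_b)
    target = (setting.sigma2_true * setting.Dk_true[0]).ravel()
    se_d = s2Ds.std(axis=0, ddof=1) / np.sqrt(n_reps)
    assert np.all(np.abs(s2Ds.mean(axis=0) - target) <= 3 * se_d)


def test_reml_variances_exceed_ml_on_average():
    """One-sided sign test for the downward bias of ML variance estimates."""
    setting = preset_setting(1, n=150, l=(25,))
    wins = 0
    n_reps = 100
    children = np.random.SeedSequence(98).spawn(n_reps)
    for child in children:
        design, _ = generate_dataset(setting, np.random.default_rng(child))
        pf = product_forms(design)
        ml = fit(pf, FitConfig(method="fsfs", reml=False))
        reml = fit(pf, FitConfig(method="fsfs", reml=True))
        tot_ml = ml.sigma2 * (1.0 + np.trace(ml.Dk_list[0]))
        tot_reml = reml.sigma2 * (1.0 + np.trace(reml.Dk_list[0]))
        wins += tot_reml > tot_ml
    # under no bias, wins ~ Binomial(100, 0.5); demand a clear majority
    assert wins >= 65


def test_loglik_trace_nondecreasing(medium_crossed_design):
    pf = product_forms(medium_crossed_design)
    for m in ("fs", "ffs", "sfs", "fsfs", "csfs"):
        res = fit(pf, FitConfig(method=m))
        diffs = np.diff(res.loglik_trace)
        assert np.all(diffs >= -1e-9), m


def test_ffs_direction_equals_fs_direction_through_duplication():
    """Per iteration, the FFS vec-step equals the FS vech-step mapped by Dup."""
    rng = rng_for(57)
    d = make_design(rng, 60, 2, [(2, 4)])
    pf = product_forms(d)
    beta0, s20, Dk0, _ = initial_values(pf)
    beta, s2, Dk = beta0, s20, Dk0
    for _ in range(3):
        params = CovarianceParams(s2, Dk)
        cs = core_solves(pf, params)
        sh = score(pf, params, beta, rep="half", cs=cs)
        ih = fisher_information(pf, params, rep="half", cs=cs)
        sf = score(pf, params, beta, rep="full", cs=cs)
        F = fisher_information(pf, params, rep="full", scoring_matrix=True, cs=cs)
        step_h = np.linalg.solve(ih.cov_blocks[(0, 0)], sh.d_cov[0])
        step_f = np.linalg.solve(F.cov_blocks[(0, 0)], sf.d_cov[0])
        dup = duplication_matrix(2)
        assert np.allclose(step_f, dup @ step_h, atol=1e-9)
        # advance with a plain SFS-style iteration to probe several points
        beta, s2 = gls_update(pf, params, cs=cs)
        from fslmm.matcalc import unvech, vech

        Dk = [project_psd(unvech(vech(Dk[0]) + step_h, 2))]


def test_csfs_final_covariance_psd_without_projection(medium_crossed_design):
    pf = product_forms(medium_crossed_design)
    res = fit(pf, FitConfig(method="csfs"))
    assert res.Lambda_list is not None
    for lam, D in zip(res.Lambda_list, res.Dk_list):
        assert np.allclose(lam @ lam.T, D, atol=1e-12)
        assert np.linalg.eigvalsh(D).min() >= -1e-12


def test_fit_reports_nonconvergence():
    design, _ = generate_dataset(preset_setting(1, n=300), seed=5)
    res = fit(product_forms(design), FitConfig(method="sfs", max_iter=2, tol=1e-12))
    assert not res.converged
    assert any("maximum number of iterations" in w for w in res.warnings)


def test_fit_rejects_rank_deficient_X():
    rng = rng_for(58)
    n = 15
    x = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), x, 2 * x])
    lev = np.concatenate([np.arange(3), rng.integers(0, 3, n - 3)])
    d = build_design(rng.standard_normal(n), X, [(lev, np.ones((n, 1)))])
    with pytest.raises(np.linalg.LinAlgError):
        fit(product_forms(d), FitConfig(method="sfs"))
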