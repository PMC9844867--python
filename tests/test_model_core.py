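"""Core likelihood machinery: design construction, the joint density q,
the random-effect mode, the Laplace log-likelihood and its derivatives,
and the local / pooled fits."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import fedglmm as fg
from fedglmm.model_core import (
    ModelError,
    _fd_grad_hess,
    build_design,
    inner_mode,
    joint_loglik_q,
    laplace_loglik,
    local_fit,
    loglik_grad_hess,
    pooled_fit,
)

from conftest import GAUSS_SPEC, LOGIT_SPEC, make_gaussian_site, make_logit_site


# ---------------------------------------------------------------------------
# design construction


def test_design_patient_intercepts_one_column_per_patient():
    tab = pd.DataFrame(
        {
            "patient_id": ["a", "a", "b", "b"],
            "y": [0.0, 1.0, 0.0, 1.0],
            "const": 1.0,
            "x1": [0.1, 0.2, 0.3, 0.4],
            "x2": 0.0,
            "x4": 0.0,
        }
    )
    d = build_design(fg.SiteData("s", tab), LOGIT_SPEC)
    assert d.nb == 2
    Z = d.Z.toarray()
    assert Z.shape == (4, 2)
    assert np.array_equal(Z, [[1, 0], [1, 0], [0, 1], [0, 1]])


def test_design_crossed_counts_levels_of_both_factors():
    spec = fg.ModelSpec(
        link="logit",
        common=("const",),
        factors=(fg.RandomFactor("patient_id"), fg.RandomFactor("physician_id")),
    )
    tab = pd.DataFrame(
        {
            "patient_id": ["a", "b", "c", "a", "b", "c"],
            "physician_id": ["u", "u", "v", "v", "u", "v"],
            "y": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
            "const": 1.0,
        }
    )
    d = build_design(fg.SiteData("s", tab), spec)
    assert d.nb == 5  # 3 patients + 2 physicians
    assert d.Z.toarray().sum(axis=1).tolist() == [2.0] * 6


def test_design_missing_column_raises():
    tab = pd.DataFrame({"patient_id": ["a"], "y": [1.0], "const": [1.0]})
    spec = fg.ModelSpec(link="logit", common=("const", "x9"))
    with pytest.raises(ModelError, match="x9"):
        build_design(fg.SiteData("s", tab), spec)


def test_design_non_numeric_covariate_raises():
    tab = pd.DataFrame(
        {"patient_id": ["a", "b"], "y": [0.0, 1.0], "const": ["one", "one"]}
    )
    with pytest.raises(ModelError, match="non-numeric"):
        build_design(fg.SiteData("s", tab), fg.ModelSpec(link="logit", common=("const",)))


# ---------------------------------------------------------------------------
# joint log-density q


def test_q_symmetric_logistic_at_zero(logit_site):
    d = build_design(logit_site, LOGIT_SPEC)
    # all-zero parameters: Bernoulli part is n*log(1/2) regardless of y;
    # Gaussian prior at b=0 contributes -1/2 log|2 pi B|
    gamma = 0.7
    delta = np.array([0.0, math.log(gamma)])
    val = joint_loglik_q(d, np.zeros(3), delta, np.zeros(d.nb))
    expected = d.n * math.log(0.5) - 0.5 * d.nb * math.log(2 * math.pi * gamma)
    assert val == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_q_matches_per_row_summation_oracle(seed):
    """q equals an independent term-by-term sum of Bernoulli log-pmfs and
    normal log-pdfs."""
    site = make_logit_site(n_patients=8, encounters=3, seed=seed)
    d = build_design(site, LOGIT_SPEC)
    rng = np.random.default_rng(seed)
    beta = rng.normal(size=3)
    alpha = rng.normal(size=1)
    gamma = float(rng.uniform(0.2, 2.0))
    b = rng.normal(size=d.nb)
    val = joint_loglik_q(d, beta, np.concatenate([alpha, [math.log(gamma)]]), b)

    eta = d.X @ beta + d.W @ alpha + b[d.codes[0]]
    oracle = sum(
        st.bernoulli.logpmf(int(yi), 1 / (1 + math.exp(-ei)))
        for yi, ei in zip(d.y, eta)
    )
    oracle += st.norm.logpdf(b, 0, math.sqrt(gamma)).sum()
    assert val == pytest.approx(oracle, rel=1e-10)


def test_q_rejects_dimension_mismatch(logit_site):
    d = build_design(logit_site, LOGIT_SPEC)
    with pytest.raises(ModelError):
        joint_loglik_q(d, np.zeros(3), np.array([0.0, 0.0]), np.zeros(d.nb + 1))


# ---------------------------------------------------------------------------
# inner mode


def test_inner_mode_gaussian_matches_direct_linear_solve(gaussian_site):
    d = build_design(gaussian_site, GAUSS_SPEC)
    beta = np.array([0.8, -0.3])
    gamma, s2 = 0.5, 0.4
    delta = np.array([math.log(gamma), math.log(s2)])
    im = inner_mode(d, beta, delta)
    assert im.converged
    Z = d.Z.toarray()
    A = Z.T @ Z / s2 + np.eye(d.nb) / gamma
    b_direct = np.linalg.solve(A, Z.T @ (d.y - d.X @ beta) / s2)
    np.testing.assert_allclose(im.b_hat, b_direct, rtol=1e-10)


def test_inner_mode_shrinks_to_zero_for_tiny_variance(logit_site):
    d = build_design(logit_site, LOGIT_SPEC)
    im = inner_mode(d, np.array([0.2, 0.5, -0.1]), np.array([0.3, math.log(1e-8)]))
    assert im.converged
    assert np.max(np.abs(im.b_hat)) < 1e-6


def test_inner_mode_matches_1d_grid_search():
    """One patient, one binary observation, scalar gamma: the mode matches a
    dense grid search of q over b."""
    tab = pd.DataFrame(
        {"patient_id": ["p"], "y": [1.0], "const": [1.0]}
    )
    spec = fg.ModelSpec(link="logit", common=("const",))
    d = build_design(fg.SiteData("s", tab), spec)
    beta = np.array([-0.4])
    delta = np.array([math.log(1.5)])
    im = inner_mode(d, beta, delta)
    grid = np.linspace(-5, 5, 200001)
    qs = np.array([joint_loglik_q(d, beta, delta, np.array([b])) for b in grid[::1000]])
    coarse = grid[::1000][np.argmax(qs)]
    fine = np.linspace(coarse - 0.06, coarse + 0.06, 12001)
    qf = np.array([joint_loglik_q(d, beta, delta, np.array([b])) for b in fine])
    assert im.b_hat[0] == pytest.approx(fine[np.argmax(qf)], abs=2e-5)


# ---------------------------------------------------------------------------
# Laplace log-likelihood


@pytest.mark.parametrize("seed", range(4))
def test_laplace_exact_for_gaussian_identity(seed):
    """Identity link: the Laplace value equals the closed-form marginal
    normal log-density with covariance Z B Z' + sigma^2 I."""
    rng = np.random.default_rng(seed)
    site = make_gaussian_site(n_patients=int(rng.integers(10, 40)), seed=seed)
    d = build_design(site, GAUSS_SPEC)
    beta = rng.normal(size=2)
    gamma = float(rng.uniform(0.1, 2.0))
    s2 = float(rng.uniform(0.2, 1.5))
    val = laplace_loglik(d, beta, np.array([math.log(gamma), math.log(s2)]))
    Z = d.Z.toarray()
    cov = gamma * Z @ Z.T + s2 * np.eye(d.n)
    oracle = st.multivariate_normal.logpdf(d.y, mean=d.X @ beta, cov=cov)
    assert val == pytest.approx(oracle, abs=1e-8)


def test_laplace_tends_to_glm_loglik_as_variance_vanishes(logit_site):
    d = build_design(logit_site, LOGIT_SPEC)
    beta = np.array([-0.3, 0.8, 0.4])
    alpha = np.array([0.2])
    val = laplace_loglik(d, beta, np.concatenate([alpha, [math.log(1e-8)]]))
    eta = d.X @ beta + d.W @ alpha
    glm = st.bernoulli.logpmf(d.y.astype(int), 1 / (1 + np.exp(-eta))).sum()
    assert val == pytest.approx(glm, abs=1e-4)


def test_laplace_matches_scalar_finite_difference_construction():
    """Single random effect: lhat = q(bhat) + log(2 pi)/2 - log(-q'')/2 with
    q'' from numerical differentiation."""
    tab = pd.DataFrame(
        {
            "patient_id": ["p"] * 4,
            "y": [1.0, 0.0, 1.0, 1.0],
            "const": 1.0,
            "x1": [0.5, -0.2, 0.1, 0.9],
        }
    )
    spec = fg.ModelSpec(link="logit", common=("const", "x1"))
    d = build_design(fg.SiteData("s", tab), spec)
    beta = np.array([0.2, -0.5])
    delta = np.array([math.log(0.9)])
    im = inner_mode(d, beta, delta)
    h = 1e-4
    qp = joint_loglik_q(d, beta, delta, im.b_hat + h)
    qm = joint_loglik_q(d, beta, delta, im.b_hat - h)
    q2 = (qp - 2 * im.q_value + qm) / h**2
    oracle = im.q_value + 0.5 * math.log(2 * math.pi) - 0.5 * math.log(-q2)
    assert laplace_loglik(d, beta, delta) == pytest.approx(oracle, abs=1e-6)


def test_laplace_invariant_to_row_permutation(logit_site):
    d1 = build_design(logit_site, LOGIT_SPEC)
    rng = np.random.default_rng(5)
    perm = rng.permutation(len(logit_site.table))
    shuffled = fg.SiteData(
        logit_site.site_id, logit_site.table.iloc[perm].reset_index(drop=True)
    )
    d2 = build_design(shuffled, LOGIT_SPEC)
    beta = np.array([0.1, 0.7, -0.2])
    delta = np.array([0.3, math.log(0.6)])
    assert laplace_loglik(d1, beta, delta) == pytest.approx(
        laplace_loglik(d2, beta, delta), rel=1e-12
    )
    g1, H1 = loglik_grad_hess(d1, beta, delta)
    g2, H2 = loglik_grad_hess(d2, beta, delta)
    np.testing.assert_allclose(g1, g2, rtol=1e-8, atol=1e-9)
    np.testing.assert_allclose(H1, H2, rtol=1e-7, atol=1e-6)


# ---------------------------------------------------------------------------
# derivatives


def _oracle_fd(d, beta, delta, h=2e-3):
    """Independent central-difference derivatives at a coarser step size."""
    t0 = np.concatenate([beta, delta])
    pb = beta.size

    def f(t):
        return laplace_loglik(d, t[:pb], t[pb:])

    p = t0.size
    g = np.empty(p)
    H = np.empty((p, p))
    f0 = f(t0)
    for i in range(p):
        e = np.zeros(p)
        e[i] = h
        g[i] = (f(t0 + e) - f(t0 - e)) / (2 * h)
        H[i, i] = (f(t0 + e) - 2 * f0 + f(t0 - e)) / h**2
    for i in range(p):
        for j in range(i + 1, p):
            ei, ej = np.zeros(p), np.zeros(p)
            ei[i] = h
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(t0 + ei + ej) - f(t0 + ei - ej) - f(t0 - ei + ej) + f(t0 - ei - ej)
            ) / (4 * h * h)
    return g, H


@pytest.mark.parametrize("seed", range(3))
def test_grad_hess_matches_independent_finite_differences(seed):
    site = make_logit_site(n_patients=15, encounters=3, seed=seed)
    d = build_design(site, LOGIT_SPEC)
    rng = np.random.default_rng(100 + seed)
    beta = rng.normal(scale=0.5, size=3)
    delta = np.concatenate([rng.normal(scale=0.5, size=1), [math.log(rng.uniform(0.3, 1.5))]])
    g, H = loglik_grad_hess(d, beta, delta)
    go, Ho = _oracle_fd(d, beta, delta)
    assert np.linalg.norm(g - go) / np.linalg.norm(go) < 1e-4
    assert np.linalg.norm(H - Ho) / np.linalg.norm(Ho) < 1e-4
    assert np.max(np.abs(H - H.T)) == 0.0  # symmetric by construction


def test_gradient_vanishes_at_local_optimum(logit_site):
    fit = local_fit(logit_site, LOGIT_SPEC)
    d = build_design(logit_site, LOGIT_SPEC)
    g, _ = loglik_grad_hess(d, fit.beta_hat, fit.delta_hat)
    assert np.max(np.abs(g)) < 1e-6


# ---------------------------------------------------------------------------
# local fit


def test_local_fit_gaussian_matches_statsmodels_mixedlm(gaussian_site):
    import statsmodels.api as sm

    fit = local_fit(gaussian_site, GAUSS_SPEC)
    tab = gaussian_site.table
    md = sm.MixedLM(
        tab["y"], tab[["const", "x1"]], groups=tab["patient_id"]
    )
    res = md.fit(reml=False, method="lbfgs")
    np.testing.assert_allclose(fit.beta_hat, res.fe_params, rtol=2e-4, atol=2e-4)
    # variance components: ours on the log scale
    gamma_hat = math.exp(fit.t_hat[2])
    s2_hat = math.exp(fit.t_hat[3])
    assert gamma_hat == pytest.approx(float(res.cov_re.iloc[0, 0]), rel=2e-3, abs=1e-4)
    assert s2_hat == pytest.approx(res.scale, rel=2e-3)


def test_local_fit_logit_matches_lme4_glmer(tmp_path):
    """Independent cross-check against glmer's Laplace fit of the same model."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not available")
    site = make_logit_site(n_patients=120, encounters=4, seed=42)
    csv = tmp_path / "site.csv"
    site.table.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        """
        suppressMessages(library(lme4))
        d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
        m <- glmer(y ~ x1 + x2 + x4 + (1 | patient_id), data=d,
                   family=binomial, nAGQ=1)
        cat(fixef(m), as.numeric(VarCorr(m)$patient_id), sep="\\n")
        """
    )
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script), str(csv)],
        capture_output=True, text=True, timeout=300,
    )
    assert out.returncode == 0, out.stderr
    vals = [float(x) for x in out.stdout.split()]
    ref_fix, ref_gamma = np.array(vals[:4]), vals[4]

    fit = local_fit(site, LOGIT_SPEC)
    ours = np.array([fit.beta_hat[0], fit.beta_hat[1], fit.beta_hat[2], fit.t_hat[3]])
    np.testing.assert_allclose(ours, ref_fix, atol=5e-3)
    assert math.exp(fit.t_hat[4]) == pytest.approx(ref_gamma, rel=2e-2, abs=5e-3)


def test_local_fit_recovers_generating_exposure_effect():
    site = make_logit_site(n_patients=300, encounters=5, seed=7)
    fit = local_fit(site, LOGIT_SPEC)
    se = math.sqrt(fit.V[1, 1])
    assert abs(fit.beta_hat[1] - 1.0) < 3 * se


def test_local_fit_flags_degenerate_outcome():
    site = make_logit_site(n_patients=20, seed=3)
    tab = site.table.copy()
    tab["y"] = 0.0
    fit = local_fit(fg.SiteData("deg", tab), LOGIT_SPEC)
    assert "separation" in fit.flags


# ---------------------------------------------------------------------------
# pooled fit


def test_pooled_single_site_collapses_to_local_fit(logit_site):
    lf = local_fit(logit_site, LOGIT_SPEC)
    pooled = pooled_fit([logit_site], LOGIT_SPEC, local_fits=[lf])
    np.testing.assert_allclose(pooled.theta.values, lf.t_hat, atol=1e-6)


def test_pooled_duplicated_site_same_beta_half_covariance(logit_site):
    spec = fg.ModelSpec(
        link="logit",
        common=("const", "x1", "x2"),
        site_specific=("x4",),
        factors=(fg.RandomFactor("patient_id"),),
        alpha_shared=True,
        gamma_shared=True,
    )
    one = pooled_fit([logit_site], spec)
    copy = fg.SiteData("s1_copy", logit_site.table.copy())
    two = pooled_fit([logit_site, copy], spec)
    np.testing.assert_allclose(two.theta.beta, one.theta.beta, atol=1e-5)
    pb = len(spec.common)
    np.testing.assert_allclose(
        two.covariance[:pb, :pb], 0.5 * one.covariance[:pb, :pb], rtol=1e-3
    )


def test_pooled_requires_at_least_one_site():
    with pytest.raises(ModelError):
        pooled_fit([], LOGIT_SPEC)
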