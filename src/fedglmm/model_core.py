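"""GLMM core: Laplace-approximated site log-likelihood, derivatives, and fits.

The model for encounter i of patient j at site k is

    g(E[y_ijk | b]) = x_ijk' beta + w_ijk' alpha_k + z_ijk' b,
    b_k ~ N(0, B_k(gamma_k)),

with intercept-only random effects per grouping factor (patient, optionally
physician), so B_k is diagonal with one variance per factor.  Supported links
are logit (Bernoulli outcome) and identity (Gaussian outcome, residual
variance carried as the last variance component).

The marginal site log-likelihood integrates the random effects out; we
approximate the integral with Laplace's method at the random-effect mode:

    lhat_k = q(b_hat) + (n_b / 2) ln(2 pi) - (1/2) ln det(-grad^2_b q(b_hat)),

where q(b) = log p(y | b) + log p(b).  For the identity link this is exact.

Outer derivatives of lhat_k with respect to (beta, alpha_k, eta_k), where
eta = log gamma, are obtained by central finite differences of lhat_k; the
inner mode is found by Newton's method with step halving, exploiting the
diagonal (single factor) or bordered-diagonal (two crossed factors)
structure of the inner Hessian.
"""

from __future__ import annotations

import math
import warnings as _pywarnings
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as spo
import scipy.sparse as sp
from scipy.special import expit

from .parameters import ParamLayout, Theta

LOG2PI = math.log(2.0 * math.pi)

# finite-difference step sizes (relative to max(1, |t_i|)); chosen to balance
# truncation against cancellation for objectives accurate to ~1e-12.  The
# inner tolerance must be tight: the log-determinant term of the Laplace
# objective is first-order sensitive to the inner-mode error.
_H_GRAD = 1e-4
_H_HESS = 1e-3

_INNER_TOL = 1e-11
_INNER_MAXIT = 100

# bounds keeping the unconstrained optimizer out of numerically degenerate
# territory: exp(-12) ~ 6e-6 is an effectively-zero variance
_ETA_BOUNDS = (-12.0, 6.0)
_COEF_BOUNDS = (-40.0, 40.0)


class ModelError(ValueError):
    """Bad model/data combination (missing column, dimension mismatch...)."""


class InnerModeError(RuntimeError):
    """The random-effect mode search failed to converge."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class RandomFactor:
    """An intercept-only random-effect grouping factor (diagonal covariance)."""

    group: str  # column holding the grouping identifier


@dataclass(frozen=True)
class ModelSpec:
    """Link, covariate roles, random-effect structure and homogeneity flags."""

    link: str  # "logit" | "identity"
    common: tuple[str, ...]  # columns with common fixed effect beta
    site_specific: tuple[str, ...] = ()  # columns with site-specific alpha_k
    factors: tuple[RandomFactor, ...] = (RandomFactor("patient_id"),)
    alpha_shared: bool = False  # alpha homogeneous across sites
    gamma_shared: bool = False  # variance components homogeneous across sites

    def __post_init__(self) -> None:
        if self.link not in ("logit", "identity"):
            raise ModelError(f"unsupported link {self.link!r}")
        if not self.factors:
            raise ModelError("at least one random-effect grouping factor required")
        if not self.common:
            raise ModelError("at least one common fixed-effect column required")
        dup = set(self.common) & set(self.site_specific)
        if dup:
            raise ModelError(f"columns in both beta and alpha roles: {sorted(dup)}")

    def gamma_labels(self) -> tuple[str, ...]:
        labs = tuple(f"log_var({f.group})" for f in self.factors)
        if self.link == "identity":
            labs = labs + ("log_var(residual)",)
        return labs

    @property
    def n_gamma(self) -> int:
        return len(self.factors) + (1 if self.link == "identity" else 0)


@dataclass
class SiteData:
    """One site's encounter table (one row per visit)."""

    site_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.site_id = str(self.site_id)
        if len(self.table) == 0:
            raise ModelError(f"site {self.site_id}: empty encounter table")
        if "patient_id" not in self.table.columns:
            raise ModelError(f"site {self.site_id}: missing patient_id column")
        if self.table.isna().any().any():
            raise ModelError(
                f"site {self.site_id}: missing values present; apply the "
                "complete-case filter (io.read_encounters) first"
            )

    @property
    def n_rows(self) -> int:
        return len(self.table)


@dataclass
class DesignBundle:
    """Row-aligned design matrices and random-effect group index maps."""

    site_id: str
    y: np.ndarray
    X: np.ndarray  # common fixed effects
    W: np.ndarray  # site-specific fixed effects (n x 0 allowed)
    codes: tuple[np.ndarray, ...]  # per factor: row -> level index
    levels: tuple[np.ndarray, ...]  # per factor: level labels, code order
    factor_names: tuple[str, ...]
    link: str
    x_cols: tuple[str, ...]
    w_cols: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def nlev(self) -> tuple[int, ...]:
        return tuple(lv.size for lv in self.levels)

    @property
    def nb(self) -> int:
        return int(sum(self.nlev))

    @property
    def offsets(self) -> tuple[int, ...]:
        out, acc = [], 0
        for n in self.nlev:
            out.append(acc)
            acc += n
        return tuple(out)

    @property
    def Z(self) -> sp.csr_matrix:
        """Sparse random-effect indicator matrix (one block per factor)."""
        n = self.n
        rows = np.tile(np.arange(n), len(self.codes))
        cols = np.concatenate(
            [c + off for c, off in zip(self.codes, self.offsets)]
        )
        data = np.ones(rows.size)
        return sp.csr_matrix((data, (rows, cols)), shape=(n, self.nb))


@dataclass
class InnerMode:
    """Random-effect mode for one site at fixed outer parameters."""

    b_hat: np.ndarray
    q_value: float
    logdet: float  # log det of the negated inner Hessian at b_hat
    converged: bool
    iterations: int
    _neg_hessian: np.ndarray | None = field(default=None, repr=False)

    def neg_inner_hessian(self) -> np.ndarray:
        if self._neg_hessian is None:
            raise ValueError("dense inner Hessian was not materialized")
        return self._neg_hessian


@dataclass
class LocalFit:
    """One site's local GLMM fit (Step 1 of the federated algorithm)."""

    site_id: str
    t_hat: np.ndarray  # (beta, alpha, eta) at the local optimum
    cov: np.ndarray  # inverse observed information over t
    loglik: float
    converged: bool
    grad_norm: float
    flags: tuple[str, ...]
    p_beta: int
    p_alpha: int

    @property
    def beta_hat(self) -> np.ndarray:
        return self.t_hat[: self.p_beta]

    @property
    def delta_hat(self) -> np.ndarray:
        return self.t_hat[self.p_beta :]

    @property
    def V(self) -> np.ndarray:
        """Estimated covariance of the local beta estimate."""
        return self.cov[: self.p_beta, : self.p_beta]


@dataclass
class PooledResult:
    """Gold-standard fit maximizing the summed site log-likelihoods."""

    theta: Theta
    covariance: np.ndarray
    loglik: float
    grad_norm: float
    converged: bool
    warnings: tuple[str, ...]
    local_fits: list[LocalFit] | None = None


# ---------------------------------------------------------------------------
# design construction


def build_design(site: SiteData, spec: ModelSpec) -> DesignBundle:
    """Assemble row-aligned X, W, and random-effect group maps for one site."""
    tab = site.table
    needed = list(spec.common) + list(spec.site_specific) + ["y"]
    for f in spec.factors:
        needed.append(f.group)
    missing = [c for c in needed if c not in tab.columns]
    if missing:
        raise ModelError(f"site {site.site_id}: missing columns {missing}")

    def mat(cols: tuple[str, ...]) -> np.ndarray:
        if not cols:
            return np.empty((len(tab), 0))
        block = tab[list(cols)]
        bad = [c for c in cols if not np.issubdtype(block[c].dtype, np.number)]
        if bad:
            raise ModelError(f"site {site.site_id}: non-numeric covariates {bad}")
        return np.ascontiguousarray(block.to_numpy(dtype=float))

    y = np.asarray(tab["y"].to_numpy(), dtype=float)
    if spec.link == "logit" and not np.all(np.isin(y, (0.0, 1.0))):
        raise ModelError(f"site {site.site_id}: logit link requires y in {{0,1}}")

    codes, levels = [], []
    for f in spec.factors:
        c, lv = pd.factorize(tab[f.group], sort=True)
        codes.append(np.asarray(c, dtype=np.intp))
        levels.append(np.asarray(lv))

    return DesignBundle(
        site_id=site.site_id,
        y=y,
        X=mat(spec.common),
        W=mat(spec.site_specific),
        codes=tuple(codes),
        levels=tuple(levels),
        factor_names=tuple(f.group for f in spec.factors),
        link=spec.link,
        x_cols=tuple(spec.common),
        w_cols=tuple(spec.site_specific),
    )


# ---------------------------------------------------------------------------
# link internals


def _split_gamma(design: DesignBundle, eta_vec: np.ndarray):
    """Unconstrained gamma block -> (factor variances, residual variance)."""
    nf = len(design.codes)
    expected = nf + (1 if design.link == "identity" else 0)
    eta_vec = np.asarray(eta_vec, dtype=float)
    if eta_vec.size != expected:
        raise ModelError(
            f"gamma block has length {eta_vec.size}, expected {expected}"
        )
    gam = np.exp(eta_vec[:nf])
    s2 = float(np.exp(eta_vec[nf])) if design.link == "identity" else 1.0
    return gam, s2


def _split_local(design: DesignBundle, t: np.ndarray):
    pb, pa = design.X.shape[1], design.W.shape[1]
    t = np.asarray(t, dtype=float)
    return t[:pb], t[pb : pb + pa], t[pb + pa :]


def _fixed_linpred(design: DesignBundle, beta, alpha) -> np.ndarray:
    eta0 = design.X @ np.asarray(beta, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if design.W.shape[1]:
        if alpha.size != design.W.shape[1]:
            raise ModelError("alpha length does not match site-specific design")
        eta0 = eta0 + design.W @ alpha
    elif alpha.size:
        raise ModelError("alpha provided but model has no site-specific columns")
    return eta0


def _obs_loglik(link: str, y, eta, s2: float) -> float:
    if link == "logit":
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    r = y - eta
    return float(-0.5 * (r @ r / s2 + y.size * math.log(2.0 * math.pi * s2)))


def _score_weight(link: str, y, eta, s2: float):
    if link == "logit":
        mu = expit(eta)
        return y - mu, mu * (1.0 - mu)
    n = y.size
    return (y - eta) / s2, np.full(n, 1.0 / s2)


def _b_linpred(design: DesignBundle, b: np.ndarray) -> np.ndarray:
    out = np.zeros(design.n)
    for c, off, nl in zip(design.codes, design.offsets, design.nlev):
        out += b[off : off + nl][c]
    return out


def _q_of_b(design, eta0, gam, s2, b) -> float:
    eta = eta0 + _b_linpred(design, b)
    val = _obs_loglik(design.link, design.y, eta, s2)
    for off, nl, g in zip(design.offsets, design.nlev, gam):
        bf = b[off : off + nl]
        val -= 0.5 * (bf @ bf / g + nl * math.log(2.0 * math.pi * g))
    return val


def joint_loglik_q(design: DesignBundle, beta, delta, b) -> float:
    """q(b) = log p(y | eta) + log p(b); the Laplace integrand's exponent."""
    beta = np.asarray(beta, dtype=float)
    alpha, eta_vec = _split_delta(design, delta)
    b = np.asarray(b, dtype=float)
    if b.size != design.nb:
        raise ModelError(f"b has length {b.size}, expected {design.nb}")
    for arr in (beta, alpha, eta_vec, b):
        if not np.all(np.isfinite(arr)):
            raise ModelError("non-finite parameter input")
    gam, s2 = _split_gamma(design, eta_vec)
    eta0 = _fixed_linpred(design, beta, alpha)
    return _q_of_b(design, eta0, gam, s2, b)


def _split_delta(design: DesignBundle, delta):
    delta = np.asarray(delta, dtype=float)
    pa = design.W.shape[1]
    return delta[:pa], delta[pa:]


# ---------------------------------------------------------------------------
# inner (random-effect) mode


def _cross_block(design, big, small, w) -> sp.csr_matrix:
    """Z_big' diag(w) Z_small as CSR, with the sparsity pattern cached on the
    design (only the data vector changes between inner iterations)."""
    cache = getattr(design, "_cross_cache", None)
    if cache is None or cache[0] != (big, small):
        cb, cs = design.codes[big], design.codes[small]
        n_small = design.nlev[small]
        pair = cb.astype(np.int64) * n_small + cs
        uniq, inv = np.unique(pair, return_inverse=True)
        rows = (uniq // n_small).astype(np.intp)
        cols = (uniq % n_small).astype(np.intp)
        proto = sp.csr_matrix(
            (np.ones(uniq.size), (rows, cols)),
            shape=(design.nlev[big], n_small),
        )
        # map each unique pair to its slot in the CSR data array
        order = np.lexsort((cols, rows))
        slot = np.empty(uniq.size, dtype=np.intp)
        slot[order] = np.arange(uniq.size)
        cache = ((big, small), inv, slot, proto)
        design._cross_cache = cache
    _, inv, slot, proto = cache
    data = np.zeros(proto.nnz)
    data[slot] = np.bincount(inv, weights=w, minlength=slot.size)
    C = proto.copy()
    C.data = data
    return C


class _InnerSolver:
    """Factorization of A = Z' diag(w) Z + B^{-1}, exploiting structure.

    One grouping factor: A is diagonal.  Two crossed factors: A is a 2x2
    block matrix with diagonal diagonal-blocks; solved by a Schur complement
    on the smaller factor.  Three or more factors: dense Cholesky.
    """

    def __init__(self, design: DesignBundle, w: np.ndarray, inv_gam: np.ndarray):
        self.design = design
        nf = len(design.codes)
        nlev, offs = design.nlev, design.offsets
        if nf == 1:
            d = np.bincount(design.codes[0], weights=w, minlength=nlev[0])
            self.kind = "diag"
            self.Ad = d + inv_gam[0]
            self.logdet = float(np.sum(np.log(self.Ad)))
        elif nf == 2:
            big, small = (0, 1) if nlev[0] >= nlev[1] else (1, 0)
            self.big, self.small = big, small
            cb, cs = design.codes[big], design.codes[small]
            D1 = np.bincount(cb, weights=w, minlength=nlev[big]) + inv_gam[big]
            D2 = np.bincount(cs, weights=w, minlength=nlev[small]) + inv_gam[small]
            C = _cross_block(design, big, small, w)
            S = np.diag(D2) - (C.multiply(1.0 / D1[:, None])).T @ C
            S = np.asarray(S)
            self.D1, self.C = D1, C
            self.S_cho = sla.cho_factor(S, lower=True)
            self.logdet = float(
                np.sum(np.log(D1)) + 2.0 * np.sum(np.log(np.diag(self.S_cho[0])))
            )
            self.kind = "schur"
        else:
            Z = design.Z.toarray()
            A = (Z * w[:, None]).T @ Z
            A[np.diag_indices_from(A)] += np.repeat(inv_gam, nlev)
            self.cho = sla.cho_factor(A, lower=True)
            self.logdet = float(2.0 * np.sum(np.log(np.diag(self.cho[0]))))
            self.kind = "dense"

    def solve(self, r: np.ndarray) -> np.ndarray:
        if self.kind == "diag":
            return r / self.Ad
        if self.kind == "dense":
            return sla.cho_solve(self.cho, r)
        d = self.design
        offs, nlev = d.offsets, d.nlev
        rb = r[offs[self.big] : offs[self.big] + nlev[self.big]]
        rs = r[offs[self.small] : offs[self.small] + nlev[self.small]]
        xs = sla.cho_solve(self.S_cho, rs - self.C.T @ (rb / self.D1))
        xb = (rb - self.C @ xs) / self.D1
        out = np.empty(r.size)
        out[offs[self.big] : offs[self.big] + nlev[self.big]] = xb
        out[offs[self.small] : offs[self.small] + nlev[self.small]] = xs
        return out


def _neg_inner_hessian_dense(design, w, inv_gam) -> np.ndarray:
    Z = design.Z.toarray()
    A = (Z * w[:, None]).T @ Z
    A[np.diag_indices_from(A)] += np.repeat(inv_gam, design.nlev)
    return A


def _inner_newton(design, eta0, gam, s2, b0, tol=_INNER_TOL, maxit=_INNER_MAXIT):
    """Newton with step halving on the concave q(b); returns the mode."""
    inv_gam = 1.0 / gam
    inv_rep = np.repeat(inv_gam, design.nlev)
    b = np.asarray(b0, dtype=float).copy()

    if design.link == "identity":
        # q is exactly quadratic in b: one linear solve from b = 0
        score0, w = _score_weight("identity", design.y, eta0, s2)
        rhs = _scatter(design, score0)
        solver = _InnerSolver(design, w, inv_gam)
        b = solver.solve(rhs)
        return b, solver, _q_of_b(design, eta0, gam, s2, b), True, 1

    q_cur = _q_of_b(design, eta0, gam, s2, b)
    solver = None
    for it in range(1, maxit + 1):
        eta = eta0 + _b_linpred(design, b)
        score, w = _score_weight(design.link, design.y, eta, s2)
        grad = _scatter(design, score) - b * inv_rep
        solver = _InnerSolver(design, w, inv_gam)
        if np.max(np.abs(grad)) <= tol:
            return b, solver, q_cur, True, it
        step = solver.solve(grad)
        for _ in range(40):
            b_new = b + step
            q_new = _q_of_b(design, eta0, gam, s2, b_new)
            if q_new >= q_cur - 1e-12 * max(1.0, abs(q_cur)):
                break
            step *= 0.5
        b, q_cur = b_new, q_new
    eta = eta0 + _b_linpred(design, b)
    score, w = _score_weight(design.link, design.y, eta, s2)
    grad = _scatter(design, score) - b * inv_rep
    converged = bool(np.max(np.abs(grad)) <= tol)
    return b, solver, q_cur, converged, maxit


def _scatter(design, vals: np.ndarray) -> np.ndarray:
    out = np.empty(design.nb)
    for c, off, nl in zip(design.codes, design.offsets, design.nlev):
        out[off : off + nl] = np.bincount(c, weights=vals, minlength=nl)
    return out


def inner_mode(design: DesignBundle, beta, delta, b_start=None) -> InnerMode:
    """Find b_hat maximizing q(b) and the factorized -grad^2_b q(b_hat)."""
    alpha, eta_vec = _split_delta(design, delta)
    gam, s2 = _split_gamma(design, eta_vec)
    eta0 = _fixed_linpred(design, beta, alpha)
    b0 = np.zeros(design.nb) if b_start is None else np.asarray(b_start, float)
    if b0.size != design.nb or not np.all(np.isfinite(b0)):
        raise ModelError("b_start has wrong length or non-finite entries")
    b, solver, q_val, conv, it = _inner_newton(design, eta0, gam, s2, b0)
    eta = eta0 + _b_linpred(design, b)
    _, w = _score_weight(design.link, design.y, eta, s2)
    dense = _neg_inner_hessian_dense(design, w, 1.0 / gam)
    return InnerMode(
        b_hat=b,
        q_value=q_val,
        logdet=solver.logdet,
        converged=conv,
        iterations=it,
        _neg_hessian=dense,
    )


# ---------------------------------------------------------------------------
# Laplace log-likelihood and derivatives


def _laplace_core(design, beta, alpha, eta_vec, b0):
    gam, s2 = _split_gamma(design, eta_vec)
    eta0 = _fixed_linpred(design, beta, alpha)
    b, solver, q_val, conv, _ = _inner_newton(design, eta0, gam, s2, b0)
    if not conv:
        raise InnerModeError(
            f"site {design.site_id}: inner mode did not converge"
        )
    lhat = q_val + 0.5 * design.nb * LOG2PI - 0.5 * solver.logdet
    return lhat, b


def laplace_loglik(design: DesignBundle, beta, delta) -> float:
    """Laplace-approximated marginal log-likelihood of one site."""
    alpha, eta_vec = _split_delta(design, delta)
    val, _ = _laplace_core(design, np.asarray(beta, float), alpha, eta_vec,
                           np.zeros(design.nb))
    return val


def _fd_grad(f, t, h_rel=_H_GRAD):
    t = np.asarray(t, dtype=float)
    p = t.size
    g = np.empty(p)
    for i in range(p):
        h = h_rel * max(1.0, abs(t[i]))
        tp, tm = t.copy(), t.copy()
        tp[i] += h
        tm[i] -= h
        g[i] = (f(tp) - f(tm)) / (2.0 * h)
    return g


def _fd_grad_hess(f, t, h_grad=_H_GRAD, h_hess=_H_HESS):
    """Central-difference gradient and Hessian of a scalar function."""
    t = np.asarray(t, dtype=float)
    p = t.size
    f0 = f(t)
    g = _fd_grad(f, t, h_rel=h_grad)
    h = np.array([h_hess * max(1.0, abs(t[i])) for i in range(p)])
    H = np.empty((p, p))
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        tp, tm = t.copy(), t.copy()
        tp[i] += h[i]
        tm[i] -= h[i]
        fp[i], fm[i] = f(tp), f(tm)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            tpp, tpm, tmp, tmm = t.copy(), t.copy(), t.copy(), t.copy()
            tpp[i] += h[i]; tpp[j] += h[j]
            tpm[i] += h[i]; tpm[j] -= h[j]
            tmp[i] -= h[i]; tmp[j] += h[j]
            tmm[i] -= h[i]; tmm[j] -= h[j]
            H[i, j] = H[j, i] = (
                f(tpp) - f(tpm) - f(tmp) + f(tmm)
            ) / (4.0 * h[i] * h[j])
    return f0, g, H


class SiteLikelihood:
    """Callable wrapper around one site's Laplace log-likelihood.

    Evaluations used for summary statistics start the inner Newton from
    b = 0 at the center point (bit-stable across processes); the finite
    difference perturbations warm-start from the center's mode.
    """

    def __init__(self, site: SiteData, spec: ModelSpec):
        self.site_id = site.site_id
        self.spec = spec
        self.design = build_design(site, spec)
        self.p_beta = self.design.X.shape[1]
        self.p_alpha = self.design.W.shape[1]
        self.p_gamma = spec.n_gamma
        self.p = self.p_beta + self.p_alpha + self.p_gamma
        self._b_warm = np.zeros(self.design.nb)

    def _value(self, t, b0):
        beta, alpha, eta_vec = _split_local(self.design, t)
        return _laplace_core(self.design, beta, alpha, eta_vec, b0)

    def loglik(self, t, warm: bool = True) -> float:
        """Laplace log-likelihood at the local vector t = (beta, alpha, eta)."""
        b0 = self._b_warm if warm else np.zeros(self.design.nb)
        val, b = self._value(t, b0)
        if warm:
            self._b_warm = b
        return val

    def value_grad(self, t):
        """(lhat, gradient) with a cold-started, deterministic center."""
        f0, bc = self._value(t, np.zeros(self.design.nb))
        f = lambda tt: self._value(tt, bc)[0]
        return f0, _fd_grad(f, t)

    def value_grad_hess(self, t):
        """(lhat, gradient, Hessian); deterministic given t and the design."""
        _, bc = self._value(t, np.zeros(self.design.nb))
        f = lambda tt: self._value(tt, bc)[0]
        return _fd_grad_hess(f, t)


def loglik_grad_hess(design: DesignBundle, beta, delta):
    """Gradient and Hessian of the Laplace log-likelihood over (beta, delta)."""
    t = np.concatenate([np.asarray(beta, float).ravel(),
                        np.asarray(delta, float).ravel()])
    _, bc = _laplace_core(design, *_split_local(design, t), np.zeros(design.nb))

    def f(tt):
        b, a, e = _split_local(design, tt)
        return _laplace_core(design, b, a, e, bc)[0]

    _, g, H = _fd_grad_hess(f, t)
    return g, H


# ---------------------------------------------------------------------------
# local fit


def _glm_start(like: SiteLikelihood):
    """Starting values from an ordinary GLM ignoring the random effects."""
    import statsmodels.api as sm

    d = like.design
    XW = np.hstack([d.X, d.W]) if d.W.shape[1] else d.X
    fam = sm.families.Binomial() if d.link == "logit" else sm.families.Gaussian()
    coef = np.zeros(XW.shape[1])
    try:
        with _pywarnings.catch_warnings():
            _pywarnings.simplefilter("ignore")
            res = sm.GLM(d.y, XW, family=fam).fit(maxiter=100)
        if np.all(np.isfinite(res.params)) and np.max(np.abs(res.params)) < 30:
            coef = np.asarray(res.params)
    except Exception:
        pass
    eta = np.full(like.p_gamma, math.log(0.5))
    if d.link == "identity":
        resid = d.y - XW @ coef
        eta[-1] = math.log(max(float(np.var(resid)) * 0.5, 1e-4))
    return np.concatenate([coef, eta])


def _newton_polish(objective, grad_hess, t, *, gtol=1e-8, max_steps=15,
                   ridge=0.0, p_coef=None, lower=None, upper=None):
    """Damped Newton refinement of a maximizer; returns (t, g, H, converged).

    Box bounds (for the log-variance coordinates, whose likelihood flattens
    exponentially as the variance tends to zero) are enforced by projection;
    the gradient criterion still applies because the objective is flat at
    the clamp.
    """

    def project(v):
        if lower is not None:
            v = np.maximum(v, lower)
        if upper is not None:
            v = np.minimum(v, upper)
        return v

    def pinned_mask(v, grad):
        """Coordinates at a bound with the gradient pointing outward."""
        pinned = np.zeros(v.size, dtype=bool)
        if lower is not None:
            pinned |= (v <= lower) & (grad < 0)
        if upper is not None:
            pinned |= (v >= upper) & (grad > 0)
        return pinned

    def kkt(v, grad):
        """Gradient with outward-pointing components at active bounds zeroed."""
        grad = grad.copy()
        grad[pinned_mask(v, grad)] = 0.0
        return grad

    t = project(np.asarray(t, dtype=float))
    f_cur = objective(t)
    g = H = None
    for _ in range(max_steps):
        _, g, H = grad_hess(t)
        if ridge:
            g = g.copy()
            H = H.copy()
            g[:p_coef] -= 2.0 * ridge * t[:p_coef]
            H[np.arange(p_coef), np.arange(p_coef)] -= 2.0 * ridge
        gk = kkt(t, g)
        if np.max(np.abs(gk)) <= gtol:
            return t, g, H, True
        # projected Newton: step only along coordinates not pinned at a bound
        free = ~pinned_mask(t, g)
        if not np.any(free):
            return t, g, H, True
        Jf = -H[np.ix_(free, free)]
        lam = 0.0
        while True:
            try:
                step_f = sla.cho_solve(
                    sla.cho_factor(Jf + lam * np.eye(Jf.shape[0]), lower=True),
                    g[free],
                )
                break
            except sla.LinAlgError:
                lam = max(2.0 * lam, 1e-4)
                if lam > 1e8:
                    return t, g, H, False
        step = np.zeros_like(g)
        step[free] = step_f
        ok = False
        for _ in range(30):
            t_new = project(t + step)
            f_new = objective(t_new)
            if f_new >= f_cur - 1e-10 * max(1.0, abs(f_cur)):
                ok = True
                break
            step *= 0.5
        if not ok or np.max(np.abs(step)) < 1e-13:
            break
        t, f_cur = t_new, f_new
    _, g, H = grad_hess(t)
    if ridge:
        g = g.copy()
        H = H.copy()
        g[:p_coef] -= 2.0 * ridge * t[:p_coef]
        H[np.arange(p_coef), np.arange(p_coef)] -= 2.0 * ridge
    return t, g, H, bool(np.max(np.abs(kkt(t, g))) <= max(gtol, 1e-6))


_RIDGE = 1e-4  # fallback penalty on (beta, alpha) for separated/degenerate sites


def local_fit(site: SiteData, spec: ModelSpec) -> LocalFit:
    """Maximize one site's Laplace log-likelihood over (beta, alpha_k, gamma_k).

    Degenerate sites (constant outcome under the logit link, or a fit that
    fails to produce an invertible information matrix) are refit with a small
    ridge penalty on the fixed effects and flagged, never silently dropped.
    """
    like = SiteLikelihood(site, spec)
    flags: list[str] = []
    ridge = 0.0
    if spec.link == "logit":
        y = like.design.y
        if y.min() == y.max():
            flags.append("separation")
            ridge = _RIDGE

    def run(ridge):
        p_coef = like.p_beta + like.p_alpha
        t0 = _glm_start(like)

        def negf(t):
            val = like.loglik(t)
            if ridge:
                val -= ridge * float(t[:p_coef] @ t[:p_coef])
            return -val

        def negf_grad(t):
            f0, g = like.value_grad(t)
            if ridge:
                f0 -= ridge * float(t[:p_coef] @ t[:p_coef])
                g = g.copy()
                g[:p_coef] -= 2.0 * ridge * t[:p_coef]
            return -f0, -g

        bounds = [_COEF_BOUNDS] * p_coef + [_ETA_BOUNDS] * like.p_gamma
        res = spo.minimize(negf_grad, t0, jac=True, method="L-BFGS-B",
                           bounds=bounds, options={"maxiter": 300})
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        t, g, H, conv = _newton_polish(
            lambda tt: -negf(tt), like.value_grad_hess, res.x,
            ridge=ridge, p_coef=p_coef, lower=lo, upper=hi,
        )
        return t, g, H, conv

    t, g, H, conv = run(ridge)
    J = -H
    try:
        cov = sla.cho_solve(sla.cho_factor(J, lower=True), np.eye(J.shape[0]))
    except sla.LinAlgError:
        if ridge == 0.0:
            flags.append("ridge_fallback")
            ridge = _RIDGE
            t, g, H, conv = run(ridge)
            J = -H
        try:
            cov = sla.cho_solve(sla.cho_factor(J, lower=True), np.eye(J.shape[0]))
        except sla.LinAlgError:
            flags.append("information_pinv")
            cov = np.linalg.pinv(J)
    cov = 0.5 * (cov + cov.T)
    if not conv:
        flags.append("nonconvergence")
    return LocalFit(
        site_id=site.site_id,
        t_hat=t,
        cov=cov,
        loglik=like.loglik(t),
        converged=conv,
        grad_norm=float(np.max(np.abs(g))),
        flags=tuple(flags),
        p_beta=like.p_beta,
        p_alpha=like.p_alpha,
    )


# ---------------------------------------------------------------------------
# pooled (gold standard) fit


def assemble_global_grad_hess(likes, layout: ParamLayout, theta: Theta):
    """Scatter-add per-site gradients/Hessians into the global layout."""
    g = np.zeros(layout.p)
    H = np.zeros((layout.p, layout.p))
    total = 0.0
    for like in likes:
        idx = layout.site_map[like.site_id]
        f0, gk, Hk = like.value_grad_hess(theta.values[idx])
        total += f0
        g[idx] += gk
        H[np.ix_(idx, idx)] += Hk
    return total, g, H


# floor for *initial* log-variances: a local fit that pins a variance at
# (numerically) zero says little about the pooled optimum, and the marginal
# likelihood is exponentially flat in log-variance below this point, so a
# Newton iteration started there can never move the coordinate.  The floor
# only affects the starting value, never the estimate.
_INIT_ETA_FLOOR = -2.0


def inverse_variance_start(local_fits, layout: ParamLayout) -> Theta:
    """Initial theta: inverse-variance-weighted beta (and shared blocks);
    per-site blocks set to the local estimates, with boundary log-variances
    floored at _INIT_ETA_FLOOR."""
    spec = layout.spec
    fits = {f.site_id: f for f in local_fits}
    if set(fits) != set(layout.site_ids):
        raise ModelError("local fits do not match layout site ids")
    values = np.zeros(layout.p)

    def combine(block_name, extract):
        """extract(fit) -> (estimate, covariance block) on the local scale."""
        num, den, used = 0.0, 0.0, 0
        dim = layout.blocks[block_name].stop - layout.blocks[block_name].start
        num = np.zeros(dim)
        den = np.zeros((dim, dim))
        for sid in layout.site_ids:
            est, covb = extract(fits[sid])
            try:
                w = sla.cho_solve(sla.cho_factor(covb, lower=True), np.eye(dim))
            except sla.LinAlgError:
                continue
            den += w
            num += w @ est
            used += 1
        if used == 0:
            raise ModelError(f"all site covariances singular for {block_name}")
        return np.linalg.solve(den, num)

    pb, pa, pg = layout.p_beta, layout.p_alpha, layout.p_gamma
    values[layout.blocks["beta"]] = combine(
        "beta", lambda f: (f.t_hat[:pb], f.cov[:pb, :pb])
    )
    if "alpha" in layout.blocks:
        sl = slice(pb, pb + pa)
        values[layout.blocks["alpha"]] = combine(
            "alpha", lambda f: (f.t_hat[sl], f.cov[sl, sl])
        )
    if "gamma" in layout.blocks:
        sl = slice(pb + pa, pb + pa + pg)
        values[layout.blocks["gamma"]] = combine(
            "gamma", lambda f: (f.t_hat[sl], f.cov[sl, sl])
        )
    for sid in layout.site_ids:
        f = fits[sid]
        if not spec.alpha_shared and pa:
            values[layout.blocks[f"alpha[{sid}]"]] = f.t_hat[pb : pb + pa]
        if not spec.gamma_shared:
            values[layout.blocks[f"gamma[{sid}]"]] = f.t_hat[pb + pa :]
    gam = np.array([lab.startswith("gamma") for lab in layout.labels])
    values[gam] = np.maximum(values[gam], _INIT_ETA_FLOOR)
    return Theta(layout, values)


def pooled_fit(
    sites,
    spec: ModelSpec,
    *,
    local_fits=None,
    gtol: float = 1e-8,
    max_newton: int = 40,
) -> PooledResult:
    """Directly maximize the summed Laplace log-likelihoods over all sites.

    This is the gold-standard estimator every federated run is measured
    against: quasi-Newton from an inverse-variance-weighted start, then
    damped Newton refinement until the assembled gradient is negligible.
    """
    if not sites:
        raise ModelError("pooled_fit requires at least one site")
    likes = [SiteLikelihood(s, spec) for s in sites]
    layout = ParamLayout(spec, [s.site_id for s in sites])
    if local_fits is None:
        local_fits = [local_fit(s, spec) for s in sites]
    theta0 = inverse_variance_start(local_fits, layout)
    warn: list[str] = []

    def negf_grad(v):
        th = Theta(layout, v)
        total, g = 0.0, np.zeros(layout.p)
        for like in likes:
            idx = layout.site_map[like.site_id]
            f0, gk = like.value_grad(th.values[idx])
            total += f0
            g[idx] += gk
        return -total, -g

    bounds = [
        _ETA_BOUNDS if lab.startswith("gamma") else _COEF_BOUNDS
        for lab in layout.labels
    ]
    res = spo.minimize(negf_grad, theta0.values, jac=True, method="L-BFGS-B",
                       bounds=bounds, options={"maxiter": 500})
    theta = Theta(layout, res.x)

    def objective(v):
        return -negf_grad(v)[0]

    def grad_hess(v):
        return assemble_global_grad_hess(likes, layout, Theta(layout, v))

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    vals, g, H, conv = _newton_polish(objective, grad_hess, theta.values,
                                      gtol=gtol, max_steps=max_newton,
                                      lower=lo, upper=hi)
    theta = Theta(layout, vals)
    J = -H
    try:
        cov = sla.cho_solve(sla.cho_factor(J, lower=True), np.eye(layout.p))
    except sla.LinAlgError:
        warn.append("covariance_pinv")
        cov = np.linalg.pinv(J)
    cov = 0.5 * (cov + cov.T)
    if not conv:
        warn.append("nonconvergence")
    return PooledResult(
        theta=theta,
        covariance=cov,
        loglik=objective(vals),
        grad_norm=float(np.max(np.abs(g))),
        converged=conv,
        warnings=tuple(warn),
        local_fits=local_fits,
    )
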