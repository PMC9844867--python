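"""Federated GLMM fitting by exchanging gradients and Hessians.

The algorithm: (1) every site fits its GLMM locally and ships its beta
estimate with its covariance; the coordinator combines them by
inverse-variance weighting to initialize the common effects, while each
site's delta_k starts at its own local estimate.  (2) Each site evaluates
the gradient s_k and Hessian H_k of its Laplace log-likelihood at the
current theta and ships only those (fewer than p^2 numbers).  (3) The
coordinator assembles the quadratic surrogate of the global log-likelihood
— exact to second order at the expansion point — and maximizes it, which is
one Newton step exploiting the arrow structure of the global Hessian
(dense common block, block-diagonal site blocks, cross-site blocks
identically zero because sites are independent).  Steps 2-3 repeat until
the iteration budget T is exhausted or the step norm falls below d.

The covariance of the federated estimator is the inverse negated surrogate
Hessian evaluated at the final iterate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from . import model_core as mc
from .parameters import ParamLayout, Theta


class ProtocolError(ValueError):
    """Summary statistics inconsistent with the coordinator's state."""


@dataclass(frozen=True)
class FedConfig:
    """Iteration control for the federated optimizer.

    max_iter: communication budget T (outer Newton steps).
    tol: convergence threshold d on the L2 step norm.
    damping0: initial Levenberg shift when the negated Hessian is not
        positive definite; doubled until it is.
    max_step: per-coordinate cap on a single update.  Rare-event sites can
        leave log-variance directions nearly flat, producing huge Newton
        components there; capping coordinates individually contains them
        without rescaling (and thereby stalling) the informative ones.
        Capped steps are flagged.
    """

    max_iter: int = 5
    tol: float = 1e-6
    damping0: float = 1e-4
    max_step: float = 2.0
    recompute_covariance: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")


@dataclass
class SummaryStats:
    """One site's shareable derivatives at a stated evaluation point."""

    site_id: str
    iteration: int
    eval_digest: str
    labels: tuple[str, ...]
    s: np.ndarray  # gradient over (beta, delta_k)
    H: np.ndarray  # Hessian over (beta, delta_k), symmetric
    loglik: float  # lhat_k at the evaluation point

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        p = self.s.size
        if self.H.shape != (p, p):
            raise ProtocolError(f"site {self.site_id}: s/H dimension mismatch")
        if np.max(np.abs(self.H - self.H.T)) > 1e-8 * max(
            1.0, float(np.max(np.abs(self.H)))
        ):
            raise ProtocolError(f"site {self.site_id}: Hessian not symmetric")
        self.H = 0.5 * (self.H + self.H.T)

    @property
    def payload_numbers(self) -> int:
        """Count of scalars actually shared: s, lower triangle of H, lhat."""
        p = self.s.size
        return p + p * (p + 1) // 2 + 1


@dataclass
class SurrogateState:
    """Assembled quadratic surrogate of the global log-likelihood at theta_bar."""

    theta_bar: Theta
    grad: np.ndarray
    hess: np.ndarray
    const: float  # sum of site log-likelihood values at theta_bar

    def value(self, theta: Theta | np.ndarray) -> float:
        v = theta.values if isinstance(theta, Theta) else np.asarray(theta)
        d = v - self.theta_bar.values
        return float(self.const + self.grad @ d + 0.5 * d @ self.hess @ d)

    def gradient(self, theta: Theta | np.ndarray) -> np.ndarray:
        v = theta.values if isinstance(theta, Theta) else np.asarray(theta)
        return self.grad + self.hess @ (v - self.theta_bar.values)


@dataclass
class FitResult:
    """Federated estimate with covariance and full iteration trace."""

    theta: Theta
    covariance: np.ndarray
    trace: np.ndarray  # (iterations used + 1, p)
    deltas: np.ndarray  # L2 step norms, one per iteration performed
    iterations: int
    converged: bool
    warnings: tuple[str, ...]
    local_fits: list | None = None
    loglik: float | None = None

    @property
    def std_errors(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def theta_at(self, iteration: int) -> Theta:
        """Iterate after `iteration` surrogate updates (0 = initial value)."""
        if iteration >= self.trace.shape[0]:
            iteration = self.trace.shape[0] - 1
        return Theta(self.theta.layout, self.trace[iteration].copy())


def meta_initialize(local_fits, layout: ParamLayout) -> Theta:
    """Inverse-variance meta-analysis initialization of theta.

    beta_bar = (sum V_k^{-1})^{-1} sum V_k^{-1} beta_bar_k with full matrix
    weights; shared alpha/gamma blocks are combined by the same rule; each
    site-specific block starts at its own local estimate.  Sites with a
    singular V_k are dropped from the weighted averages (their delta_k is
    still used).
    """
    return mc.inverse_variance_start(local_fits, layout)


def compute_summary(
    site, spec: mc.ModelSpec | None, theta_bar: Theta, iteration: int = 0
) -> SummaryStats:
    """Evaluate one site's (s_k, H_k, lhat_k) at theta_bar.

    Accepts either a SiteData (a design is built) or a prebuilt
    SiteLikelihood.  The payload carries no row-level data.
    """
    if isinstance(site, mc.SiteLikelihood):
        like = site
    else:
        like = mc.SiteLikelihood(site, spec)
    t = theta_bar.site_vector(like.site_id)
    try:
        f0, g, H = like.value_grad_hess(t)
    except mc.InnerModeError as e:
        raise mc.InnerModeError(
            f"summary statistics failed at site {like.site_id}: {e}"
        ) from e
    return SummaryStats(
        site_id=like.site_id,
        iteration=iteration,
        eval_digest=theta_bar.site_digest(like.site_id),
        labels=tuple(theta_bar.layout.local_labels(like.site_id)),
        s=g,
        H=H,
        loglik=f0,
    )


def assemble_surrogate(summaries, theta_bar: Theta) -> SurrogateState:
    """Scatter-add site derivatives into the global surrogate at theta_bar.

    Under homogeneity flags, site contributions to shared blocks accumulate
    by summation; cross-site blocks remain exactly zero.
    """
    layout = theta_bar.layout
    seen = set()
    grad = np.zeros(layout.p)
    hess = np.zeros((layout.p, layout.p))
    const = 0.0
    for s in summaries:
        if s.site_id in seen:
            raise ProtocolError(f"duplicate summary for site {s.site_id}")
        seen.add(s.site_id)
        if s.site_id not in layout.site_map:
            raise ProtocolError(f"unknown site {s.site_id}")
        idx = layout.site_map[s.site_id]
        if s.s.size != idx.size:
            raise ProtocolError(
                f"site {s.site_id}: dimension {s.s.size}, expected {idx.size}"
            )
        expected = theta_bar.site_digest(s.site_id)
        if s.eval_digest != expected:
            raise ProtocolError(
                f"site {s.site_id}: evaluation-point digest mismatch "
                "(summaries were computed at a different theta)"
            )
        grad[idx] += s.s
        hess[np.ix_(idx, idx)] += s.H
        const += s.loglik
    if seen != set(layout.site_ids):
        raise ProtocolError(f"missing summaries for {set(layout.site_ids) - seen}")
    return SurrogateState(theta_bar=theta_bar, grad=grad, hess=hess, const=const)


def _arrow_solve(J, g, layout: ParamLayout):
    """Solve J x = g via the Schur complement on the shared block.

    J has arrow structure: shared rows/columns are dense, site blocks are
    block diagonal.  Raises LinAlgError if any block is not positive
    definite.
    """
    s_idx = layout.shared_idx
    site_blocks = [layout.site_block_idx[sid] for sid in layout.site_ids]
    S = J[np.ix_(s_idx, s_idx)].copy()
    rhs = g[s_idx].copy()
    cache = []
    for idx in site_blocks:
        if idx.size == 0:
            cache.append(None)
            continue
        Jkk = J[np.ix_(idx, idx)]
        Jks = J[np.ix_(idx, s_idx)]
        cho = sla.cho_factor(Jkk, lower=True)
        Y = sla.cho_solve(cho, Jks)  # Jkk^{-1} Jks
        z = sla.cho_solve(cho, g[idx])
        S -= Jks.T @ Y
        rhs -= Jks.T @ z
        cache.append((cho, Jks, z, Y))
    x = np.zeros_like(g)
    x[s_idx] = sla.cho_solve(sla.cho_factor(S, lower=True), rhs)
    for idx, c in zip(site_blocks, cache):
        if c is None:
            continue
        cho, Jks, z, Y = c
        x[idx] = z - Y @ x[s_idx]
    return x


def surrogate_update(state: SurrogateState, config: FedConfig | None = None):
    """Maximize the quadratic surrogate: one structured Newton step.

    Returns (theta_new, warnings).  When the negated Hessian is not positive
    definite a Levenberg shift is added (doubled until factorization
    succeeds) and the step is flagged; oversized steps are norm-capped.
    """
    config = config or FedConfig()
    layout = state.theta_bar.layout
    J = -state.hess
    warnings: list[str] = []
    try:
        step = _arrow_solve(J, state.grad, layout)
    except sla.LinAlgError:
        # negated Hessian not positive definite (typical for variance
        # blocks of rare-event sites far from the optimum): flip negative
        # curvature and floor tiny eigenvalues, then step
        w, V = sla.eigh(J)
        floor = max(config.damping0, 1e-8 * float(np.max(np.abs(w))))
        winv = 1.0 / np.maximum(np.abs(w), floor)
        step = V @ (winv * (V.T @ state.grad))
        warnings.append("saddle_free_newton")
    big = float(np.max(np.abs(step)))
    if big > config.max_step:
        step = np.clip(step, -config.max_step, config.max_step)
        warnings.append(f"step_capped(max={big:.3g})")
    new_vals = state.theta_bar.values + step
    # keep variance components in the same box the local fits use; the
    # likelihood is exponentially flat beyond it
    gam = np.array([lab.startswith("gamma") for lab in layout.labels])
    lo, hi = mc._ETA_BOUNDS
    clipped = np.clip(new_vals[gam], lo, hi)
    if np.any(clipped != new_vals[gam]):
        warnings.append("gamma_clamped")
        new_vals[gam] = clipped
    return state.theta_bar.replace(new_vals), warnings


def estimate_covariance(state: SurrogateState):
    """Var(theta_Fed) = (-H_Fed)^{-1} at the assembled state.

    Returns (covariance, flags); a non-positive-definite information matrix
    falls back to the pseudo-inverse with a flag.
    """
    J = -state.hess
    flags: list[str] = []
    try:
        cov = sla.cho_solve(sla.cho_factor(J, lower=True), np.eye(J.shape[0]))
    except sla.LinAlgError:
        flags.append("covariance_pinv")
        cov = np.linalg.pinv(J)
    return 0.5 * (cov + cov.T), flags


def fed_glmm(
    sites,
    spec: mc.ModelSpec,
    config: FedConfig | None = None,
    *,
    init: Theta | None = None,
    local_fits=None,
) -> FitResult:
    """Run the full federated algorithm on locally available sites.

    Step 1 (local fits + meta-analysis initialization) is skipped when an
    explicit `init` is given.  Precomputed `local_fits` may be passed to
    avoid refitting when the caller already has them.
    """
    if not sites:
        raise mc.ModelError("fed_glmm requires at least one site")
    config = config or FedConfig()
    likes = [mc.SiteLikelihood(s, spec) for s in sites]
    layout = ParamLayout(spec, [s.site_id for s in sites])
    if init is not None:
        theta = init if isinstance(init, Theta) else Theta(layout, init)
        if theta.layout.p != layout.p:
            raise mc.ModelError("init theta does not match the site layout")
    else:
        if local_fits is None:
            local_fits = [mc.local_fit(s, spec) for s in sites]
        theta = meta_initialize(local_fits, layout)

    warnings: list[str] = []
    if local_fits:
        for lf in local_fits:
            for fl in lf.flags:
                warnings.append(f"local_fit[{lf.site_id}]:{fl}")

    trace = [theta.values.copy()]
    deltas: list[float] = []
    converged = False
    state = None
    for t_iter in range(1, config.max_iter + 1):
        summaries = [
            compute_summary(like, spec, theta, iteration=t_iter) for like in likes
        ]
        state = assemble_surrogate(summaries, theta)
        theta_new, w = surrogate_update(state, config)
        warnings.extend(f"iter{t_iter}:{x}" for x in w)
        delta = float(np.linalg.norm(theta_new.values - theta.values))
        deltas.append(delta)
        theta = theta_new
        trace.append(theta.values.copy())
        if delta <= config.tol:
            converged = True
            break

    if config.recompute_covariance or state is None:
        summaries = [
            compute_summary(like, spec, theta, iteration=len(deltas) + 1)
            for like in likes
        ]
        state = assemble_surrogate(summaries, theta)
    cov, cflags = estimate_covariance(state)
    warnings.extend(cflags)
    return FitResult(
        theta=theta,
        covariance=cov,
        trace=np.asarray(trace),
        deltas=np.asarray(deltas),
        iterations=len(deltas),
        converged=converged,
        warnings=tuple(warnings),
        local_fits=local_fits,
        loglik=state.const,
    )
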