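"""Synthetic multi-site EHR generator and accuracy-experiment harness.

The generator emulates encounter-level logistic data: per site k, a binary
outcome with

    logit P(y=1) = beta0 + x1 + 0.5 x2 + 0.5 x3 + alpha_k x4 + b_jk,

x1 ~ Bernoulli(p_x) (the binary exposure), x2 ~ Uniform(0,1),
x3 ~ Bernoulli(0.5), x4 ~ N(0,1), and a patient-level random intercept
b_jk ~ N(0, gamma_k).  Site-level heterogeneity comes from distinct
alpha_k spanning [0,1] and distinct gamma_k spanning (0,2].  The intercept
beta0 is solved so that the marginal outcome prevalence hits a target.

An optional crossed variant adds a physician-level random intercept with
community structure in the patient-physician assignment, used by the
data-splitting experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import federation as fed
from . import model_core as mc
from .parameters import ParamLayout


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic multi-site generator."""

    K: int = 8
    n_patients: tuple[int, int] = (100, 450)  # per-site range, inclusive
    encounters: int = 5
    p_x: float = 0.25  # exposure prevalence
    p_y: float = 0.25  # target marginal outcome prevalence
    beta0: float | None = None  # solved from p_y when None
    beta_exposure: float = 1.0
    beta_x2: float = 0.5
    beta_x3: float = 0.5
    alpha_values: tuple[float, ...] | None = None  # default: spread over [0,1]
    gamma_values: tuple[float, ...] | None = None  # default: spread over (0,2]
    per_patient_exposure: bool = False
    # crossed design (physician random intercept), 0 physicians = disabled
    physicians_per_site: int = 0
    communities: int = 1
    cross_prob: float = 0.1
    gamma_physician: float = 0.5
    seed: int = 0  # master seed fixing the site-effect assignment

    def __post_init__(self):
        if not (0.0 < self.p_x < 1.0 and 0.0 < self.p_y < 1.0):
            raise ValueError("prevalences must be in (0, 1)")
        if self.n_patients[0] > self.n_patients[1]:
            raise ValueError("n_patients range inverted")

    def site_effects(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alpha_k, gamma_k): evenly spaced values over their
        stated ranges, shuffled by the master seed so every configuration is
        reproducible."""
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 104729]))
        if self.alpha_values is not None:
            alphas = np.asarray(self.alpha_values, dtype=float)
        else:
            alphas = rng.permutation(np.linspace(0.0, 1.0, self.K))
        if self.gamma_values is not None:
            gammas = np.asarray(self.gamma_values, dtype=float)
        else:
            # evenly spaced over (0, 2]; exactly 0 is degenerate under the
            # log-variance parameterization
            gammas = rng.permutation(np.linspace(0.0, 2.0, self.K + 1)[1:])
        if alphas.size != self.K or gammas.size != self.K:
            raise ValueError("alpha/gamma value lists must have length K")
        if np.any(gammas < 0):
            raise ValueError("variance components must be >= 0")
        return alphas, gammas


def model_spec_for(
    config: SimConfig, *, alpha_shared: bool = False, gamma_shared: bool = False
) -> mc.ModelSpec:
    """The GLMM specification matching the generator's column conventions."""
    factors = [mc.RandomFactor("patient_id")]
    if config.physicians_per_site > 0:
        factors.append(mc.RandomFactor("physician_id"))
    return mc.ModelSpec(
        link="logit",
        common=("const", "x1", "x2", "x3"),
        site_specific=("x4",),
        factors=tuple(factors),
        alpha_shared=alpha_shared,
        gamma_shared=gamma_shared,
    )


def solve_intercept(p_y: float, config: SimConfig, n_draws: int = 100_000) -> float:
    """Intercept beta0 giving marginal outcome prevalence p_y.

    Root-found on a large fixed-seed Monte-Carlo sample of the linear
    predictor under the full generative model (site mixture, covariates and
    random intercepts), so repeated calls are deterministic.
    """
    if not 0.0 < p_y < 1.0:
        raise ValueError("p_y must be in (0, 1)")
    alphas, gammas = config.site_effects()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 15485863]))
    site = rng.integers(0, config.K, n_draws)
    x1 = rng.random(n_draws) < config.p_x
    x2 = rng.random(n_draws)
    x3 = rng.random(n_draws) < 0.5
    x4 = rng.standard_normal(n_draws)
    b = rng.standard_normal(n_draws) * np.sqrt(gammas[site])
    lp = (
        config.beta_exposure * x1
        + config.beta_x2 * x2
        + config.beta_x3 * x3
        + alphas[site] * x4
        + b
    )

    def f(b0):
        return float(np.mean(expit(b0 + lp))) - p_y

    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("intercept search does not bracket the target prevalence")
    return float(brentq(f, lo, hi, xtol=1e-10))


def _simulate_one_site(config, k, alpha, gamma, beta0, rng) -> mc.SiteData:
    n_pat = int(rng.integers(config.n_patients[0], config.n_patients[1] + 1))
    enc = config.encounters
    n = n_pat * enc
    pat = np.repeat(np.arange(n_pat), enc)
    b_pat = rng.normal(0.0, np.sqrt(gamma), n_pat)

    if config.per_patient_exposure:
        x1 = (rng.random(n_pat) < config.p_x).astype(float)[pat]
    else:
        x1 = (rng.random(n) < config.p_x).astype(float)
    x2 = rng.random(n)
    x3 = (rng.random(n) < 0.5).astype(float)
    x4 = rng.standard_normal(n)

    lp = (
        beta0
        + config.beta_exposure * x1
        + config.beta_x2 * x2
        + config.beta_x3 * x3
        + alpha * x4
        + b_pat[pat]
    )

    cols = {}
    if config.physicians_per_site > 0:
        P, C = config.physicians_per_site, max(1, config.communities)
        phys_comm = np.arange(P) % C
        by_comm = [np.flatnonzero(phys_comm == c) for c in range(C)]
        pat_comm = rng.integers(0, C, n_pat)
        phys = np.empty(n, dtype=int)
        cross = rng.random(n) < config.cross_prob
        for i in range(n):
            pool = np.arange(P) if cross[i] else by_comm[pat_comm[pat[i]]]
            phys[i] = pool[rng.integers(0, pool.size)]
        b_phys = rng.normal(0.0, np.sqrt(config.gamma_physician), P)
        lp = lp + b_phys[phys]
        cols["physician_id"] = np.array([f"d{j:03d}" for j in phys])

    y = (rng.random(n) < expit(lp)).astype(float)
    tab = pd.DataFrame(
        {
            "site_id": f"site{k}",
            "patient_id": np.array([f"p{j:05d}" for j in pat]),
            "y": y,
            "const": 1.0,
            "x1": x1,
            "x2": x2,
            "x3": x3,
            "x4": x4,
            **cols,
        }
    )
    return mc.SiteData(site_id=f"site{k}", table=tab)


def simulate_sites(config: SimConfig, seed: int) -> list[mc.SiteData]:
    """Draw one replicate of the K-site study; byte-reproducible per seed."""
    alphas, gammas = config.site_effects()
    beta0 = config.beta0 if config.beta0 is not None else solve_intercept(
        config.p_y, config
    )
    children = np.random.SeedSequence([int(seed), 32452843]).spawn(config.K)
    return [
        _simulate_one_site(config, k, alphas[k], gammas[k], beta0,
                           np.random.default_rng(children[k]))
        for k in range(config.K)
    ]


def relative_bias(estimate: float, pooled_estimate: float) -> float:
    """|estimate - pooled| / |pooled| for a focal coefficient."""
    if pooled_estimate == 0:
        raise ZeroDivisionError("pooled estimate is zero")
    return abs(estimate - pooled_estimate) / abs(pooled_estimate)


_EXPOSURE = "beta:x1"


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def run_bias_grid(
    cells,
    replicates: int,
    config: SimConfig,
    seed: int,
    iterations: tuple[int, ...] = (1, 2, 5),
) -> pd.DataFrame:
    """Accuracy grid: per (p_y, p_x) cell and replicate, the relative bias of
    the meta-analysis and of the federated estimator after 1, 2 and 5
    iterations, all against the pooled gold standard.

    Failed pooled fits are recorded with status="pooled_failed" rather than
    dropped.  Returns a long table with one row per (cell, replicate, method).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    methods = ["meta"] + [f"fed{i}" for i in iterations]
    rows = []
    for ci, (p_y, p_x) in enumerate(cells):
        cfg = replace(config, p_y=p_y, p_x=p_x, beta0=None)
        cfg = replace(cfg, beta0=solve_intercept(p_y, cfg))
        spec = model_spec_for(cfg)
        for r in range(replicates):
            rep_seed = _derived_seed(seed, ci, r)
            sites = simulate_sites(cfg, rep_seed)
            layout = ParamLayout(spec, [s.site_id for s in sites])
            bx = layout.labels.index(_EXPOSURE)
            status = "ok"
            try:
                local_fits = [mc.local_fit(s, spec) for s in sites]
                pooled = mc.pooled_fit(sites, spec, local_fits=local_fits)
                pooled_est = float(pooled.theta.values[bx])
                meta_est = float(
                    fed.meta_initialize(local_fits, layout).values[bx]
                )
                result = fed.fed_glmm(
                    sites,
                    spec,
                    fed.FedConfig(max_iter=max(iterations), tol=1e-14,
                                  recompute_covariance=False),
                    local_fits=local_fits,
                )
                estimates = {"meta": meta_est}
                for i in iterations:
                    estimates[f"fed{i}"] = float(result.theta_at(i).values[bx])
            except Exception:
                status = "pooled_failed"
                pooled_est = np.nan
                estimates = {m: np.nan for m in methods}
            for m in methods:
                est = estimates[m]
                rb = (
                    relative_bias(est, pooled_est)
                    if status == "ok" and pooled_est != 0
                    else np.nan
                )
                rows.append(
                    {
                        "p_y": p_y,
                        "p_x": p_x,
                        "replicate": r,
                        "seed": rep_seed,
                        "method": m,
                        "estimate": est,
                        "pooled_estimate": pooled_est,
                        "relative_bias": rb,
                        "status": status,
                    }
                )
    return pd.DataFrame(rows)


def summarize_bias(table: pd.DataFrame) -> pd.DataFrame:
    """Median relative bias per cell and method."""
    return (
        table.groupby(["p_y", "p_x", "method"], as_index=False)["relative_bias"]
        .median()
        .rename(columns={"relative_bias": "median_relative_bias"})
    )


def run_split_scaling(
    config: SimConfig,
    subset_counts,
    replicates: int,
    seed: int,
    fed_iterations: int = 5,
) -> pd.DataFrame:
    """Subset-scaling accuracy: one centralized dataset per replicate, split
    into m subsets; relative bias of the meta-analysis and of the federated
    estimator versus the pooled fit on the unsplit data.

    The configuration should be homogeneous (single alpha/gamma value);
    fitting uses shared alpha and gamma so the parameter dimension does not
    grow with m.
    """
    from . import partitioning as pt

    spec = model_spec_for(config, alpha_shared=True, gamma_shared=True)
    cfg = config if config.beta0 is not None else replace(
        config, beta0=solve_intercept(config.p_y, config)
    )
    rows = []
    for r in range(replicates):
        rep_seed = _derived_seed(seed, 9001, r)
        (site,) = simulate_sites(replace(cfg, K=1), rep_seed)
        pooled = mc.pooled_fit([site], spec)
        bx = pooled.theta.layout.labels.index(_EXPOSURE)
        pooled_est = float(pooled.theta.values[bx])
        for m in subset_counts:
            plan = pt.random_split(site, m, _derived_seed(seed, 9002, r, m))
            subsets = plan.subsets(site)
            layout = ParamLayout(spec, [s.site_id for s in subsets])
            local_fits = [mc.local_fit(s, spec) for s in subsets]
            meta_est = float(
                fed.meta_initialize(local_fits, layout).values[
                    layout.labels.index(_EXPOSURE)
                ]
            )
            result = fed.fed_glmm(
                subsets,
                spec,
                fed.FedConfig(max_iter=fed_iterations, tol=1e-14,
                              recompute_covariance=False),
                local_fits=local_fits,
            )
            fed_est = float(
                result.theta.values[layout.labels.index(_EXPOSURE)]
            )
            for method, est in (("meta", meta_est), (f"fed{fed_iterations}", fed_est)):
                rows.append(
                    {
                        "replicate": r,
                        "m": m,
                        "method": method,
                        "estimate": est,
                        "pooled_estimate": pooled_est,
                        "relative_bias": relative_bias(est, pooled_est),
                        "seed": rep_seed,
                    }
                )
    return pd.DataFrame(rows)
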