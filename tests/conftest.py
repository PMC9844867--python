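"""Shared fixtures: small synthetic logistic and Gaussian sites."""

import numpy as np
import pandas as pd
import pytest

import fedglmm as fg


def make_logit_site(
    site_id="s1",
    n_patients=80,
    encounters=5,
    beta=(-0.5, 1.0, 0.5),
    alpha=(0.4,),
    gamma=1.2,
    seed=0,
):
    """Logistic site with a patient random intercept.

    Columns: const, x1 (binary), x2 (normal) for beta; x4 (normal) for alpha.
    """
    rng = np.random.default_rng(seed)
    n = n_patients * encounters
    pat = np.repeat(np.arange(n_patients), encounters)
    x1 = (rng.random(n) < 0.4).astype(float)
    x2 = rng.standard_normal(n)
    x4 = rng.standard_normal(n)
    b = rng.normal(0, np.sqrt(gamma), n_patients)
    lp = beta[0] + beta[1] * x1 + beta[2] * x2 + alpha[0] * x4 + b[pat]
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    tab = pd.DataFrame(
        {
            "patient_id": [f"p{j}" for j in pat],
            "y": y,
            "const": 1.0,
            "x1": x1,
            "x2": x2,
            "x4": x4,
        }
    )
    return fg.SiteData(site_id=site_id, table=tab)


def make_gaussian_site(
    site_id="g1",
    n_patients=40,
    encounters=4,
    beta=(1.0, -0.5),
    gamma=1.0,
    sigma2=0.5,
    seed=0,
):
    """Gaussian-identity site with a patient random intercept."""
    rng = np.random.default_rng(seed)
    n = n_patients * encounters
    pat = np.repeat(np.arange(n_patients), encounters)
    x1 = rng.standard_normal(n)
    b = rng.normal(0, np.sqrt(gamma), n_patients)
    y = beta[0] + beta[1] * x1 + b[pat] + rng.normal(0, np.sqrt(sigma2), n)
    tab = pd.DataFrame(
        {
            "patient_id": [f"p{j}" for j in pat],
            "y": y,
            "const": 1.0,
            "x1": x1,
        }
    )
    return fg.SiteData(site_id=site_id, table=tab)


LOGIT_SPEC = fg.ModelSpec(
    link="logit",
    common=("const", "x1", "x2"),
    site_specific=("x4",),
    factors=(fg.RandomFactor("patient_id"),),
)

GAUSS_SPEC = fg.ModelSpec(
    link="identity",
    common=("const", "x1"),
    factors=(fg.RandomFactor("patient_id"),),
)


@pytest.fixture(scope="session")
def logit_site():
    return make_logit_site()


@pytest.fixture(scope="session")
def gaussian_site():
    return make_gaussian_site()


@pytest.fixture(scope="session")
def logit_sites_3():
    return [
        make_logit_site(site_id=f"s{k}", n_patients=50 + 10 * k, seed=10 + k)
        for k in range(3)
    ]
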