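"""Latent-scale vs data-scale variance components for the Poisson log-link
model.

A log-link GLMM estimates variance components on the scale of the linear
predictor (the latent scale).  For counts y | eta ~ Poisson(exp(eta)) with
eta ~ N(mu, s2) the observed counts are lognormal-Poisson, and all data-scale
quantities have closed forms:

    mean_obs   = exp(mu + s2/2)
    var_obs    = mean_obs + mean_obs^2 * (exp(s2) - 1)
    s2_A_obs   = mean_obs^2 * sigma2_A          (Psi^2 * sigma2_A with
                                                 Psi = E[d exp(eta)/d eta])
    h2_obs     = s2_A_obs / var_obs

With per-record linear predictors mu_i (fixed effects), the closed forms are
averaged over the empirical predictor distribution, which also folds the
fixed-effect variance into var_obs.  Heritability on the data scale is always
below the latent-scale value when non-additive latent variance is present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import PosteriorChain

__all__ = [
    "LatentParameters",
    "DataScaleParameters",
    "h2_latent",
    "poisson_log_data_scale",
    "poisson_log_data_scale_quadrature",
    "data_scale_chain",
]


@dataclass
class LatentParameters:
    mu: float | np.ndarray
    sigma2_A: float
    sigma2_rest: float

    def __post_init__(self) -> None:
        if self.sigma2_A < 0 or self.sigma2_rest < 0:
            raise ValueError("variances must be non-negative")


@dataclass
class DataScaleParameters:
    mean_obs: float
    var_obs: float
    sigma2_A_obs: float
    h2_obs: float


def h2_latent(sigma2_A: float, sigma2_rest: float) -> float:
    """Latent-scale narrow-sense heritability sigma2_A / (sigma2_A + rest),
    where rest is the sum of every non-additive latent variance component."""
    if sigma2_A < 0 or sigma2_rest < 0:
        raise ValueError("variances must be non-negative")
    total = sigma2_A + sigma2_rest
    if total == 0:
        raise ValueError("heritability undefined when all variances are zero")
    return sigma2_A / total


def poisson_log_data_scale(p: LatentParameters) -> DataScaleParameters:
    """Exact closed-form conversion of latent parameters to the data scale."""
    s2 = p.sigma2_A + p.sigma2_rest
    mu = np.atleast_1d(np.asarray(p.mu, dtype=float))
    lam = np.exp(mu + s2 / 2.0)        # E[y | record]
    mean_obs = float(lam.mean())
    # E[y^2 | record] = lam + lam^2 * exp(s2); averaging keeps the
    # fixed-effect spread of the lam_i inside var_obs
    ey2 = lam + lam**2 * np.exp(s2)
    var_obs = float(ey2.mean() - mean_obs**2)
    s2_A_obs = mean_obs**2 * p.sigma2_A
    h2 = s2_A_obs / var_obs if var_obs > 0 else 0.0
    return DataScaleParameters(mean_obs, var_obs, s2_A_obs, h2)


def poisson_log_data_scale_quadrature(
    p: LatentParameters, n_nodes: int = 64,
) -> DataScaleParameters:
    """Gauss-Hermite evaluation of the same conversion.

    Kept as an independent numerical path for validating the closed forms
    (and as a template for families without closed forms).
    """
    s2 = p.sigma2_A + p.sigma2_rest
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    mu = np.atleast_1d(np.asarray(p.mu, dtype=float))
    eta = mu[:, None] + np.sqrt(s2) * nodes[None, :]
    w = weights / weights.sum()
    lam_rec = np.exp(eta) @ w                       # E[y | record]
    ey2_rec = (np.exp(eta) + np.exp(2 * eta)) @ w   # E[y^2 | record]
    mean_obs = float(lam_rec.mean())
    var_obs = float(ey2_rec.mean() - mean_obs**2)
    # Psi = E[exp(eta)] averaged over records
    s2_A_obs = float(lam_rec.mean()) ** 2 * p.sigma2_A
    h2 = s2_A_obs / var_obs if var_obs > 0 else 0.0
    return DataScaleParameters(mean_obs, var_obs, s2_A_obs, h2)


def data_scale_chain(
    chain: PosteriorChain, site: str = "mean",
) -> "np.recarray | object":
    """Convert every posterior draw to data-scale parameters.

    For each draw the vector of fitted fixed-effect predictors X beta is
    used as mu (marginalizing over the observed covariate combinations) and
    the closed-form conversion applied.  Returns a DataFrame with columns
    mean_obs, var_obs, sigma2_A_obs, h2_obs, h2_latent.
    """
    import pandas as pd

    if chain.family != "poisson-log":
        raise ValueError("data-scale conversion applies to the poisson-log family")
    if chain.design is None:
        raise ValueError("chain carries no design; cannot form fitted predictors")
    X = chain.design.X
    betas = chain.beta_draws()
    sa = chain.draws["sigma2_A"].to_numpy()
    rest = chain.sigma2_rest(site=site)
    rows = np.empty((len(chain), 4))
    for k in range(len(chain)):
        d = poisson_log_data_scale(LatentParameters(X @ betas[k], sa[k], rest[k]))
        rows[k] = (d.mean_obs, d.var_obs, d.sigma2_A_obs, d.h2_obs)
    out = pd.DataFrame(rows, columns=["mean_obs", "var_obs", "sigma2_A_obs", "h2_obs"])
    out["h2_latent"] = sa / (sa + rest)
    return out
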