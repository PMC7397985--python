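"""Selection-response arithmetic for the extra-pair offspring count.

Pure algebra around the breeder's equation and its covariance form: the
per-generation change in a trait mean is

    delta_zbar = h2 * Cov(omega, z) = sigma2_A * b

with b the selection gradient Cov(omega, z) / sigma2_z.  Female extra-pair
mating behaviour additionally gets the indirect/direct decomposition in
units of phenotypic standard deviations.  All functions return full
precision; round only for presentation.
"""

from __future__ import annotations

import math

__all__ = [
    "response_breeder",
    "delta_mean_h2",
    "delta_mean_gradient",
    "delta_indirect",
    "delta_direct",
    "selection_intensity",
    "gradient_required",
]


def _check_h2(h2: float) -> None:
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must be in [0, 1], got {h2}")


def response_breeder(h2: float, s: float) -> float:
    """Breeder's equation R = h2 * s for selection differential s."""
    _check_h2(h2)
    return h2 * s


def delta_mean_h2(h2: float, fitness_covariance: float) -> float:
    """delta_zbar = h2 * Cov(omega, z)."""
    _check_h2(h2)
    return h2 * fitness_covariance


def delta_mean_gradient(sigma2_A: float, gradient: float) -> float:
    """delta_zbar = sigma2_A * b; identical to delta_mean_h2 when
    b = Cov/sigma2_z and h2 = sigma2_A/sigma2_z."""
    if sigma2_A < 0:
        raise ValueError("sigma2_A must be non-negative")
    return sigma2_A * gradient


def delta_indirect(h2: float, sigma_nepo: float, s_ew: float) -> float:
    """Change in mean EPO number under indirect selection (phenotypic-SD
    units): h2 * sigma_NEPO * s_EW, with s_EW the fitness difference between
    extra-pair and within-pair offspring."""
    _check_h2(h2)
    return h2 * sigma_nepo * s_ew


def delta_direct(h2: float, sigma_nepo: float, beta_fepc: float) -> float:
    """Change in mean EPO number under direct selection on female extra-pair
    copulation propensity: (1/2) * h2 * sigma_NEPO * beta_fEPC."""
    _check_h2(h2)
    return 0.5 * h2 * sigma_nepo * beta_fepc


def selection_intensity(delta_zbar: float, h2: float, sigma2_z: float) -> float:
    """Selection intensity i = delta_zbar / (h2 * sqrt(sigma2_z)) needed for
    a target shift of the trait mean."""
    _check_h2(h2)
    if h2 == 0:
        raise ValueError("selection intensity is infinite at h2 = 0")
    if sigma2_z <= 0:
        raise ValueError("sigma2_z must be positive")
    return delta_zbar / (h2 * math.sqrt(sigma2_z))


def gradient_required(delta_zbar: float, sigma2_A: float) -> float:
    """Selection gradient beta = delta_zbar / sigma2_A that produces a target
    shift of the trait mean (inverts the gradient form of the response)."""
    if sigma2_A <= 0:
        raise ValueError("sigma2_A must be positive")
    return delta_zbar / sigma2_A
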