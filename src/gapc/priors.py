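"""Hyperpriors for the precision parameters of the latent Gaussian fields.

Two families are supported for each precision tau = 1/sigma^2:

* penalised-complexity (PC) prior, induced by an exponential prior on the
  standard deviation sigma calibrated through P(sigma > u) = alpha; on the
  precision scale this is the type-2 Gumbel density
  pi(tau) = (lambda/2) tau^(-3/2) exp(-lambda tau^(-1/2)),
  lambda = -log(alpha) / u;
* a bounded uniform prior on the standard deviation, pi(sigma) ∝ 1 on
  (0, sigma_max], which guarantees a proper posterior while staying close
  to the improper uniform-on-SD reference prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GapcError

__all__ = ["PriorConfig", "pc_precision_logdensity", "uniform_sd_precision_logdensity"]


def pc_precision_logdensity(tau: float, u: float = 1.0, alpha: float = 0.01) -> float:
    """Log density of the PC prior on a precision.

    ``u`` is the threshold on the SD scale and ``alpha`` the tail
    probability in P(sigma > u) = alpha.
    """
    if not (0 < alpha < 1) or u <= 0:
        raise GapcError(f"need 0 < alpha < 1 and u > 0, got alpha={alpha}, u={u}")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise GapcError("precision must be positive")
    lam = -np.log(alpha) / u
    out = np.log(lam / 2.0) - 1.5 * np.log(tau) - lam / np.sqrt(tau)
    return out.item() if out.ndim == 0 else out


def uniform_sd_precision_logdensity(tau: float, sigma_max: float = 100.0) -> float:
    """Log density (unnormalized) on tau implied by sigma ~ Uniform(0, sigma_max].

    Change of variables sigma = tau^(-1/2) gives pi(tau) ∝ tau^(-3/2) on
    [sigma_max^(-2), inf).
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise GapcError("precision must be positive")
    out = np.where(tau >= sigma_max**-2, -1.5 * np.log(tau), -np.inf)
    return out.item() if out.ndim == 0 else out


@dataclass
class PriorConfig:
    """Hyperprior settings for all precision parameters and the intercepts.

    ``family`` applies to every random-effect precision; ``pc_u`` and
    ``pc_alpha`` calibrate the PC prior through P(sigma > pc_u) = pc_alpha.
    ``intercept_variance`` is the variance of the vague zero-mean normal
    prior on the gender intercepts.
    """

    family: str = "pc_precision"  # or "uniform_sd"
    pc_u: float = 1.0
    pc_alpha: float = 0.01
    sigma_max: float = 100.0
    intercept_variance: float = 1000.0

    def __post_init__(self) -> None:
        if self.family not in ("pc_precision", "uniform_sd"):
            raise GapcError(f"unknown prior family {self.family!r}")
        if not (0 < self.pc_alpha < 1) or self.pc_u <= 0:
            raise GapcError("need 0 < pc_alpha < 1 and pc_u > 0")

    def logdensity(self, tau: float) -> float:
        if self.family == "pc_precision":
            return pc_precision_logdensity(tau, self.pc_u, self.pc_alpha)
        return uniform_sd_precision_logdensity(tau, self.sigma_max)
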