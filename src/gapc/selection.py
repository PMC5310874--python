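"""Bayesian model comparison by DIC and WAIC.

Both criteria are computed at the cell level (g, a, i, t) from the
posterior draws of the latent effects.  The DIC plug-in deviance is
evaluated at the posterior means of the latent effects (the level at which
the hierarchical model is specified), and WAIC uses the cell as the
pointwise prediction unit.  Smaller values indicate better expected
predictive performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .data_model import MortalityDataset
from .errors import GapcError
from .inference import PosteriorResult
from .structure import linear_predictor

__all__ = ["ModelScore", "poisson_deviance", "dic", "waic", "rank_models"]


def poisson_deviance(deaths, mu) -> float:
    """Poisson deviance D = 2 sum[y log(y/mu) - (y - mu)].

    The y = 0 term is read as 2*mu (its limit).  Requires mu > 0 wherever
    y > 0.
    """
    y = np.asarray(deaths, dtype=float).ravel()
    m = np.asarray(mu, dtype=float).ravel()
    if np.any((m <= 0) & (y > 0)):
        raise GapcError("deviance undefined: mu = 0 with observed deaths > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / m) - (y - m), m)
    return float(2.0 * np.sum(term))


@dataclass(order=False)
class ModelScore:
    """Information-criterion scores for one fitted model."""

    name: str = "model"
    dic: float = np.nan
    p_dic: float = np.nan
    waic: float = np.nan
    p_waic: float = np.nan
    lppd: float = np.nan
    pointwise: dict = field(default_factory=dict, repr=False)


def _log_mu_draws(result: PosteriorResult, dataset: MortalityDataset) -> np.ndarray:
    """Per-draw log Poisson means, shape (draws, cells)."""
    log_rate = result.log_rate_draws(dataset)
    S = log_rate.shape[0]
    return (log_rate + np.log(dataset.population)[None]).reshape(S, -1)


def dic(result: PosteriorResult, dataset: MortalityDataset, score: ModelScore | None = None) -> ModelScore:
    """DIC = mean deviance + p_D, with p_D = D_bar - D(posterior-mean effects)."""
    score = score or ModelScore()
    y = dataset.deaths.astype(float).ravel()
    log_mu = _log_mu_draws(result, dataset)
    devs = np.array([poisson_deviance(y, np.exp(lm)) for lm in log_mu])
    d_bar = float(devs.mean())
    _, log_mu_hat = linear_predictor(result.posterior_mean_effects(), dataset, result.spec)
    d_hat = poisson_deviance(y, np.exp(log_mu_hat))
    score.p_dic = d_bar - d_hat
    score.dic = d_bar + score.p_dic
    score.pointwise["deviance_draws"] = devs
    return score


def waic(result: PosteriorResult, dataset: MortalityDataset, score: ModelScore | None = None) -> ModelScore:
    """WAIC = -2 (lppd - p_waic), with the variance-based p_waic."""
    score = score or ModelScore()
    y = dataset.deaths.astype(float).ravel()
    log_mu = _log_mu_draws(result, dataset)  # (S, cells)
    logp = y[None] * log_mu - np.exp(log_mu) - gammaln(y + 1.0)[None]
    if not np.all(np.isfinite(logp)):
        s, cell = np.argwhere(~np.isfinite(logp))[0]
        raise GapcError(f"non-finite log-density at draw {s}, cell index {cell}")
    S = logp.shape[0]
    lppd_cell = logsumexp(logp, axis=0) - np.log(S)
    p_cell = logp.var(axis=0, ddof=1) if S > 1 else np.zeros(logp.shape[1])
    score.lppd = float(lppd_cell.sum())
    score.p_waic = float(p_cell.sum())
    score.waic = -2.0 * (score.lppd - score.p_waic)
    score.pointwise["lppd"] = lppd_cell
    score.pointwise["p_waic"] = p_cell
    return score


def score_model(result: PosteriorResult, dataset: MortalityDataset, name: str = "model") -> ModelScore:
    """Convenience: both criteria in one ModelScore."""
    score = ModelScore(name=name)
    dic(result, dataset, score)
    waic(result, dataset, score)
    return score


def rank_models(scores: list[ModelScore], criterion: str = "waic"):
    """Ascending ranking by DIC or WAIC; ties broken by fewer effective parameters, then name."""
    import pandas as pd

    if not scores:
        raise GapcError("rank_models needs at least one score")
    if criterion not in ("dic", "waic"):
        raise GapcError(f"criterion must be 'dic' or 'waic', got {criterion!r}")
    p_key = "p_dic" if criterion == "dic" else "p_waic"
    ordered = sorted(scores, key=lambda s: (getattr(s, criterion), getattr(s, p_key), s.name))
    return pd.DataFrame(
        [
            {
                "rank": j + 1,
                "name": s.name,
                "dic": s.dic,
                "p_dic": s.p_dic,
                "waic": s.waic,
                "p_waic": s.p_waic,
            }
            for j, s in enumerate(ordered)
        ]
    )
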