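"""Posterior summary statistics: PD/p, MAP, HDI, Savage-Dickey BF, split-R-hat.

Conventions: the probability of direction (PD) is the posterior mass on the
dominant sign and converts to a two-sided p-value as p = 2(1 - PD); the MAP
is the peak of a Gaussian kernel density estimate; the HDI is the shortest
contiguous interval holding the requested mass; the Bayes factor BF10 is the
Savage-Dickey density ratio prior(0)/posterior(0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ..exceptions import DegenerateDrawsWarning

BF_INFINITY = np.inf
_KDE_FLOOR = 1e-300


def pd_and_p(draws: np.ndarray) -> tuple[float, float]:
    """Probability of direction and its two-sided p-value, p = 2(1 - PD)."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 draws")
    if np.all(x == 0.0):
        warnings.warn("all draws exactly zero", DegenerateDrawsWarning)
        return 0.5, 1.0
    pos = np.mean(x > 0)
    neg = np.mean(x < 0)
    # draws exactly at zero count toward neither sign; PD stays >= 1/2
    pd_ = float(max(pos, neg, 0.5))
    return pd_, float(2.0 * (1.0 - pd_))


def map_estimate(draws: np.ndarray) -> float:
    """Posterior mode via Gaussian KDE (Silverman bandwidth) on a 512-point grid."""
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("need at least 100 draws for a KDE mode")
    if np.ptp(x) == 0.0:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    dens = kde(grid)
    return float(grid[np.argmax(dens)])


def hdi95(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``prob`` of the draws.

    Ties between minimal-width windows return the lowest window (a tie flag
    is issued as a warning).
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 100:
        raise ValueError("need at least 100 draws for an HDI")
    k = max(int(np.ceil(prob * n)), 2)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    if np.sum(widths == widths[i]) > 1 and widths[i] > 0:
        warnings.warn("multiple minimal-width HDI windows; returning the lowest",
                      DegenerateDrawsWarning)
    return float(x[i]), float(x[i + k - 1])


def savage_dickey_bf10(
    posterior_draws: np.ndarray, prior_draws: np.ndarray, at: float = 0.0
) -> float:
    """Bayes factor for the alternative over the point null via Savage-Dickey:
    prior density at the null value divided by posterior density there."""
    post = np.asarray(posterior_draws, dtype=float).ravel()
    prior = np.asarray(prior_draws, dtype=float).ravel()
    if post.size < 1000 or prior.size < 1000:
        raise ValueError("need at least 1000 draws in each set")
    prior_d = float(gaussian_kde(prior, bw_method="silverman")(at)[0])
    if prior_d <= 0:
        raise ValueError("prior density at the null point must be positive")
    if np.ptp(post) == 0.0:
        warnings.warn("degenerate posterior draws in BF10", DegenerateDrawsWarning)
        return BF_INFINITY if post[0] != at else 0.0
    post_d = float(gaussian_kde(post, bw_method="silverman")(at)[0])
    if post_d < _KDE_FLOOR:
        warnings.warn("posterior density at null below numerical floor; BF10 = inf",
                      DegenerateDrawsWarning)
        return BF_INFINITY
    return prior_d / post_d


def split_rhat(chains: np.ndarray) -> float:
    """Gelman's split-R-hat for one parameter, chains of shape (m, n).

    Each chain is split in half; R-hat = sqrt(((n-1)/n W + B/n) / W) over the
    split halves.  Returns NaN with a warning when the within-chain variance
    is zero.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 4:
        raise ValueError("need >= 2 chains of >= 4 draws")
    half = arr.shape[1] // 2
    halves = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    w = float(halves.var(axis=1, ddof=1).mean())
    b = float(n * means.var(ddof=1))
    if w == 0.0:
        warnings.warn("zero within-chain variance; R-hat undefined",
                      DegenerateDrawsWarning)
        return float("nan")
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


@dataclass
class FitSummary:
    """Summary of a single scalar parameter's posterior."""

    name: str
    map: float
    hdi_lower: float
    hdi_upper: float
    pd: float
    p: float
    bf10: Optional[float] = None
    rhat: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "map": self.map,
            "hdi_lower": self.hdi_lower,
            "hdi_upper": self.hdi_upper,
            "pd": self.pd,
            "p": self.p,
            "bf10": self.bf10,
            "rhat": self.rhat,
        }


def summarize_draws(
    draws_by_chain: np.ndarray,
    name: str,
    prior_draws: Optional[np.ndarray] = None,
) -> FitSummary:
    """Full summary (MAP / HDI95 / PD / p / BF10 / split-R-hat) for one
    parameter given its (chains, draws) array."""
    arr = np.asarray(draws_by_chain, dtype=float)
    flat = arr.ravel()
    pd_, p = pd_and_p(flat)
    lo, hi = hdi95(flat)
    bf = None
    if prior_draws is not None:
        bf = savage_dickey_bf10(flat, prior_draws)
    rhat = split_rhat(arr) if arr.ndim == 2 and arr.shape[0] >= 2 else None
    return FitSummary(
        name=name,
        map=map_estimate(flat),
        hdi_lower=lo,
        hdi_upper=hi,
        pd=pd_,
        p=p,
        bf10=bf,
        rhat=rhat,
    )


def summary_table(summaries: list[FitSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in summaries])
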