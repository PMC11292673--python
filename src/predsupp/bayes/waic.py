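"""WAIC: widely applicable information criterion and compared differences.

WAIC = -2 (lppd - p_waic) with lppd the summed log pointwise predictive
density (log of the posterior-mean likelihood per observation, computed with
log-sum-exp) and p_waic the summed posterior variance of the pointwise log
likelihood.  Lower is better.  A difference between two models fitted to the
same observations carries a standard error from the pointwise ELPD
differences; |difference| > SE is read as a reliable distinction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from ..exceptions import AlignmentError, DataError


@dataclass
class WAICResult:
    lppd: float
    p_waic: float
    waic: float
    pointwise_elpd: np.ndarray  # per-observation lppd_i - p_waic_i
    n_obs: int

    def as_dict(self) -> dict:
        return {
            "lppd": self.lppd,
            "p_waic": self.p_waic,
            "waic": self.waic,
            "n_obs": self.n_obs,
        }


def waic(log_likelihood: np.ndarray) -> WAICResult:
    """WAIC from a pointwise log-likelihood array.

    Accepts (chains, draws, observations) or (draws, observations); chains
    are pooled, as all post-warmup draws are exchangeable.
    """
    ll = np.asarray(log_likelihood, dtype=float)
    if ll.ndim == 3:
        ll = ll.reshape(-1, ll.shape[-1])
    if ll.ndim != 2 or ll.shape[1] < 1:
        raise DataError("log-likelihood must be (draws, observations) with >= 1 obs")
    if not np.all(np.isfinite(ll)):
        raise DataError("non-finite pointwise log-likelihood values")
    s = ll.shape[0]
    lppd_i = logsumexp(ll, axis=0) - np.log(s)
    # single draw: zero variance by definition
    p_i = ll.var(axis=0, ddof=1) if s > 1 else np.zeros(ll.shape[1])
    if not np.all(np.isfinite(p_i)):
        raise DataError("non-finite pointwise variance in WAIC")
    elpd_i = lppd_i - p_i
    lppd = float(lppd_i.sum())
    p_waic = float(p_i.sum())
    return WAICResult(
        lppd=lppd,
        p_waic=p_waic,
        waic=float(-2.0 * (lppd - p_waic)),
        pointwise_elpd=elpd_i,
        n_obs=ll.shape[1],
    )


def waic_diff(a: WAICResult, b: WAICResult) -> tuple[float, float, bool]:
    """(a.waic - b.waic, its SE, significance flag |delta| > SE).

    The SE comes from the pointwise ELPD differences: se = 2 sqrt(n Var(d_i)),
    the factor 2 moving from the ELPD to the deviance scale.
    """
    if a.n_obs != b.n_obs:
        raise AlignmentError(
            f"models were fit to different observation counts ({a.n_obs} vs {b.n_obs})"
        )
    delta = float(a.waic - b.waic)
    d = a.pointwise_elpd - b.pointwise_elpd
    var = float(d.var(ddof=1)) if a.n_obs > 1 else 0.0
    se = float(2.0 * np.sqrt(a.n_obs * var))
    return delta, se, bool(abs(delta) > se)
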