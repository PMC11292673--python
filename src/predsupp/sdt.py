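"""Multilevel Bayesian 3AFC signal-detection model of deviant-position reports.

Each subject's correct-report count is binomial with success probability
given by the unbiased-observer 3AFC link Pc(d') (see :mod:`predsupp.afc`):

    k_s ~ Binomial(n_s, Pc(d'_s)),   d'_s ~ Normal(mu_d, sigma_d)

with priors mu_d ~ Normal(0, 3) and sigma_d ~ half-normal(1.5) — wide enough
to span an easy task without forcing the group mean positive.  The three
response alternatives are treated as exchangeable; per-position accuracy is
exported descriptively.  Subjects at floor or ceiling are retained: the
hierarchical prior regularizes their estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .afc import mafc_pc, mafc_pc_grad
from .bayes import PosteriorDraws, sample_posterior, summarize_draws
from .bayes.transforms import half_normal_logp_grad
from .exceptions import DataError

_P_CLIP = 1e-12


@dataclass
class SDTPriors:
    mu_scale: float = 3.0
    sigma_scale: float = 1.5


class _SDTDensity:
    """Unconstrained layout: mu_d | log_sigma_d | d_s (S), centered.

    With hundreds of trials per subject the likelihood pins each d'_s
    tightly, so the subject sensitivities are sampled directly (centered
    parameterization); the non-centered variant creates a curved ridge
    between the group parameters and the subject offsets in this regime.
    """

    def __init__(self, k: np.ndarray, n: np.ndarray, priors: SDTPriors):
        self.k, self.n = k.astype(float), n.astype(float)
        self.S = len(k)
        self.priors = priors
        self.n_params = 2 + self.S

    def _split(self, theta):
        return theta[0], np.exp(theta[1]), theta[2:]

    def logp_grad(self, theta):
        mu, sig, d = self._split(theta)
        pc, dpc = mafc_pc_grad(d)
        pc = np.clip(pc, _P_CLIP, 1.0 - _P_CLIP)
        logp = float(np.sum(self.k * np.log(pc) + (self.n - self.k) * np.log1p(-pc)))
        dll_dp = self.k / pc - (self.n - self.k) / (1.0 - pc)
        g_d = dll_dp * dpc

        # hierarchical prior d_s ~ Normal(mu, sig)
        r = (d - mu) / sig
        logp += float(-0.5 * np.sum(r**2) - self.S * np.log(sig))
        g_d += -r / sig
        g_mu = float(np.sum(r) / sig)
        g_logsig = float(np.sum(r**2) - self.S)

        logp += float(-0.5 * (mu / self.priors.mu_scale) ** 2)
        g_mu += -mu / self.priors.mu_scale**2
        lp_sig, g_logsig_prior = half_normal_logp_grad(
            np.array([theta[1]]), self.priors.sigma_scale
        )
        logp += lp_sig
        g_logsig += float(g_logsig_prior[0])

        return logp, np.concatenate([[g_mu, g_logsig], g_d])

    def constrain(self, theta):
        mu, sig, d = self._split(theta)
        return {"mu_dprime": mu, "sigma_dprime": sig, "dprime": d}

    def pointwise_loglik(self, theta):
        from scipy.special import gammaln

        d = self._split(theta)[2]
        pc = np.clip(mafc_pc_grad(d)[0], _P_CLIP, 1.0 - _P_CLIP)
        binom = (
            gammaln(self.n + 1) - gammaln(self.k + 1) - gammaln(self.n - self.k + 1)
        )
        return binom + self.k * np.log(pc) + (self.n - self.k) * np.log1p(-pc)


class SDTModel:
    """Hierarchical 3AFC sensitivity model built from a behavioral table.

    The table needs columns subject and correct (0/1 per trial); position and
    response columns, when present, feed the descriptive per-position
    accuracy table.
    """

    def __init__(self, behavior: pd.DataFrame, priors: Optional[SDTPriors] = None):
        if behavior is None or len(behavior) == 0:
            raise DataError("empty behavioral table")
        required = {"subject", "correct"}
        if not required.issubset(behavior.columns):
            raise DataError(f"behavioral table needs columns {sorted(required)}")
        self.data = behavior.reset_index(drop=True)
        agg = behavior.groupby("subject")["correct"].agg(["sum", "count"])
        self.subjects = list(agg.index)
        self.k = agg["sum"].to_numpy()
        self.n = agg["count"].to_numpy()
        self.priors = priors or SDTPriors()
        self._density = _SDTDensity(self.k, self.n, self.priors)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SDTModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, seed: int, chains: int = 6, iters: int = 2000,
            warmup: int = 1000, **kw) -> "SDTResults":
        draws = sample_posterior(
            self._density, seed=seed, chains=chains, iters=iters, warmup=warmup, **kw
        )
        return SDTResults(self, draws)


@dataclass
class SDTResults:
    model: SDTModel
    draws: PosteriorDraws

    def _group_prior_draws(self, size: int = 20000) -> np.ndarray:
        rng = np.random.default_rng(np.random.SeedSequence((self.draws.seed, 17)))
        return rng.normal(scale=self.model.priors.mu_scale, size=size)

    def group_summary(self):
        return summarize_draws(
            self.draws.params["mu_dprime"],
            "mu_dprime",
            prior_draws=self._group_prior_draws(),
        )

    def subject_summaries(self) -> pd.DataFrame:
        d = self.draws.params["dprime"]  # (chains, draws, S)
        rows = []
        for i, s in enumerate(self.model.subjects):
            summ = summarize_draws(d[..., i], f"dprime[{s}]").as_dict()
            summ.update(subject=s,
                        accuracy=float(self.model.k[i] / self.model.n[i]))
            rows.append(summ)
        return pd.DataFrame(rows)

    def position_accuracy(self) -> Optional[pd.DataFrame]:
        """Descriptive accuracy by true deviant position, when available."""
        if "position" not in self.model.data.columns:
            return None
        return (
            self.model.data.groupby("position")["correct"]
            .agg(accuracy="mean", n="count")
            .reset_index()
        )

    def summary(self) -> pd.DataFrame:
        g = self.group_summary().as_dict()
        g.update(subject="group", accuracy=float(self.model.k.sum() / self.model.n.sum()))
        return pd.concat(
            [pd.DataFrame([g]), self.subject_summaries()], ignore_index=True
        )

    def expected_accuracy(self) -> float:
        """Posterior-mean predicted accuracy at the subjects' d' estimates."""
        d = self.draws.stacked("dprime").mean(axis=0)
        return float(np.mean([mafc_pc(x) for x in d]))

    def plot_dprime(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        table = self.subject_summaries()
        y = np.arange(len(table))
        ax.errorbar(
            table["map"], y,
            xerr=[table["map"] - table["hdi_lower"], table["hdi_upper"] - table["map"]],
            fmt="o", capsize=3,
        )
        g = self.group_summary()
        ax.axvline(g.map, color="C1", label=f"group MAP = {g.map:.2f}")
        ax.set_yticks(y)
        ax.set_yticklabels(table["subject"])
        ax.set_xlabel("d'")
        ax.legend()
        return ax
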