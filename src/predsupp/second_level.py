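"""Group-level pooling of first-level estimates with measurement error.

The model treats each first-level beta as a noisy observation of a latent
cell mean with *known* observation SD (the first-level SE), so precision is
pooled rather than discarded:

    beta_obs[i]  ~ Normal(eta[i], se_obs[i])
    eta[cell, roi] = mu[roi, cond] + u[subject, roi] + eps[cell, roi]
    eps[cell, :] ~ MVN(0, diag(sigma) R diag(sigma))
    u[subject, roi] ~ Normal(0, tau[roi])

with a cell being one subject x run x condition.  The residual correlation
matrix R couples the ROIs, which is what lets the model report cross-ROI
correlations of neural activity.  Priors are weakly informative and
scale-adaptive: mu ~ Normal(0, 10 sd(beta)), tau and sigma half-t(3) scaled
to sd(beta), R ~ LKJ(2).

Inference summaries for the four expectancy contrasts (adaptation std0-std1,
deviant detection dev4-std1, predictive suppression dev4-dev6, complete
suppression dev6-std2) and for the pairwise ROI correlations hang off the
results object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .bayes import PosteriorDraws, sample_posterior, summarize_draws
from .bayes.summaries import FitSummary, summary_table
from .bayes.transforms import (
    LOG_2PI,
    corr_chol_with_tangents,
    half_t_logp_grad,
    lkj_z_logp_grad,
)
from .design import ODDBALL_CONDITIONS, PHASEFLIP_CONDITIONS, ROIS
from .exceptions import DataError

ODDBALL_CONTRASTS = (
    ("adaptation", "std0", "std1"),
    ("deviant_detection", "dev4", "std1"),
    ("predictive_suppression", "dev4", "dev6"),
    ("complete_suppression", "dev6", "std2"),
)

PHASEFLIP_CONTRASTS = (
    ("inphase_vs_control", "inphase", "control"),
    ("antiphase_vs_control", "antiphase", "control"),
    ("inphase_vs_antiphase", "inphase", "antiphase"),
)


@dataclass
class SecondLevelPriors:
    """Weakly informative, scale-adaptive priors; None means 'from the data'."""

    mu_scale: Optional[float] = None
    tau_scale: Optional[float] = None
    sigma_scale: Optional[float] = None
    lkj_eta: float = 2.0
    scale_df: float = 3.0


class _SecondLevelDensity:
    """Joint log density with analytic gradient, on unconstrained coordinates.

    Layout: mu (K*C) | u_raw (S*K) | log_tau (K) | log_sigma (K) |
    z_corr (K(K-1)/2, absent for K=1) | eps_raw (n_cells*K).
    Random effects and cell residuals are non-centered.
    """

    def __init__(self, b, se, roi_idx, cond_idx, subj_idx, cell_idx,
                 K, C, S, n_cells, priors: SecondLevelPriors):
        self.b, self.se = b, se
        self.roi_idx, self.cond_idx = roi_idx, cond_idx
        self.subj_idx, self.cell_idx = subj_idx, cell_idx
        self.K, self.C, self.S, self.n_cells = K, C, S, n_cells
        self.priors = priors
        self.nz = K * (K - 1) // 2
        self._off = np.cumsum([0, K * C, S * K, K, K, self.nz])
        self.n_params = self._off[-1] + n_cells * K
        self.se2 = se**2
        # flattened scatter indices and constant likelihood terms
        self._mu_flat = roi_idx * C + cond_idx
        self._u_flat = subj_idx * K + roi_idx
        self._eps_flat = cell_idx * K + roi_idx
        self._ll_const = float(-np.sum(np.log(se)) - 0.5 * len(b) * LOG_2PI)

    def _split(self, theta):
        o = self._off
        mu = theta[o[0] : o[1]].reshape(self.K, self.C)
        u_raw = theta[o[1] : o[2]].reshape(self.S, self.K)
        log_tau = theta[o[2] : o[3]]
        log_sigma = theta[o[3] : o[4]]
        z = theta[o[4] : o[5]]
        eps_raw = theta[o[5] :].reshape(self.n_cells, self.K)
        return mu, u_raw, log_tau, log_sigma, z, eps_raw

    def _means(self, mu, u_raw, tau, sigma, L, eps_raw):
        eps = eps_raw @ L.T
        mean = (
            mu[self.roi_idx, self.cond_idx]
            + tau[self.roi_idx] * u_raw[self.subj_idx, self.roi_idx]
            + sigma[self.roi_idx] * eps[self.cell_idx, self.roi_idx]
        )
        return mean, eps

    def logp_grad(self, theta):
        p = self.priors
        mu, u_raw, log_tau, log_sigma, z, eps_raw = self._split(theta)
        tau, sigma = np.exp(log_tau), np.exp(log_sigma)
        if self.K > 1:
            L, T = corr_chol_with_tangents(z, self.K)
        else:
            L, T = np.ones((1, 1)), np.zeros((0, 1, 1))
        mean, eps = self._means(mu, u_raw, tau, sigma, L, eps_raw)
        resid = self.b - mean
        logp = float(-0.5 * np.sum(resid**2 / self.se2)) + self._ll_const
        w = resid / self.se2

        K, C = self.K, self.C
        g_mu = np.bincount(self._mu_flat, w, minlength=K * C).reshape(K, C)
        g_uraw = np.bincount(
            self._u_flat, w * tau[self.roi_idx], minlength=self.S * K
        ).reshape(self.S, K)
        g_tau_lik = np.bincount(
            self.roi_idx, w * u_raw[self.subj_idx, self.roi_idx], minlength=K
        )
        g_sigma_lik = np.bincount(
            self.roi_idx, w * eps[self.cell_idx, self.roi_idx], minlength=K
        )
        g_eps = np.bincount(
            self._eps_flat, w * sigma[self.roi_idx], minlength=self.n_cells * K
        ).reshape(self.n_cells, K)
        g_eraw = g_eps @ L if K > 1 else g_eps

        # priors
        logp += float(-0.5 * np.sum((mu / p.mu_scale) ** 2))
        g_mu += -mu / p.mu_scale**2
        logp += float(-0.5 * np.sum(u_raw**2) - 0.5 * np.sum(eps_raw**2))
        g_uraw += -u_raw
        g_eraw += -eps_raw
        lp_tau, g_lt_prior = half_t_logp_grad(log_tau, p.tau_scale, p.scale_df)
        lp_sig, g_ls_prior = half_t_logp_grad(log_sigma, p.sigma_scale, p.scale_df)
        logp += lp_tau + lp_sig
        g_lt = tau * g_tau_lik + g_lt_prior
        g_ls = sigma * g_sigma_lik + g_ls_prior

        if self.K > 1:
            g_L = g_eps.T @ eps_raw
            g_z = np.einsum("kij,ij->k", T, g_L)
            lp_z, g_z_prior = lkj_z_logp_grad(z, self.K, p.lkj_eta)
            logp += lp_z
            g_z = g_z + g_z_prior
        else:
            g_z = np.zeros(0)

        grad = np.concatenate(
            [g_mu.ravel(), g_uraw.ravel(), g_lt, g_ls, g_z, g_eraw.ravel()]
        )
        return logp, grad

    def constrain(self, theta):
        mu, u_raw, log_tau, log_sigma, z, _ = self._split(theta)
        tau, sigma = np.exp(log_tau), np.exp(log_sigma)
        if self.K > 1:
            L, _ = corr_chol_with_tangents(z, self.K)
            R = L @ L.T
        else:
            R = np.ones((1, 1))
        return {"mu": mu, "tau": tau, "sigma": sigma, "R": R, "u": tau * u_raw}

    def pointwise_loglik(self, theta):
        mu, u_raw, log_tau, log_sigma, z, eps_raw = self._split(theta)
        tau, sigma = np.exp(log_tau), np.exp(log_sigma)
        L = corr_chol_with_tangents(z, self.K)[0] if self.K > 1 else np.ones((1, 1))
        mean, _ = self._means(mu, u_raw, tau, sigma, L, eps_raw)
        resid = self.b - mean
        return -0.5 * resid**2 / self.se2 - np.log(self.se) - 0.5 * LOG_2PI


class SecondLevelModel:
    """Multivariate multilevel measurement-error model over ROI responses.

    Parameters
    ----------
    estimates : DataFrame with columns subject, run, roi, condition, beta, se.
    condition_set : "oddball" or "phaseflip"; selects conditions and contrasts.
    granularity : "run" uses the per-run rows (default), "pooled" the
        subject-pooled rows produced by the first level.
    """

    def __init__(
        self,
        estimates: pd.DataFrame,
        condition_set: str = "oddball",
        granularity: str = "run",
        priors: Optional[SecondLevelPriors] = None,
    ):
        if condition_set == "oddball":
            conds = [c for c in ODDBALL_CONDITIONS]
        elif condition_set == "phaseflip":
            conds = list(PHASEFLIP_CONDITIONS)
        else:
            raise DataError(f"unknown condition set {condition_set!r}")
        df = estimates.copy()
        df["run"] = df["run"].astype(str)
        if granularity == "run":
            df = df[df["run"] != "pooled"]
        elif granularity == "pooled":
            df = df[df["run"] == "pooled"]
        else:
            raise DataError(f"unknown granularity {granularity!r}")
        df = df[df["condition"].isin(conds)].reset_index(drop=True)
        if df.empty:
            raise DataError("no rows for the requested condition set")
        if (df["se"] <= 0).any() or not np.isfinite(df[["beta", "se"]]).all().all():
            raise DataError("standard errors must be positive and finite")

        rois = [r for r in ROIS if r in set(df["roi"])]
        rois += sorted(set(df["roi"]) - set(rois))
        subjects = sorted(df["subject"].unique())
        conds = [c for c in conds if c in set(df["condition"])]
        missing = [
            (s, c, r)
            for s in subjects
            for c in conds
            for r in rois
            if df[(df.subject == s) & (df.condition == c) & (df.roi == r)].empty
        ]
        if missing:
            warnings.warn(
                f"{len(missing)} subject x condition x roi cells have no rows; "
                "the model tolerates the imbalance"
            )

        cells = df[["subject", "run", "condition"]].drop_duplicates().reset_index(drop=True)
        cell_key = {tuple(row): i for i, row in enumerate(cells.to_numpy())}
        self.condition_set = condition_set
        self.conditions = conds
        self.rois = rois
        self.subjects = subjects
        self.data = df
        b = df["beta"].to_numpy(dtype=float)
        se = df["se"].to_numpy(dtype=float)
        roi_idx = df["roi"].map({r: i for i, r in enumerate(rois)}).to_numpy()
        cond_idx = df["condition"].map({c: i for i, c in enumerate(conds)}).to_numpy()
        subj_idx = df["subject"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
        cell_idx = np.array(
            [cell_key[(s, r, c)] for s, r, c in df[["subject", "run", "condition"]].to_numpy()]
        )

        priors = priors or SecondLevelPriors()
        sd_b = float(np.std(b)) or 1.0
        if priors.mu_scale is None:
            priors.mu_scale = 10.0 * sd_b
        if priors.tau_scale is None:
            priors.tau_scale = sd_b
        if priors.sigma_scale is None:
            priors.sigma_scale = sd_b
        self.priors = priors
        self._density = _SecondLevelDensity(
            b, se, roi_idx, cond_idx, subj_idx, cell_idx,
            len(rois), len(conds), len(subjects), len(cells), priors,
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SecondLevelModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(
        self,
        seed: int,
        chains: int = 6,
        iters: int = 2000,
        warmup: int = 1000,
        **sampler_kwargs,
    ) -> "SecondLevelResults":
        draws = sample_posterior(
            self._density, seed=seed, chains=chains, iters=iters, warmup=warmup,
            **sampler_kwargs,
        )
        return SecondLevelResults(self, draws)


@dataclass
class SecondLevelResults:
    """Posterior draws plus the contrast and correlation summaries."""

    model: SecondLevelModel
    draws: PosteriorDraws

    @property
    def contrast_definitions(self):
        return (
            ODDBALL_CONTRASTS
            if self.model.condition_set == "oddball"
            else PHASEFLIP_CONTRASTS
        )

    def contrast_draws(self, c1: str, c2: str, roi: str) -> np.ndarray:
        conds, rois = self.model.conditions, self.model.rois
        for c in (c1, c2):
            if c not in conds:
                raise DataError(f"unknown condition label {c!r}")
        if roi not in rois:
            raise DataError(f"unknown ROI label {roi!r}")
        mu = self.draws.params["mu"]  # (chains, draws, K, C)
        r = rois.index(roi)
        return mu[..., r, conds.index(c1)] - mu[..., r, conds.index(c2)]

    def _contrast_prior_draws(self, size: int = 20000, seed: int = 0) -> np.ndarray:
        # the implied prior of a difference of two independent mu priors
        rng = np.random.default_rng(np.random.SeedSequence((self.draws.seed, seed)))
        s = self.model.priors.mu_scale
        return rng.normal(scale=s, size=size) - rng.normal(scale=s, size=size)

    def contrasts(self) -> pd.DataFrame:
        """MAP / HDI95 / PD / p / BF10 per ROI and contrast."""
        prior = self._contrast_prior_draws()
        rows = []
        for name, c1, c2 in self.contrast_definitions:
            for roi in self.model.rois:
                delta = self.contrast_draws(c1, c2, roi)
                s = summarize_draws(delta, f"{roi}:{name}", prior_draws=prior)
                d = s.as_dict()
                d.update(roi=roi, contrast=name)
                rows.append(d)
        return pd.DataFrame(rows)

    def roi_correlations(self) -> pd.DataFrame:
        """Posterior summaries of the pairwise residual ROI correlations."""
        K = len(self.model.rois)
        if K < 2:
            raise DataError("correlations are not applicable to a univariate fit")
        R = self.draws.params["R"]  # (chains, draws, K, K)
        rows = []
        for i in range(K):
            for j in range(i + 1, K):
                pair = f"{self.model.rois[i]}-{self.model.rois[j]}"
                s = summarize_draws(R[..., i, j], pair)
                d = s.as_dict()
                d.update(pair=pair)
                rows.append(d)
        return pd.DataFrame(rows)

    def condition_means(self) -> pd.DataFrame:
        mu = self.draws.params["mu"]
        rows = []
        for r, roi in enumerate(self.model.rois):
            for c, cond in enumerate(self.model.conditions):
                s = summarize_draws(mu[..., r, c], f"{roi}:{cond}")
                d = s.as_dict()
                d.update(roi=roi, condition=cond)
                rows.append(d)
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        return self.contrasts()

    def plot_contrasts(self, ax=None):
        """Point (MAP) and HDI95 interval per ROI x contrast."""
        import matplotlib.pyplot as plt

        table = self.contrasts()
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        y = np.arange(len(table))
        ax.errorbar(
            table["map"], y,
            xerr=[table["map"] - table["hdi_lower"], table["hdi_upper"] - table["map"]],
            fmt="o", capsize=3,
        )
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_yticks(y)
        ax.set_yticklabels(table["roi"] + ":" + table["contrast"])
        ax.set_xlabel("contrast (arb. units)")
        return ax
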