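"""Directional path models of auditory-pathway coupling, compared by WAIC.

Two analyses, each pitting a bottom-up chain against its top-down mirror and
an intercept-only null:

* initial tone detection — the response to the first tone of each sequence
  (std0) across all four ROIs; bottom-up chain IC -> MGB -> AC -> STG,
  top-down STG -> AC -> MGB -> IC; raw betas with their first-level SEs.
* predictive suppression — the deviant responses (dev4/dev5/dev6) in the
  ROIs showing suppression (IC, MGB, AC), standardized per subject and ROI,
  with deviant position (coded 1/2/3) as an exogenous error-free source and
  participant random intercepts; top-down chain position -> AC -> MGB -> IC,
  bottom-up position -> IC -> MGB -> AC.

Every node's observed beta is a noisy measure of a latent true score
(b ~ Normal(t, se)); the structural layer regresses each latent on its
parent's latent, so first-level uncertainty propagates through both sides of
every path.  Model comparison uses WAIC on the observation layer with the
|difference| > SE decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bayes import PosteriorDraws, sample_posterior, summarize_draws, waic, waic_diff
from .bayes.transforms import LOG_2PI, half_t_logp_grad
from .bayes.waic import WAICResult
from .exceptions import AlignmentError, DataError, UnsupportedStructureError

POSITION_SOURCE = "position"
DETECTION_NODES = ("IC", "MGB", "AC", "STG")
SUPPRESSION_NODES = ("IC", "MGB", "AC")
POSITION_CODES = {"dev4": 1, "dev5": 2, "dev6": 3}


@dataclass(frozen=True)
class PathModelSpec:
    """One structural model: ordered nodes and a simple chain of edges."""

    name: str
    analysis: str  # "detection" | "suppression"
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    random_intercepts: bool = False
    standardize: bool = False

    def __post_init__(self):
        targets = [t for _, t in self.edges]
        if len(targets) != len(set(targets)):
            raise UnsupportedStructureError("a node has more than one parent")
        for s, t in self.edges:
            if t not in self.nodes:
                raise UnsupportedStructureError(f"edge target {t!r} not a node")
            if s != POSITION_SOURCE and s not in self.nodes:
                raise UnsupportedStructureError(f"edge source {s!r} not a node")
        # chain check: following parents from any node must terminate
        parent = {t: s for s, t in self.edges}
        for n in self.nodes:
            seen, cur = set(), n
            while cur in parent and parent[cur] != POSITION_SOURCE:
                if cur in seen:
                    raise UnsupportedStructureError("cycle in path specification")
                seen.add(cur)
                cur = parent[cur]

    @property
    def edge_names(self) -> list[str]:
        return [f"{s}->{t}" for s, t in self.edges]


def make_specs(analysis: str) -> tuple[PathModelSpec, PathModelSpec, PathModelSpec]:
    """The (bottom-up, top-down, intercept-only) triplet for an analysis."""
    if analysis == "detection":
        nodes = DETECTION_NODES
        chain = lambda order: tuple(zip(order[:-1], order[1:]))
        bottom_up = PathModelSpec("bottom_up", analysis, nodes, chain(nodes))
        top_down = PathModelSpec("top_down", analysis, nodes, chain(nodes[::-1]))
        null = PathModelSpec("null", analysis, nodes, ())
        return bottom_up, top_down, null
    if analysis == "suppression":
        nodes = SUPPRESSION_NODES
        bu_edges = ((POSITION_SOURCE, "IC"), ("IC", "MGB"), ("MGB", "AC"))
        td_edges = ((POSITION_SOURCE, "AC"), ("AC", "MGB"), ("MGB", "IC"))
        kw = dict(random_intercepts=True, standardize=True)
        return (
            PathModelSpec("bottom_up", analysis, nodes, bu_edges, **kw),
            PathModelSpec("top_down", analysis, nodes, td_edges, **kw),
            PathModelSpec("null", analysis, nodes, (), **kw),
        )
    raise DataError(f"unknown analysis {analysis!r}")


def prepare_path_data(
    estimates: pd.DataFrame, analysis: str, granularity: str = "run"
) -> pd.DataFrame:
    """Observation table for a path analysis.

    Detection keeps the std0 rows as-is; suppression keeps the deviant rows,
    z-scores betas per subject x ROI (dividing the SEs by the same sd) and
    codes deviant position 1/2/3.  Re-applying to an already prepared table
    re-standardizes and is idempotent.
    """
    df = estimates.copy()
    if "run" in df.columns:
        df["run"] = df["run"].astype(str)
        if granularity == "run":
            df = df[df["run"] != "pooled"]
        else:
            df = df[df["run"] == "pooled"]

    if analysis == "detection":
        if "condition" in df.columns:
            df = df[df["condition"] == "std0"]
        if df.empty:
            raise DataError("no std0 rows for the detection analysis")
        out = df[["subject", "run", "roi", "beta", "se"]].reset_index(drop=True)
        return out

    if analysis != "suppression":
        raise DataError(f"unknown analysis {analysis!r}")

    if "condition" in df.columns:
        df = df[df["condition"].isin(POSITION_CODES)]
        if df.empty:
            raise DataError("no deviant rows for the suppression analysis")
        df["position"] = df["condition"].map(POSITION_CODES)
    elif "position" not in df.columns:
        raise DataError("need condition or position column")

    out_rows = []
    for (subj, roi), g in df.groupby(["subject", "roi"]):
        sd = float(g["beta"].std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise DataError(
                f"zero variance under standardization for subject {subj}, ROI {roi}"
            )
        mean = float(g["beta"].mean())
        g = g.copy()
        g["beta"] = (g["beta"] - mean) / sd
        g["se"] = g["se"] / sd
        out_rows.append(g)
    out = pd.concat(out_rows, ignore_index=True)
    return out[["subject", "run", "position", "roi", "beta", "se"]]


class _PathDensity:
    """Latent-score chain regression with known observation SDs.

    Layout: t (N*K) | alpha (K) | beta (E) | log_s (K) |
    [u_raw (S*K) | log_tau (K)] when random intercepts are on.

    The sampler coordinates are a preconditioned affine reparameterization of
    the model quantities: latent scores are centered on the node data means
    and scaled by the node data SDs, structural regressors are centered on
    their parent's mean, and slopes are rescaled by the node/parent SD ratio.
    This is a fixed linear change of variables — the likelihood, the priors
    (stated on the raw-unit quantities) and WAIC are untouched — that removes
    the extreme intercept/slope correlation of raw-scale chains and keeps the
    posterior close to unit scale for the sampler.  The reported ``alpha`` is
    the centered intercept: the node's expected score at the parent's mean.
    """

    def __init__(self, b, se, subj_idx, position, spec: PathModelSpec,
                 ab_scale: float, scale_prior: float):
        self.b, self.se = b, se  # (N, K)
        self.se2 = se**2
        self.subj_idx = subj_idx
        self.position = position  # (N,) or None
        self.spec = spec
        self.N, self.K = b.shape
        self.S = int(subj_idx.max()) + 1 if len(subj_idx) else 0
        self.E = len(spec.edges)
        self.ab_scale = ab_scale
        self.scale_prior = scale_prior
        node_pos = {n: i for i, n in enumerate(spec.nodes)}
        self.parent = np.full(self.K, -1, dtype=int)   # node index of parent
        self.from_position = np.zeros(self.K, dtype=bool)
        self.beta_of_node = np.full(self.K, -1, dtype=int)
        for e, (s, t) in enumerate(spec.edges):
            k = node_pos[t]
            self.beta_of_node[k] = e
            if s == POSITION_SOURCE:
                if position is None:
                    raise DataError("spec uses a position source but data has none")
                self.from_position[k] = True
            else:
                self.parent[k] = node_pos[s]
        self.ri = spec.random_intercepts
        n = self.N * self.K + self.K + self.E + self.K
        if self.ri:
            n += self.S * self.K + self.K
        self.n_params = n

        # preconditioning constants; latents use their approximate posterior
        # scale (observation SE and node SD combined in quadrature)
        self.m_b = b.mean(axis=0)
        self.c_b = np.maximum(b.std(axis=0), 1e-8)
        self.c_t = 1.0 / np.sqrt(1.0 / np.maximum(se, 1e-12) ** 2
                                 + 1.0 / self.c_b**2)
        if position is not None:
            self.pos_mean = float(np.mean(position))
            self.pos_sd = max(float(np.std(position)), 1e-8)
        self.c_beta = np.empty(self.E)
        self.x_center = np.empty(self.E)
        for e, (src, tgt) in enumerate(spec.edges):
            k = node_pos[tgt]
            if src == POSITION_SOURCE:
                cx, mx = self.pos_sd, self.pos_mean
            else:
                p = node_pos[src]
                cx, mx = self.c_b[p], self.m_b[p]
            self.c_beta[e] = self.c_b[k] / cx
            self.x_center[e] = mx
        self.log_c_b = np.log(self.c_b)

    def _split(self, theta):
        """Sampler coordinates -> raw-unit model quantities."""
        o = 0
        t_raw = theta[o : o + self.N * self.K].reshape(self.N, self.K)
        o += self.N * self.K
        t = self.m_b + self.c_t * t_raw
        alpha = self.c_b * theta[o : o + self.K]; o += self.K
        beta = self.c_beta * theta[o : o + self.E]; o += self.E
        log_s = theta[o : o + self.K] + self.log_c_b; o += self.K
        u_raw = log_tau = None
        if self.ri:
            u_raw = theta[o : o + self.S * self.K].reshape(self.S, self.K)
            o += self.S * self.K
            log_tau = theta[o : o + self.K] + self.log_c_b
        return t, alpha, beta, log_s, u_raw, log_tau

    def _structural_inputs(self, t, beta, k):
        """(centered regressor, slope) for node k; zeros for root nodes."""
        e = self.beta_of_node[k]
        if e < 0:
            return np.zeros(self.N), 0.0
        if self.from_position[k]:
            return self.position - self.x_center[e], beta[e]
        return t[:, self.parent[k]] - self.x_center[e], beta[e]

    def logp_grad(self, theta):
        t, alpha, beta, log_s, u_raw, log_tau = self._split(theta)
        s = np.exp(log_s)
        tau = np.exp(log_tau) if self.ri else None

        # observation layer
        resid_obs = self.b - t
        logp = float(np.sum(-0.5 * resid_obs**2 / self.se2 - np.log(self.se))
                     - 0.5 * self.N * self.K * LOG_2PI)
        g_t = resid_obs / self.se2

        g_alpha = np.zeros(self.K)
        g_beta = np.zeros(self.E)
        g_logs_lik = np.zeros(self.K)
        g_uraw = np.zeros((self.S, self.K)) if self.ri else None
        g_tau_lik = np.zeros(self.K) if self.ri else None

        for k in range(self.K):
            x, bk = self._structural_inputs(t, beta, k)
            m = alpha[k] + bk * x
            if self.ri:
                m = m + tau[k] * u_raw[self.subj_idx, k]
            r = t[:, k] - m
            w = r / s[k] ** 2
            logp += float(-0.5 * np.sum(r**2) / s[k] ** 2
                          - self.N * np.log(s[k]) - 0.5 * self.N * LOG_2PI)
            g_t[:, k] += -w
            g_alpha[k] = np.sum(w)
            e = self.beta_of_node[k]
            if e >= 0:
                g_beta[e] = float(np.sum(w * x))
                if not self.from_position[k]:
                    g_t[:, self.parent[k]] += beta[e] * w
            g_logs_lik[k] = float(np.sum(r**2) / s[k] ** 2 - self.N)
            if self.ri:
                np.add.at(g_uraw[:, k], self.subj_idx, w * tau[k])
                g_tau_lik[k] = float(np.sum(w * u_raw[self.subj_idx, k]))

        # priors (on the raw-unit quantities; affine Jacobians are constant)
        logp += float(-0.5 * (np.sum(alpha**2) + np.sum(beta**2)) / self.ab_scale**2)
        g_alpha += -alpha / self.ab_scale**2
        g_beta += -beta / self.ab_scale**2
        lp_s, g_logs_prior = half_t_logp_grad(log_s, self.scale_prior)
        logp += lp_s
        g_logs = g_logs_lik + g_logs_prior
        # chain rule back to sampler coordinates
        parts = [
            (g_t * self.c_t).ravel(),
            g_alpha * self.c_b,
            g_beta * self.c_beta,
            g_logs,
        ]
        if self.ri:
            logp += float(-0.5 * np.sum(u_raw**2))
            g_uraw += -u_raw
            lp_tau, g_logtau_prior = half_t_logp_grad(log_tau, self.scale_prior)
            logp += lp_tau
            g_logtau = tau * g_tau_lik + g_logtau_prior
            parts += [g_uraw.ravel(), g_logtau]
        return logp, np.concatenate(parts)

    def constrain(self, theta):
        t, alpha, beta, log_s, u_raw, log_tau = self._split(theta)
        out = {"alpha": alpha, "sigma": np.exp(log_s)}
        if self.E:
            out["beta"] = beta
        if self.ri:
            out["tau"] = np.exp(log_tau)
        return out

    def pointwise_loglik(self, theta):
        t = self._split(theta)[0]
        resid = self.b - t
        ll = -0.5 * resid**2 / self.se2 - np.log(self.se) - 0.5 * LOG_2PI
        return ll.ravel()  # unit-major, node-minor: identical across specs


@dataclass
class PathPriors:
    ab_scale: Optional[float] = None  # None: 5 standardized, 10 sd(b) otherwise
    scale_df: float = 3.0


def _wide_arrays(data: pd.DataFrame, spec: PathModelSpec):
    unit_cols = ["subject", "run"]
    if POSITION_SOURCE in data.columns:
        unit_cols.append(POSITION_SOURCE)
    for n in spec.nodes:
        if n not in set(data["roi"]):
            raise DataError(f"node {n!r} missing from the observation table")
    sub = data[data["roi"].isin(spec.nodes)]
    wide_b = sub.pivot_table(index=unit_cols, columns="roi", values="beta")
    wide_se = sub.pivot_table(index=unit_cols, columns="roi", values="se")
    if wide_b[list(spec.nodes)].isna().any().any():
        raise DataError("incomplete units: every node needs a value per unit")
    units = wide_b.index.to_frame(index=False)
    b = wide_b[list(spec.nodes)].to_numpy(dtype=float)
    se = wide_se[list(spec.nodes)].to_numpy(dtype=float)
    subjects = sorted(units["subject"].unique())
    subj_idx = units["subject"].map({s: i for i, s in enumerate(subjects)}).to_numpy()
    position = (
        units[POSITION_SOURCE].to_numpy(dtype=float)
        if POSITION_SOURCE in units.columns
        else None
    )
    return b, se, subj_idx, position, units


class PathModel:
    """One structural model over the prepared observation table."""

    def __init__(self, data: pd.DataFrame, spec: PathModelSpec,
                 priors: Optional[PathPriors] = None):
        b, se, subj_idx, position, units = _wide_arrays(data, spec)
        if (se <= 0).any():
            raise DataError("non-positive SEs in observation table")
        priors = priors or PathPriors()
        sd_b = float(np.std(b)) or 1.0
        ab_scale = priors.ab_scale or (5.0 if spec.standardize else 10.0 * sd_b)
        scale_prior = 1.0 if spec.standardize else sd_b
        self.spec = spec
        self.data = data
        self.units = units
        self.ab_scale = ab_scale
        self._density = _PathDensity(b, se, subj_idx, position, spec,
                                     ab_scale, scale_prior)

    def fit(self, seed: int, chains: int = 6, iters: int = 2000,
            warmup: int = 1000, **kw) -> "PathResults":
        draws = sample_posterior(
            self._density, seed=seed, chains=chains, iters=iters, warmup=warmup, **kw
        )
        return PathResults(self, draws)


@dataclass
class PathResults:
    model: PathModel
    draws: PosteriorDraws

    @property
    def spec(self) -> PathModelSpec:
        return self.model.spec

    def waic(self) -> WAICResult:
        return waic(self.draws.log_likelihood)

    def beta_summaries(self) -> pd.DataFrame:
        if not self.spec.edges:
            return pd.DataFrame(
                columns=["name", "map", "hdi_lower", "hdi_upper", "pd", "p",
                         "bf10", "rhat", "edge"]
            )
        rng = np.random.default_rng(np.random.SeedSequence((self.draws.seed, 23)))
        # Savage-Dickey needs a minimum sample; omit BF on very short runs
        prior = (
            rng.normal(scale=self.model.ab_scale, size=20000)
            if self.draws.chains * self.draws.draws >= 1000
            else None
        )
        beta = self.draws.params["beta"]  # (chains, draws, E)
        rows = []
        for e, name in enumerate(self.spec.edge_names):
            s = summarize_draws(beta[..., e], name, prior_draws=prior).as_dict()
            s.update(edge=name)
            rows.append(s)
        return pd.DataFrame(rows)


def fit_path_model(data: pd.DataFrame, spec: PathModelSpec,
                   priors: Optional[PathPriors] = None, seed: int = 0,
                   **sampler_kw) -> PathResults:
    return PathModel(data, spec, priors).fit(seed=seed, **sampler_kw)


@dataclass
class ModelComparison:
    """WAIC table, pairwise differences, and the winner of one analysis."""

    analysis: str
    results: dict[str, PathResults]
    waics: dict[str, WAICResult]
    pairwise: list[dict]
    winner: str  # spec name or "inconclusive"
    directional: bool  # winner is directional and both directions beat the null

    def as_dict(self) -> dict:
        return {
            "analysis": self.analysis,
            "waic": {k: v.as_dict() for k, v in self.waics.items()},
            "pairwise": self.pairwise,
            "winner": self.winner,
            "directional": self.directional,
        }


def compare_path_models(
    data: pd.DataFrame,
    specs: Sequence[PathModelSpec],
    seed: int,
    priors: Optional[PathPriors] = None,
    **sampler_kw,
) -> ModelComparison:
    """Fit every spec on the identical observation set and compare by WAIC.

    A winner is declared only when its |WAIC difference| exceeds the SE
    against every competitor; a directional verdict additionally requires
    both directional models to beat the intercept-only null.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs))
    results: dict[str, PathResults] = {}
    for spec, child in zip(specs, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        results[spec.name] = fit_path_model(
            data, spec, priors=priors, seed=sub_seed, **sampler_kw
        )
    names = [s.name for s in specs]
    waics = {n: results[n].waic() for n in names}
    n_obs = {w.n_obs for w in waics.values()}
    if len(n_obs) != 1:
        raise AlignmentError("specs were fit on different observation sets")
    pairwise = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            delta, se, sig = waic_diff(waics[a], waics[b])
            pairwise.append(
                {"a": a, "b": b, "delta": delta, "se": se, "significant": sig}
            )
    best = min(names, key=lambda n: waics[n].waic)
    wins = all(
        abs(waics[best].waic - waics[n].waic)
        > waic_diff(waics[best], waics[n])[1]
        for n in names
        if n != best
    )
    winner = best if wins else "inconclusive"
    directional = False
    directional_names = [n for n in names if n not in ("null",)]
    if winner in directional_names and "null" in names:
        directional = all(
            waics[n].waic < waics["null"].waic
            and waic_diff(waics[n], waics["null"])[2]
            for n in directional_names
        )
    analysis = specs[0].analysis if specs else ""
    return ModelComparison(analysis, results, waics, pairwise, winner, directional)
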