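"""Event-related first-level GLM: design matrices and per-ROI fits.

Condition events are modeled as zero-duration impulses on a fine time grid,
convolved with a canonical double-gamma haemodynamic response, and sampled at
volume acquisition times.  Parametric modulators (ordinal within-sequence
position for the pre- and post-deviant standards) ride on the same impulses
after within-run mean-centering.  Fits are ordinary least squares with
optional AR(1) prewhitening, returning per-condition estimates with standard
errors both per run and pooled across runs by inverse-variance weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .design import (
    ExperimentDesign,
    ODDBALL_CONDITIONS,
    PHASEFLIP_CONDITIONS,
    RunDesign,
)
from .exceptions import DataError, DegenerateDesignError

MODULATED_CONDITIONS = ("std1", "std2")
HRF_TAIL = 32.0  # seconds of response modeled after an event


def hrf(
    t: np.ndarray,
    peak: float = 6.0,
    undershoot: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, scaled to peak 1.

    Difference of two gamma densities with modes at ``peak`` and
    ``undershoot`` seconds (unit scale) and undershoot weight ``ratio``;
    zero at t = 0.
    """
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, a=peak + 1.0) - ratio * gamma_dist.pdf(t, a=undershoot + 1.0)
    peak_val = h.max() if h.size else 1.0
    if peak_val <= 0:
        dense = np.linspace(0, HRF_TAIL, 2048)
        peak_val = (
            gamma_dist.pdf(dense, a=peak + 1.0)
            - ratio * gamma_dist.pdf(dense, a=undershoot + 1.0)
        ).max()
    return h / peak_val


def cosine_drift(n_volumes: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass basis up to 1/cutoff Hz (constant excluded)."""
    duration = n_volumes * tr
    order = int(np.floor(2.0 * duration / cutoff))
    t = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes))
        for k in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


@dataclass
class DesignMatrix:
    """A volumes x regressors matrix with named column groups."""

    frame: pd.DataFrame
    condition_columns: list[str]
    modulator_columns: list[str]
    nuisance_columns: list[str]
    drift_columns: list[str]
    tr: float

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n_volumes(self) -> int:
        return len(self.frame)


def _convolve_sticks(
    onsets: np.ndarray,
    weights: np.ndarray,
    n_volumes: int,
    tr: float,
    dt: float,
) -> np.ndarray:
    """Weighted impulses on a dt grid, HRF-convolved, sampled at volume times."""
    n_fine = int(np.ceil((n_volumes * tr + HRF_TAIL) / dt)) + 1
    neural = np.zeros(n_fine)
    idx = np.round(onsets / dt).astype(int)
    np.add.at(neural, idx, weights)
    kernel = hrf(np.arange(0.0, HRF_TAIL, dt))
    bold = np.convolve(neural, kernel)[:n_fine]
    vol_times = np.arange(n_volumes) * tr
    return np.interp(vol_times, np.arange(n_fine) * dt, bold)


def build_design_matrix(
    events: pd.DataFrame,
    condition_set: str,
    nuisance: Optional[pd.DataFrame],
    tr: float,
    n_volumes: int,
    dt: float = 0.05,
    hp_cutoff: float = 128.0,
) -> DesignMatrix:
    """Build the design matrix for one run.

    ``condition_set`` is "oddball" (6 conditions + 2 position modulators) or
    "phaseflip" (3 conditions from the block labels).  Silent events mark the
    baseline and get no regressor.
    """
    events = events.sort_values("onset").reset_index(drop=True)
    tone = events[events["trial_type"] != "silent"]
    if tone.empty:
        raise DegenerateDesignError("no tone events in run: condition columns empty")
    if (np.diff(events["onset"].to_numpy()) < 0).any():
        raise DataError("event onsets must be non-decreasing")

    cols: dict[str, np.ndarray] = {}
    cond_cols: list[str] = []
    mod_cols: list[str] = []

    if condition_set == "oddball":
        labels = ODDBALL_CONDITIONS
        key = "trial_type"
    elif condition_set == "phaseflip":
        labels = PHASEFLIP_CONDITIONS
        key = "block_condition"
        if tone[key].isna().any():
            raise DataError("phaseflip set requires block_condition on tone events")
    else:
        raise DataError(f"unknown condition set {condition_set!r}")

    unknown = set(tone[key].dropna()) - set(labels)
    if unknown:
        raise DataError(f"unknown {key} labels: {sorted(unknown)}")

    for lab in labels:
        sub = tone[tone[key] == lab]
        if sub.empty:
            raise DegenerateDesignError(f"condition {lab!r} has no events")
        onsets = sub["onset"].to_numpy()
        cols[lab] = _convolve_sticks(onsets, np.ones(len(sub)), n_volumes, tr, dt)
        cond_cols.append(lab)

    if condition_set == "oddball":
        for lab in MODULATED_CONDITIONS:
            sub = tone[tone[key] == lab]
            mods = sub["modulator"].to_numpy(dtype=float)
            if np.isnan(mods).any():
                raise DataError(f"missing modulator values for {lab}")
            centered = mods - mods.mean()  # orthogonal to the run intercept
            name = f"{lab}_pos"
            cols[name] = _convolve_sticks(
                sub["onset"].to_numpy(), centered, n_volumes, tr, dt
            )
            mod_cols.append(name)

    nuis_cols: list[str] = []
    if nuisance is not None and len(nuisance.columns):
        if len(nuisance) != n_volumes:
            raise DataError("nuisance rows must match the number of volumes")
        for c in nuisance.columns:
            name = f"nuis_{c}"
            cols[name] = nuisance[c].to_numpy(dtype=float)
            nuis_cols.append(name)

    drift = cosine_drift(n_volumes, tr, hp_cutoff)
    drift_cols = []
    for k in range(drift.shape[1]):
        name = f"drift_{k + 1}"
        cols[name] = drift[:, k]
        drift_cols.append(name)
    cols["intercept"] = np.ones(n_volumes)
    drift_cols.append("intercept")

    frame = pd.DataFrame(cols)
    X = frame.to_numpy()
    zero = ~np.any(X != 0.0, axis=0)
    if zero.any():
        bad = [frame.columns[i] for i in np.flatnonzero(zero)]
        raise DegenerateDesignError(f"all-zero design columns: {bad}")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DegenerateDesignError(_describe_collinearity(frame))
    return DesignMatrix(frame, cond_cols, mod_cols, nuis_cols, drift_cols, tr)


def _describe_collinearity(frame: pd.DataFrame) -> str:
    """Name the columns involved in a rank deficiency (smallest singular vector)."""
    X = frame.to_numpy()
    Xn = X / np.linalg.norm(X, axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(Xn, full_matrices=False)
    v = np.abs(vt[-1])
    involved = [c for c, w in zip(frame.columns, v) if w > 0.1]
    return f"design matrix is rank deficient; collinear columns include {involved}"


@dataclass
class ROIGLMResults:
    """OLS (optionally AR(1)-prewhitened) estimates for one ROI and run."""

    params: pd.Series
    bse: pd.Series
    rho: float
    sigma: float
    df_resid: int
    resid: np.ndarray
    design: DesignMatrix

    def condition_estimates(self) -> pd.DataFrame:
        keep = self.design.condition_columns + self.design.modulator_columns
        return pd.DataFrame(
            {
                "condition": keep,
                "beta": [self.params[c] for c in keep],
                "se": [self.bse[c] for c in keep],
            }
        )


class ROIGLM:
    """General linear model for a single ROI time series.

    Ordinary least squares; with ``ar1=True`` the AR(1) coefficient is
    estimated from the OLS residuals and both sides are prewhitened
    (Cochrane-Orcutt with exact scaling of the first observation) before the
    final fit.
    """

    def __init__(self, endog: np.ndarray, design: DesignMatrix):
        y = np.asarray(endog, dtype=float).ravel()
        if len(y) != design.n_volumes:
            raise DataError("time series length does not match design matrix rows")
        if not np.all(np.isfinite(y)):
            raise DataError("non-finite values in time series")
        self.endog = y
        self.design = design

    def fit(self, ar1: bool = True) -> ROIGLMResults:
        X = self.design.values
        y = self.endog
        beta, resid = _ols(y, X)
        rho = 0.0
        if ar1:
            denom = float(resid[:-1] @ resid[:-1])
            rho = float(resid[1:] @ resid[:-1] / denom) if denom > 0 else 0.0
            rho = float(np.clip(rho, -0.99, 0.99))
            c = np.sqrt(1.0 - rho**2)
            yw = np.concatenate(([y[0] * c], y[1:] - rho * y[:-1]))
            Xw = np.vstack([X[0] * c, X[1:] - rho * X[:-1]])
            beta, resid = _ols(yw, Xw)
            X = Xw
        n, p = X.shape
        df = n - p
        sigma2 = float(resid @ resid) / df
        cov = sigma2 * np.linalg.inv(X.T @ X)
        cols = self.design.columns
        return ROIGLMResults(
            params=pd.Series(beta, index=cols),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=cols),
            rho=rho,
            sigma=float(np.sqrt(sigma2)),
            df_resid=df,
            resid=resid,
            design=self.design,
        )


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError("rank-deficient design in GLM fit")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta, y - X @ beta


def fit_roi_glm(
    y: np.ndarray, design: DesignMatrix, ar1_correction: bool = True
) -> ROIGLMResults:
    """Functional wrapper around :class:`ROIGLM`."""
    return ROIGLM(y, design).fit(ar1=ar1_correction)


def pool_runs(estimates: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance weighted pooling of per-run estimates to one row per
    subject x roi x condition (run label "pooled")."""
    def _pool(g: pd.DataFrame) -> pd.Series:
        w = 1.0 / g["se"] ** 2
        beta = float((w * g["beta"]).sum() / w.sum())
        return pd.Series({"beta": beta, "se": float(np.sqrt(1.0 / w.sum()))})

    pooled = (
        estimates.groupby(["subject", "roi", "condition"])
        .apply(_pool, include_groups=False)
        .reset_index()
    )
    pooled.insert(1, "run", "pooled")
    return pooled[["subject", "run", "roi", "condition", "beta", "se"]]


def fit_first_level(
    design: ExperimentDesign,
    bold: Mapping[int, pd.DataFrame],
    nuisance: Optional[Mapping[int, pd.DataFrame]] = None,
    condition_set: str = "oddball",
    ar1_correction: bool = True,
    subject: str | int = 0,
) -> pd.DataFrame:
    """Fit every run x ROI GLM of a session and return the estimate table.

    ``bold`` maps run index to a volumes x ROI data frame.  Returns rows with
    schema subject, run, roi, condition, beta, se — per-run rows plus pooled
    rows per subject.
    """
    rows = []
    for run_design in design.runs:
        r = run_design.run
        data = bold[r]
        nuis = nuisance[r] if nuisance is not None else None
        dm = build_design_matrix(
            run_design.events_frame(),
            condition_set,
            nuis,
            design.params.tr,
            len(data),
        )
        for roi in data.columns:
            res = ROIGLM(data[roi].to_numpy(), dm).fit(ar1=ar1_correction)
            est = res.condition_estimates()
            est.insert(0, "roi", roi)
            est.insert(0, "run", r)
            est.insert(0, "subject", subject)
            rows.append(est)
    per_run = pd.concat(rows, ignore_index=True)
    condition_rows = per_run[~per_run["condition"].str.endswith("_pos")]
    pooled = pool_runs(condition_rows)
    modulators = per_run[per_run["condition"].str.endswith("_pos")]
    return pd.concat([condition_rows, modulators, pooled], ignore_index=True)
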