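"""Forward simulation: ROI BOLD time courses and 3AFC behavior.

The BOLD generator is the exact forward model of the first-level GLM: per
tone event a stick scaled by the ROI x condition amplitude (plus optional
modulator slopes), convolved with the shared canonical HRF and sampled at the
TR, to which low-frequency cosine drift and AR(1) noise are added.  With the
noise and drift turned off, fitting the matched GLM returns the generative
amplitudes exactly (round-trip identity), which the tests exploit.

The default amplitude profile encodes the qualitative expectancy pattern the
oddball paradigm is built around: a strong response to the first tone of a
sequence, adaptation for repeated standards, a strong response to the least
predictable deviant (position 4), and progressively suppressed responses as
the deviant becomes more certain — monotone over dev4 -> dev5 -> dev6 in the
"suppressive" regions (IC, MGB, AC), with cortical effects roughly four times
the subcortical ones, while STG responds to all deviants alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .afc import mafc_pc
from .design import ExperimentDesign, ODDBALL_CONDITIONS, ROIS, RunDesign
from .exceptions import DataError
from .glm import DesignMatrix, build_design_matrix, cosine_drift

SUPPRESSIVE_ROIS = ("IC", "MGB", "AC")

_DEFAULT_AMPLITUDES = pd.DataFrame(
    {
        # condition:  std0  std1  dev4  dev5  dev6  std2
        "IC": [11.0, 5.0, 12.0, 8.0, 3.0, 3.0],
        "MGB": [12.0, 5.0, 9.0, 7.0, 6.0, 5.0],
        "AC": [30.0, 5.0, 28.0, 15.0, 6.0, 4.0],
        "STG": [11.0, 5.0, 15.0, 14.5, 14.0, 4.0],
    },
    index=list(ODDBALL_CONDITIONS),
).T


@dataclass
class GroundTruth:
    """Generative settings for the BOLD and behavioral simulators."""

    amplitudes: pd.DataFrame = field(
        default_factory=lambda: _DEFAULT_AMPLITUDES.copy()
    )
    modulator_slopes: Mapping[str, float] | None = None  # condition -> slope
    ar1_rho: float = 0.3
    noise_sd: float = 6.0
    drift_amplitude: float = 3.0
    nuisance_sd: float = 0.0
    dprime_group_mean: float = 3.38
    dprime_group_sd: float = 0.5

    def __post_init__(self) -> None:
        missing = set(ODDBALL_CONDITIONS) - set(self.amplitudes.columns)
        if missing:
            raise DataError(f"amplitude table missing conditions: {sorted(missing)}")
        for roi in SUPPRESSIVE_ROIS:
            if roi in self.amplitudes.index:
                a = self.amplitudes.loc[roi, ["dev4", "dev5", "dev6"]].to_numpy()
                if not (a[0] >= a[1] >= a[2]):
                    raise DataError(
                        f"suppressive ROI {roi} must be monotone non-increasing "
                        "over dev4 -> dev5 -> dev6"
                    )

    @property
    def rois(self) -> list[str]:
        return list(self.amplitudes.index)


def default_ground_truth(**overrides) -> GroundTruth:
    return GroundTruth(**overrides)


def simulate_nuisance(
    n_volumes: int, seed: int | np.random.Generator, n_regressors: int = 6
) -> pd.DataFrame:
    """Six smooth seeded random walks standing in for motion parameters."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_volumes, n_regressors))
    walk = np.cumsum(steps, axis=0)
    kernel = np.hanning(21)
    kernel /= kernel.sum()
    smooth = np.column_stack(
        [np.convolve(walk[:, j], kernel, mode="same") for j in range(n_regressors)]
    )
    smooth -= smooth.mean(axis=0)
    sd = smooth.std(axis=0)
    sd[sd == 0] = 1.0
    smooth /= sd
    return pd.DataFrame(smooth, columns=[f"motion_{j + 1}" for j in range(n_regressors)])


def _ar1_noise(
    rng: np.random.Generator, n: int, rho: float, sd: float
) -> np.ndarray:
    e = rng.normal(scale=sd, size=n)
    x = np.empty(n)
    x[0] = e[0] / np.sqrt(1.0 - rho**2) if abs(rho) < 1 else e[0]
    for t in range(1, n):
        x[t] = rho * x[t - 1] + e[t]
    return x


@dataclass
class ROITimeSeries:
    """Simulated BOLD for one ROI and run, with its nuisance regressors."""

    roi: str
    run: int
    values: np.ndarray
    tr: float
    nuisance: pd.DataFrame
    design_matrix: DesignMatrix


def simulate_roi_bold(
    run_design: RunDesign,
    truth: GroundTruth,
    roi: str,
    seed: int | np.random.Generator,
    n_volumes: Optional[int] = None,
    nuisance: Optional[pd.DataFrame] = None,
) -> ROITimeSeries:
    """Simulate one run of one ROI's BOLD signal from the ground truth."""
    if roi not in truth.amplitudes.index:
        raise KeyError(f"unknown ROI label {roi!r}")
    rng = np.random.default_rng(seed)
    n_vol = n_volumes if n_volumes is not None else run_design.n_volumes
    tr = run_design.params.tr

    dm = build_design_matrix(
        run_design.events_frame(), "oddball", None, tr, n_vol
    )
    amps = truth.amplitudes.loc[roi]
    beta = np.zeros(len(dm.columns))
    cols = dm.columns
    for cond in ODDBALL_CONDITIONS:
        beta[cols.index(cond)] = amps[cond]
    if truth.modulator_slopes:
        for cond, slope in truth.modulator_slopes.items():
            beta[cols.index(f"{cond}_pos")] = slope
    signal = dm.values @ beta

    drift_basis = cosine_drift(n_vol, tr)
    if drift_basis.shape[1] and truth.drift_amplitude > 0:
        weights = rng.normal(scale=truth.drift_amplitude, size=drift_basis.shape[1])
        signal = signal + drift_basis @ weights

    if nuisance is None:
        nuisance = simulate_nuisance(n_vol, rng)
    if truth.nuisance_sd > 0:
        weights = rng.normal(scale=truth.nuisance_sd, size=nuisance.shape[1])
        signal = signal + nuisance.to_numpy() @ weights

    if truth.noise_sd > 0:
        signal = signal + _ar1_noise(rng, n_vol, truth.ar1_rho, truth.noise_sd)

    return ROITimeSeries(roi, run_design.run, signal, tr, nuisance, dm)


def simulate_experiment_bold(
    design: ExperimentDesign,
    truth: GroundTruth,
    seed: int,
) -> tuple[dict[int, pd.DataFrame], dict[int, pd.DataFrame]]:
    """Simulate all runs x ROIs; returns (bold, nuisance) keyed by run index.

    All ROIs of a run share the nuisance regressors, as motion is a
    run-level process.
    """
    ss = np.random.SeedSequence(seed)
    bold: dict[int, pd.DataFrame] = {}
    nuis: dict[int, pd.DataFrame] = {}
    for run_design, child in zip(design.runs, ss.spawn(len(design.runs))):
        n_vol = run_design.n_volumes
        sub = child.spawn(len(truth.rois) + 1)
        nuisance = simulate_nuisance(n_vol, np.random.default_rng(sub[0]))
        series = {}
        for roi, s in zip(truth.rois, sub[1:]):
            ts = simulate_roi_bold(
                run_design, truth, roi, np.random.default_rng(s), n_vol, nuisance
            )
            series[roi] = ts.values
        bold[run_design.run] = pd.DataFrame(series)
        nuis[run_design.run] = nuisance
    return bold, nuis


def simulate_behavior(
    design: ExperimentDesign,
    truth: GroundTruth,
    n_subjects: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate 3AFC position reports for every tone trial of the session.

    Per subject a sensitivity d'_s ~ Normal(group mean, group sd); per trial
    the target position's strength is Normal(d'_s, 1) against two standard
    normal distractors, and the response is the position of the maximum.
    """
    if n_subjects < 1:
        raise DataError("need at least one subject")
    rng = np.random.default_rng(seed)
    positions = list(design.params.deviant_positions)
    rows = []
    for s in range(n_subjects):
        d_s = rng.normal(truth.dprime_group_mean, truth.dprime_group_sd)
        for run in design.runs:
            for trial in run.tone_trials:
                strengths = rng.normal(size=len(positions))
                target = positions.index(trial.deviant_position)
                strengths[target] += d_s
                response = positions[int(np.argmax(strengths))]
                rows.append(
                    dict(
                        subject=s,
                        run=run.run,
                        trial=trial.index,
                        position=trial.deviant_position,
                        response=response,
                        correct=int(response == trial.deviant_position),
                    )
                )
    return pd.DataFrame(rows)
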