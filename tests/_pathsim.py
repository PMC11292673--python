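"""Generative twins of the path models, used as recovery/selection oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd

DETECTION_BETAS = (1.33, 3.1, 0.3)      # IC->MGB, MGB->AC, AC->STG
SUPPRESSION_BETAS = (-0.92, 0.78, 0.88)  # position->AC, AC->MGB, MGB->IC


def simulate_detection_table(
    seed: int,
    betas=DETECTION_BETAS,
    n_subjects: int = 10,
    n_runs: int = 4,
    root_mean: float = 11.0,
    root_sd: float = 2.0,
    resid_sd=(2.0, 4.0, 2.0),
    se_scale: float = 1.5,
    direction: str = "bottom_up",
) -> pd.DataFrame:
    """std0 observations from a latent chain IC->MGB->AC->STG (or its mirror)."""
    rng = np.random.default_rng(seed)
    order = ["IC", "MGB", "AC", "STG"]
    if direction == "top_down":
        order = order[::-1]
    rows = []
    for s in range(n_subjects):
        for r in range(n_runs):
            t = {order[0]: rng.normal(root_mean, root_sd)}
            for (b, sd, parent, child) in zip(
                betas, resid_sd, order[:-1], order[1:]
            ):
                t[child] = b * t[parent] + rng.normal(0.0, sd)
            for roi in order:
                se = se_scale * (0.8 + 0.4 * rng.random())
                rows.append(
                    dict(subject=s, run=r, roi=roi, condition="std0",
                         beta=t[roi] + rng.normal(0.0, se), se=se)
                )
    return pd.DataFrame(rows)


def simulate_suppression_table(
    seed: int,
    betas=SUPPRESSION_BETAS,
    n_subjects: int = 10,
    n_runs: int = 4,
    resid_sd=(0.6, 0.6, 0.6),
    tau: float = 0.3,
    se_scale: float = 0.4,
    direction: str = "top_down",
) -> pd.DataFrame:
    """Deviant observations: position drives the first ROI of the chain.

    Generated on an approximately standardized scale (the preparation step
    re-standardizes per subject and ROI before fitting).
    """
    rng = np.random.default_rng(seed)
    if direction == "top_down":
        order = ["AC", "MGB", "IC"]
    else:
        order = ["IC", "MGB", "AC"]
    cond_of = {1: "dev4", 2: "dev5", 3: "dev6"}
    rows = []
    for s in range(n_subjects):
        u = {roi: rng.normal(0.0, tau) for roi in order}
        for r in range(n_runs):
            for pos in (1, 2, 3):
                t = {order[0]: betas[0] * pos + u[order[0]]
                     + rng.normal(0.0, resid_sd[0])}
                for (b, sd, parent, child) in zip(
                    betas[1:], resid_sd[1:], order[:-1], order[1:]
                ):
                    t[child] = b * t[parent] + u[child] + rng.normal(0.0, sd)
                for roi in order:
                    se = se_scale * (0.8 + 0.4 * rng.random())
                    rows.append(
                        dict(subject=s, run=r, roi=roi, condition=cond_of[pos],
                             beta=t[roi] + rng.normal(0.0, se), se=se)
                    )
    return pd.DataFrame(rows)
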