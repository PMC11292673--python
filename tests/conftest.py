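"""Shared fixtures: small seeded designs and synthetic estimate tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from predsupp.design import (
    DesignParams,
    assign_block_conditions,
    generate_experiment,
    generate_run_design,
)

SMALL_PARAMS = DesignParams(
    blocks_per_run=3,
    trials_per_block=3,
    silent_trials_per_run=4,
    n_runs=2,
)


@pytest.fixture(scope="session")
def default_run():
    return generate_run_design(1)


@pytest.fixture(scope="session")
def default_experiment():
    return generate_experiment(1)


@pytest.fixture(scope="session")
def small_experiment():
    """A 2-run, 9-tone-trial design for fast end-to-end tests."""
    return assign_block_conditions(generate_experiment(5, SMALL_PARAMS), seed=6)


def make_estimates(
    seed: int,
    n_subjects: int = 6,
    n_runs: int = 2,
    rois=("IC", "MGB", "AC", "STG"),
    conditions=("std0", "std1", "dev4", "dev5", "dev6", "std2"),
    means=None,
    tau: float = 1.0,
    sigma: float = 2.0,
    se_scale: float = 1.5,
    roi_corr: np.ndarray | None = None,
) -> pd.DataFrame:
    """Estimate table generated from the second-level model's own structure.

    ``roi_corr`` optionally correlates the cell-level residuals across ROIs
    (defaults to independence).
    """
    rng = np.random.default_rng(seed)
    K = len(rois)
    L = np.linalg.cholesky(roi_corr) if roi_corr is not None else np.eye(K)
    rows = []
    for s in range(n_subjects):
        u = {roi: rng.normal(0.0, tau) for roi in rois}
        for r in range(n_runs):
            for c in conditions:
                eps = sigma * (L @ rng.normal(size=K))
                for k, roi in enumerate(rois):
                    m = 0.0 if means is None else means[roi][c]
                    se = se_scale * (0.8 + 0.4 * rng.random())
                    beta = m + u[roi] + eps[k] + rng.normal(0.0, se)
                    rows.append(
                        dict(subject=s, run=r, roi=roi, condition=c, beta=beta, se=se)
                    )
    return pd.DataFrame(rows)


def chain_correlation(rho: float = 0.6, K: int = 4) -> np.ndarray:
    """Adjacent-pair correlation matrix (AR(1)-style chain structure)."""
    idx = np.arange(K)
    return rho ** np.abs(idx[:, None] - idx[None, :])


@pytest.fixture
def estimates_null():
    return make_estimates(seed=11)
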