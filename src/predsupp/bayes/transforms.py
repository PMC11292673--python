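"""Reusable log-density building blocks with analytic gradients.

All model log densities in this package are hand-differentiated; the helpers
here cover the recurring pieces: positive scales sampled on the log axis with
half-Student-t priors, and correlation matrices sampled through the C-vine
canonical-partial-correlation construction of the LKJ distribution.

The LKJ piece deserves a note.  Sampling independent canonical partial
correlations x_ij ~ 2 Beta(b_j, b_j) - 1 with b_j = eta + (K - 2 - j)/2
(j the size of the conditioning set) and assembling the Cholesky factor row
by row generates exactly an LKJ(eta) correlation matrix — this is the
generative definition of the distribution.  Writing x = tanh(z) for an
unconstrained z, the induced log density collapses to b_j log(1 - x^2) up to
a constant, with gradient -2 b_j tanh(z).  Gradients of the likelihood with
respect to z are obtained by forward-mode tangents dL/dz_k propagated
through the row-by-row construction.
"""

from __future__ import annotations

import numpy as np

LOG_2PI = float(np.log(2.0 * np.pi))


def normal_logpdf(x: np.ndarray, mu, sd) -> np.ndarray:
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * LOG_2PI


def half_t_logp_grad(log_scale: np.ndarray, prior_scale, df: float = 3.0):
    """Log density and gradient for scale = exp(log_scale) ~ half-t(df, A).

    Includes the log-Jacobian of the log transform, so the returned values
    are the contribution to the unconstrained-space target.
    """
    s = np.exp(log_scale)
    q = (s / prior_scale) ** 2 / df
    logp = -0.5 * (df + 1.0) * np.log1p(q) + log_scale
    # d/dlog_scale = s * dlogp/ds + 1
    dlogp_ds = -(df + 1.0) * s / (df * prior_scale**2 * (1.0 + q))
    grad = s * dlogp_ds + 1.0
    return np.sum(logp), grad


def half_normal_logp_grad(log_scale: np.ndarray, prior_scale):
    """scale = exp(log_scale) ~ half-normal(A), with log-transform Jacobian."""
    s = np.exp(log_scale)
    logp = -0.5 * (s / prior_scale) ** 2 + log_scale
    grad = -(s / prior_scale) ** 2 + 1.0
    return np.sum(logp), grad


def lkj_vine_beta_params(K: int, eta: float) -> np.ndarray:
    """Beta shape b_j for each canonical partial correlation, in row-major
    order of the strict lower triangle (i from 1, j from 0 to i-1)."""
    out = []
    for i in range(1, K):
        for j in range(i):
            out.append(eta + 0.5 * (K - 2 - j))
    return np.array(out)


def lkj_z_logp_grad(z: np.ndarray, K: int, eta: float):
    """Prior contribution of the unconstrained correlation parameters."""
    b = lkj_vine_beta_params(K, eta)
    x = np.tanh(z)
    logp = float(np.sum(b * np.log1p(-(x**2))))
    grad = -2.0 * b * x
    return logp, grad


def corr_chol_with_tangents(z: np.ndarray, K: int):
    """Cholesky factor L of a correlation matrix from unconstrained z, plus
    forward-mode tangents T[k] = dL/dz_k.

    Row-by-row construction: L[i,0] = x[i,0]; L[i,j] = x[i,j] sqrt(1 - s)
    with s the running sum of squares of the row; L[i,i] = sqrt(1 - s).
    """
    nz = K * (K - 1) // 2
    if z.shape != (nz,):
        raise ValueError(f"expected {nz} correlation parameters, got {z.shape}")
    x = np.tanh(z)
    dx = 1.0 - x**2  # dx/dz
    L = np.zeros((K, K))
    T = np.zeros((nz, K, K))
    L[0, 0] = 1.0
    k = 0
    for i in range(1, K):
        s = 0.0
        ds = np.zeros(nz)
        for j in range(i):
            root = np.sqrt(max(1.0 - s, 1e-15))
            droot = -ds / (2.0 * root)
            L[i, j] = x[k] * root
            T[:, i, j] = x[k] * droot
            T[k, i, j] += dx[k] * root
            ds = ds + 2.0 * L[i, j] * T[:, i, j]
            s = s + L[i, j] ** 2
            k += 1
        root = np.sqrt(max(1.0 - s, 1e-15))
        L[i, i] = root
        T[:, i, i] = -ds / (2.0 * root)
    return L, T
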