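"""Fractional Gaussian noise synthesis.

Fractional Brownian motion (fBM) with Hurst exponent H = alpha/2 has
stationary increments -- fractional Gaussian noise (fGN) -- whose
autocovariance at integer lag k is

    gamma(k) = sigma^2/2 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}).

Sub-diffusive trajectories (alpha < 1) have anti-correlated increments,
super-diffusive ones (alpha > 1) positively correlated increments, and
alpha = 1 recovers ordinary Brownian motion with independent steps.

Synthesis uses Davies-Harte circulant embedding (exact covariance,
O(n log n)); when the embedding is not positive semi-definite the code
falls back to a Cholesky factorisation of the Toeplitz covariance.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cholesky, toeplitz

__all__ = ["fgn_autocovariance", "sample_fgn"]


def fgn_autocovariance(alpha: float, lags: np.ndarray | int) -> np.ndarray:
    """Exact unit-variance fGN autocovariance gamma(k) at the given lags.

    The |0|^{2H} term is taken as 0 for every H >= 0 so that the H -> 0
    limit gamma(1) = -1/2 is reached continuously at alpha = 0.
    """
    k = np.atleast_1d(np.asarray(lags, dtype=float))
    twoH = float(alpha)

    def pw(v: np.ndarray) -> np.ndarray:
        a = np.abs(v)
        out = np.zeros_like(a)
        nz = a > 0
        out[nz] = a[nz] ** twoH
        return out

    return 0.5 * (pw(k + 1) - 2.0 * pw(k) + pw(k - 1))


def sample_fgn(alpha: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` unit-scale fGN increments with Hurst exponent alpha/2.

    Parameters
    ----------
    alpha : anomalous exponent in [0, 2]; H = alpha/2.
    n : number of increments (>= 1).
    rng : NumPy random generator.

    Returns
    -------
    1-D array of length ``n``; cumulative sums form a unit fBM path with
    Var[B_H(t)] = t^{2H}.
    """
    if not 0.0 <= alpha <= 2.0:
        raise ValueError(f"alpha must lie in [0, 2], got {alpha}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if alpha == 2.0:
        # H = 1: increments perfectly correlated -> ballistic motion,
        # a single Gaussian draw repeated.
        return np.full(n, rng.standard_normal())
    if alpha == 1.0:
        return rng.standard_normal(n)

    gamma = fgn_autocovariance(alpha, np.arange(n))
    # Circulant embedding of size 2n: [g0 .. g_{n-1}, 0, g_{n-1} .. g1]
    row = np.concatenate([gamma, [0.0], gamma[-1:0:-1]])
    eig = np.fft.fft(row).real
    if np.min(eig) >= -1e-10:
        eig = np.clip(eig, 0.0, None)
        m = 2 * n
        z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        w = np.fft.fft(np.sqrt(eig / (2.0 * m)) * z)
        return np.sqrt(2.0) * w[:n].real
    # Rare non-PSD embedding: exact but O(n^2) fallback.
    cov = toeplitz(gamma)
    lower = cholesky(cov, lower=True)
    return lower @ rng.standard_normal(n)
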