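"""Fractional Gaussian noise generation.

Fractional Brownian motion B_H is the Gaussian process with stationary
increments and Var B_H(t) = t^(2H); its unit-step increments (fractional
Gaussian noise, fGn) have autocovariance

    gamma(j) = 0.5 * (|j+1|^(2H) - 2|j|^(2H) + |j-1|^(2H)),

negative at all lags for H < 1/2 (anti-persistent walks, the obstructed
diffusion regime) and zero for H = 1/2 (ordinary white noise).  The primary
generator embeds the Toeplitz covariance in a circulant matrix and samples
it exactly by FFT (Davies–Harte / Dietrich–Newsam); an O(n²) Cholesky
factorisation of the covariance is kept both as a fallback for the rare
embeddings with negative eigenvalues and as an independent oracle in tests.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError

__all__ = ["fgn_autocovariance", "fgn_davies_harte", "fgn_cholesky", "FgnSampler"]


def _check_hurst(hurst: float) -> None:
    if not 0.0 < hurst < 1.0:
        raise DomainError(f"Hurst exponent must lie in (0, 1), got {hurst}")


def fgn_autocovariance(hurst: float, n_lags: int) -> np.ndarray:
    """Autocovariance gamma(0..n_lags-1) of unit-variance fGn."""
    _check_hurst(hurst)
    j = np.arange(n_lags, dtype=float)
    two_h = 2.0 * hurst
    return 0.5 * (np.abs(j + 1) ** two_h - 2.0 * np.abs(j) ** two_h + np.abs(j - 1) ** two_h)


class FgnSampler:
    """Reusable Davies–Harte sampler for fixed (hurst, n_steps).

    Precomputes the circulant eigenvalues once; :meth:`sample` then costs a
    single batched FFT.  Falls back to Cholesky when the circulant embedding
    is not non-negative definite (does not occur for fGn in practice, but
    the guard is cheap).
    """

    def __init__(self, hurst: float, n_steps: int):
        _check_hurst(hurst)
        if n_steps < 1:
            raise DomainError(f"n_steps must be >= 1, got {n_steps}")
        self.hurst = float(hurst)
        self.n_steps = int(n_steps)
        gamma = fgn_autocovariance(hurst, n_steps + 1)
        circ = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2*n_steps
        eig = np.fft.fft(circ).real
        tol = -1e-10 * max(1.0, eig.max())
        if eig.min() < tol:
            self._eig = None  # not embeddable; use Cholesky
            cov = _toeplitz(gamma[:-1])
            self._chol = np.linalg.cholesky(cov)
        else:
            self._eig = np.sqrt(np.clip(eig, 0.0, None))
            self._chol = None

    def sample(self, rng: np.random.Generator, n_paths: int = 1) -> np.ndarray:
        """Draw fGn, shape (n_paths, n_steps)."""
        n = self.n_steps
        if self._eig is None:
            z = rng.standard_normal((n_paths, n))
            return z @ self._chol.T
        m = 2 * n
        # Hermitian half-spectrum with the circulant eigenvalues; the
        # inverse real FFT then realises the full symmetric transform.
        u = rng.standard_normal((n_paths, n + 1))
        v = rng.standard_normal((n_paths, n - 1))
        w = np.empty((n_paths, n + 1), dtype=np.complex128)
        w[:, 0] = np.sqrt(1.0 / m) * self._eig[0] * u[:, 0]
        w[:, n] = np.sqrt(1.0 / m) * self._eig[n] * u[:, n]
        half = np.sqrt(0.5 / m)
        w[:, 1:n] = half * self._eig[1:n] * (u[:, 1:n] + 1j * v)
        return m * np.fft.irfft(w, n=m, axis=1)[:, :n]


def fgn_davies_harte(
    hurst: float, n_steps: int, rng: np.random.Generator, n_paths: int = 1
) -> np.ndarray:
    """One-shot Davies–Harte fGn draw, shape (n_paths, n_steps)."""
    return FgnSampler(hurst, n_steps).sample(rng, n_paths)


def fgn_cholesky(
    hurst: float, n_steps: int, rng: np.random.Generator, n_paths: int = 1
) -> np.ndarray:
    """Exact fGn by Cholesky factorisation of the covariance (O(n²) memory).

    Independent of the FFT route; used as the cross-check oracle.
    """
    _check_hurst(hurst)
    cov = _toeplitz(fgn_autocovariance(hurst, n_steps))
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_paths, n_steps))
    return z @ chol.T


def _toeplitz(col: np.ndarray) -> np.ndarray:
    n = len(col)
    idx = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    return col[idx]
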