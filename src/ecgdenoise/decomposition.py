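"""Empirical and variational mode decomposition, plus the final VMD smoothing.

EMD follows classic sifting: cubic-spline upper/lower envelopes through the
local maxima/minima (mirror boundary extension), iterated until the Cauchy
criterion SD = Σ(h_prev − h)² / Σ h_prev² falls below ``sift_sd`` or the sift
budget is exhausted; the decomposition ends when the remainder has fewer than
two extrema. Conservation — input == Σ IMFs + residual — holds to floating
point by construction.

VMD solves the constrained variational problem with the standard ADMM scheme:
spectral Wiener-like mode updates, power-weighted center-frequency updates,
and dual ascent with step τ, on a mirror-extended copy of the signal. Modes
are returned sorted by descending converged center frequency, so index 0 is
the highest-frequency mode for both methods.

``vmdr_denoise`` implements the smoothing stage: decompose with VMD, discard
the single highest-center-frequency mode (which carries the residual
high-frequency noise) together with the reconstruction remainder, and sum
what is left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .core_io import TimedSignal
from .errors import ContractError

__all__ = [
    "EmdParams",
    "VmdParams",
    "ImfDecomposition",
    "emd_decompose",
    "vmd_decompose",
    "vmdr_denoise",
]


@dataclass
class EmdParams:
    sift_sd: float = 0.2
    max_imfs: int = 12
    max_sifts: int = 50


@dataclass
class VmdParams:
    alpha: float = 2000.0
    tau: float = 0.0
    tol: float = 1e-7
    max_iter: int = 500


@dataclass
class ImfDecomposition:
    """Ordered modes (index 0 = highest frequency) plus residual.

    For EMD the residual is the final low-frequency remainder r(n); for VMD
    it is the reconstruction remainder input − Σ modes. ``center_frequencies``
    holds the converged ω_k for VMD and a diagnostic spectral centroid for
    EMD, both in Hz.
    """

    imfs: list[np.ndarray]
    residual: np.ndarray
    method: str
    fs: float
    center_frequencies: list[float] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        total = self.residual.copy()
        for imf in self.imfs:
            total += imf
        return total


# ---------------------------------------------------------------- EMD ------


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    rising = d > 0
    falling = d < 0
    maxima = np.flatnonzero(rising[:-1] & falling[1:]) + 1
    minima = np.flatnonzero(falling[:-1] & rising[1:]) + 1
    return maxima, minima


def _mirror_knots(idx: np.ndarray, val: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to two extrema across each end to anchor the spline."""
    k = min(2, idx.size)
    left_i = -idx[:k][::-1]
    left_v = val[:k][::-1]
    right_i = 2 * (n - 1) - idx[-k:][::-1]
    right_v = val[-k:][::-1]
    ti = np.concatenate([left_i, idx, right_i]).astype(np.float64)
    tv = np.concatenate([left_v, val, right_v])
    keep = np.concatenate([[True], np.diff(ti) > 0])
    return ti[keep], tv[keep]


def _envelope_mean(x: np.ndarray) -> np.ndarray | None:
    maxima, minima = _local_extrema(x)
    if maxima.size < 1 or minima.size < 1 or maxima.size + minima.size < 2:
        return None
    n = x.size
    ti, tv = _mirror_knots(maxima, x[maxima], n)
    upper = CubicSpline(ti, tv)(np.arange(n))
    ti, tv = _mirror_knots(minima, x[minima], n)
    lower = CubicSpline(ti, tv)(np.arange(n))
    return 0.5 * (upper + lower)


def _spectral_centroid(x: np.ndarray, fs: float) -> float:
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    total = spec.sum()
    if total <= 0:
        return 0.0
    return float((freqs * spec).sum() / total)


def emd_decompose(x: TimedSignal, params: EmdParams | None = None) -> ImfDecomposition:
    """Classic EMD by sifting. Monotone input yields 0 IMFs, residual == input."""
    p = params or EmdParams()
    if len(x) < 8:
        raise ContractError("EMD requires at least 8 samples")
    residual = x.samples.astype(np.float64).copy()
    scale = np.ptp(residual)
    imfs: list[np.ndarray] = []
    for _ in range(p.max_imfs):
        # numerical-residue guard: a remainder this small is not a mode
        if np.ptp(residual) <= 1e-7 * scale:
            break
        maxima, minima = _local_extrema(residual)
        if maxima.size + minima.size < 2:
            break
        h = residual.copy()
        for _sift in range(p.max_sifts):
            mean = _envelope_mean(h)
            if mean is None:
                break
            h_new = h - mean
            denom = float(np.sum(h * h))
            sd = float(np.sum(mean * mean)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < p.sift_sd:
                break
        imfs.append(h)
        residual = residual - h
    centroids = [_spectral_centroid(imf, x.fs) for imf in imfs]
    return ImfDecomposition(imfs, residual, "EMD", x.fs, centroids)


# ---------------------------------------------------------------- VMD ------


def vmd_decompose(
    x: TimedSignal,
    K: int,
    params: VmdParams | None = None,
) -> ImfDecomposition:
    """Variational mode decomposition into K band-limited modes (ADMM)."""
    p = params or VmdParams()
    n = len(x)
    if K < 1:
        raise ContractError("K must be >= 1")
    if K > n // 2:
        raise ContractError(f"K={K} exceeds length/2 ({n // 2})")

    f = x.samples.astype(np.float64)
    # mirror-extend to 2N to soften boundary effects
    half = n // 2
    f_ext = np.concatenate([f[:half][::-1], f, f[n - (n - half):][::-1]])
    T = f_ext.size
    freqs = np.arange(T) / T - 0.5  # normalized frequency grid, fftshifted

    f_hat = np.fft.fftshift(np.fft.fft(f_ext))
    f_hat_plus = f_hat.copy()
    f_hat_plus[: T // 2] = 0  # analytic (positive-frequency) representation

    u_hat = np.zeros((K, T), dtype=complex)
    omega = 0.5 * np.arange(K) / K  # uniform initialization in [0, 0.5)
    lam_hat = np.zeros(T, dtype=complex)

    alpha = p.alpha
    for _ in range(p.max_iter):
        u_prev = u_hat.copy()
        sum_u = u_hat.sum(axis=0)
        for k in range(K):
            sum_u -= u_hat[k]
            u_hat[k] = (f_hat_plus - sum_u + lam_hat / 2.0) / (
                1.0 + 2.0 * alpha * (freqs - omega[k]) ** 2
            )
            power = np.abs(u_hat[k, T // 2 :]) ** 2
            total = power.sum()
            if total > 0:
                omega[k] = float((freqs[T // 2 :] * power).sum() / total)
            sum_u += u_hat[k]
        lam_hat = lam_hat + p.tau * (sum_u - f_hat_plus)
        num = np.sum(np.abs(u_hat - u_prev) ** 2, axis=1)
        den = np.sum(np.abs(u_prev) ** 2, axis=1)
        diff = float(np.sum(num / np.where(den > 0, den, 1.0)))
        if diff < p.tol:
            break

    # back to time domain, crop the mirror extension
    modes = np.zeros((K, n))
    for k in range(K):
        spec = np.fft.ifftshift(u_hat[k])
        mode_ext = np.real(np.fft.ifft(spec)) * 2.0
        modes[k] = mode_ext[half : half + n]

    order = np.argsort(-omega)  # descending center frequency
    modes = modes[order]
    omega_sorted = omega[order]
    imfs = [modes[k].copy() for k in range(K)]
    residual = f - modes.sum(axis=0)
    centers = [float(w * x.fs) for w in omega_sorted]
    return ImfDecomposition(imfs, residual, "VMD", x.fs, centers)


def vmdr_denoise(
    x: TimedSignal,
    K: int,
    params: VmdParams | None = None,
) -> TimedSignal:
    """Smooth ``x`` by VMD, dropping the highest-frequency mode and remainder."""
    if K < 2:
        raise ContractError("VMDR needs K >= 2 (nothing would remain for K=1)")
    dec = vmd_decompose(x, K, params)
    kept = np.sum(dec.imfs[1:], axis=0)
    return x.with_samples(kept)
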