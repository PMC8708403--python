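"""Per-segment normalization and rational-rate resampling.

The ECG is z-score normalized, x̂ = (x − μ)/σ with the population standard
deviation; accelerometer channels are min–max normalized into [0, 1]. The
accelerometer (recorded at a lower rate, e.g. 50 Hz) is brought to the ECG
rate by polyphase rational resampling: upsample by L with zero insertion,
FIR anti-aliasing low-pass designed with a Kaiser window (cutoff π/max(L, M),
passband gain L), decimate by M, with the filter group delay compensated so
the output stays phase-aligned with the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .core_io import TimedSignal
from .errors import ContractError, DegenerateSignalError

__all__ = [
    "NormalizationParams",
    "ResampleSpec",
    "zscore",
    "minmax",
    "denormalize",
    "resample_rational",
]


@dataclass
class NormalizationParams:
    """Statistics needed to undo a normalization."""

    method: str  # "zscore" or "minmax"
    mean: float = 0.0
    std: float = 1.0
    min: float = 0.0
    max: float = 1.0


def zscore(x: TimedSignal) -> tuple[TimedSignal, NormalizationParams]:
    """Standardize to zero mean, unit population standard deviation."""
    mu = float(np.mean(x.samples))
    sigma = float(np.std(x.samples))  # population (ddof=0)
    if sigma == 0.0:
        raise DegenerateSignalError("constant signal: z-score undefined (sigma = 0)")
    out = x.with_samples((x.samples - mu) / sigma)
    return out, NormalizationParams("zscore", mean=mu, std=sigma)


def minmax(x: TimedSignal) -> tuple[TimedSignal, NormalizationParams]:
    """Map linearly onto [0, 1]; the minimum maps to 0 and the maximum to 1."""
    lo = float(np.min(x.samples))
    hi = float(np.max(x.samples))
    if hi == lo:
        raise DegenerateSignalError("constant signal: min-max normalization undefined")
    out = x.with_samples((x.samples - lo) / (hi - lo))
    return out, NormalizationParams("minmax", min=lo, max=hi)


def denormalize(x: TimedSignal, params: NormalizationParams) -> TimedSignal:
    """Invert :func:`zscore` or :func:`minmax` given the recorded parameters."""
    if params.method == "zscore":
        return x.with_samples(x.samples * params.std + params.mean)
    if params.method == "minmax":
        return x.with_samples(x.samples * (params.max - params.min) + params.min)
    raise ContractError(f"unknown normalization method {params.method!r}")


@dataclass
class ResampleSpec:
    """Anti-aliasing filter design knobs for rational resampling.

    ``taps_per_phase`` sets the FIR half-length per polyphase branch; the full
    filter has 2·taps_per_phase·max(L, M) + 1 taps.
    """

    kaiser_beta: float = 5.0
    taps_per_phase: int = 10


_MAX_FACTOR = 10_000


def _ratio(target_fs: float, fs: float) -> tuple[int, int]:
    frac = Fraction(target_fs / fs).limit_denominator(_MAX_FACTOR)
    if frac.numerator < 1 or frac.numerator > _MAX_FACTOR or frac.denominator > _MAX_FACTOR:
        raise ContractError(
            f"resampling ratio {target_fs}/{fs} is not a small rational"
        )
    if abs(float(frac) - target_fs / fs) > 1e-9:
        raise ContractError(
            f"resampling ratio {target_fs}/{fs} is not rational within tolerance"
        )
    return frac.numerator, frac.denominator


def resample_rational(
    x: TimedSignal,
    target_fs: float,
    spec: ResampleSpec | None = None,
) -> TimedSignal:
    """Resample ``x`` to ``target_fs`` where target_fs/fs = L/M in lowest terms.

    Polyphase implementation of zero-insertion upsampling by L, Kaiser-window
    FIR low-pass at π/max(L, M) with passband gain L, and decimation by M.
    Output length is ceil(len(x)·L/M) and the filter delay is removed so the
    output is sample-aligned with the input timeline.
    """
    spec = spec or ResampleSpec()
    L, M = _ratio(target_fs, x.fs)
    if L == M:
        return TimedSignal(x.samples.copy(), target_fs, x.label)
    n_half = spec.taps_per_phase * max(L, M)
    taps = sps.firwin(2 * n_half + 1, 1.0 / max(L, M), window=("kaiser", spec.kaiser_beta))
    out = sps.resample_poly(x.samples, L, M, window=taps)
    return TimedSignal(out, target_fs, x.label)
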