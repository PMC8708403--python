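"""LMS adaptive noise cancellation with the motion-sensitive reference.

The measured segment m(n) is modelled as desired signal plus additive noise
that is correlated with the reference X(n). A length-M tapped delay line of
the reference drives a linear filter whose output y(k) = X(k)ᵀW(k) is
subtracted from the measurement; the error e(k) = m(k) − y(k) is both the
cleaned output and the adaptation signal:

    W(k+1) = W(k) + 2 μ X(k) e(k)

Defaults μ = 0.01 and M = 10. Weights start at zero and are reset for every
segment, the delay line is zero-padded at the segment start, and adaptation
aborts loudly if any weight exceeds 10⁶ in magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .core_io import TimedSignal
from .errors import ContractError, DivergenceError
from .motion_reference import ReferenceNoise

__all__ = ["LmsConfig", "LmsResult", "lms_run"]

_WEIGHT_LIMIT = 1e6


@dataclass
class LmsConfig:
    mu: float = 0.01
    order: int = 10
    init_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.mu >= 0):
            raise ContractError("mu must be >= 0")
        if self.order < 1:
            raise ContractError("order must be a positive integer")
        if self.init_weights is not None:
            self.init_weights = np.asarray(self.init_weights, dtype=np.float64)
            if self.init_weights.shape != (self.order,):
                raise ContractError("init_weights must have length == order")


@dataclass
class LmsResult:
    cleaned: TimedSignal  # e(k) = m(k) − y(k)
    noise_estimate: TimedSignal  # y(k)
    weights_final: np.ndarray
    error_power_trace: np.ndarray  # e(k)²


def lms_run(
    measured: TimedSignal,
    reference: Union[ReferenceNoise, TimedSignal],
    cfg: LmsConfig | None = None,
) -> LmsResult:
    """Run the LMS noise canceller over one segment."""
    cfg = cfg or LmsConfig()
    ref_sig = reference.x_ref if isinstance(reference, ReferenceNoise) else reference
    if len(ref_sig) != len(measured):
        raise ContractError("measured and reference must have equal length")
    m = measured.samples
    n = m.size
    M = cfg.order
    xp = np.concatenate([np.zeros(M - 1), ref_sig.samples])  # zero-padded delay line
    w = (
        cfg.init_weights.copy()
        if cfg.init_weights is not None
        else np.zeros(M, dtype=np.float64)
    )
    y = np.empty(n)
    e = np.empty(n)
    two_mu = 2.0 * cfg.mu
    for k in range(n):
        xv = xp[k : k + M][::-1]  # [x(k), x(k−1), …, x(k−M+1)]
        y[k] = float(xv @ w)
        e[k] = m[k] - y[k]
        w = w + two_mu * e[k] * xv
        if not np.all(np.isfinite(w)) or np.max(np.abs(w)) > _WEIGHT_LIMIT:
            raise DivergenceError(
                f"LMS weights diverged at sample {k} (|w| > {_WEIGHT_LIMIT:g})",
                sample=k,
            )
    return LmsResult(
        cleaned=measured.with_samples(e, label="lms_cleaned"),
        noise_estimate=measured.with_samples(y, label="lms_noise"),
        weights_final=w,
        error_power_trace=e * e,
    )
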