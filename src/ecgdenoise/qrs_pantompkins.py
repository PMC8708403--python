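"""Pan–Tompkins style QRS detection.

Pipeline: band-pass 5–15 Hz (2nd-order Butterworth, forward-backward) →
5-point derivative → pointwise squaring → 150 ms moving-window integration →
dual adaptive thresholds with running signal/noise peak estimates, a 200 ms
refractory period and T-wave discrimination by slope inside 360 ms. Each
accepted event is refined to the largest band-passed deflection within
±75 ms. All thresholds are relative, so detection is invariant to positive
amplitude scaling of the input.

The same detector serves two roles: finding beats on raw segments and
counting QRS evidence on individual intrinsic mode functions, whose
morphology differs from raw ECG — hence the deliberately generic,
scale-free formulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core_io import TimedSignal
from .errors import ContractError

__all__ = ["QrsParams", "QrsAnnotation", "detect_qrs"]


@dataclass
class QrsParams:
    band_low_hz: float = 5.0
    band_high_hz: float = 15.0
    integration_ms: float = 150.0
    refractory_ms: float = 200.0
    twave_ms: float = 360.0
    refine_ms: float = 75.0
    searchback: bool = False  # kept off: 10-s segments, no search-back pass


@dataclass
class QrsAnnotation:
    """Strictly increasing 0-based sample indices of detected R events."""

    peaks: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=np.int64)
        if self.peaks.size > 1 and np.any(np.diff(self.peaks) <= 0):
            raise ContractError("peaks must be strictly increasing")

    def __len__(self) -> int:
        return self.peaks.size

    def times(self) -> np.ndarray:
        return self.peaks / self.fs


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(2, [lo, hi], btype="band", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def detect_qrs(x: TimedSignal, params: QrsParams | None = None) -> QrsAnnotation:
    """Detect R events on ``x``; returns an empty annotation on silent input."""
    p = params or QrsParams()
    fs = x.fs
    if fs < 100:
        raise ContractError(f"detector requires fs >= 100 Hz, got {fs}")
    if len(x) < int(2 * fs):
        raise ContractError("detector requires at least 2 s of samples")

    band = _bandpass(x.samples, fs, p.band_low_hz, p.band_high_hz)
    deriv = np.convolve(band, np.array([1.0, 2.0, 0.0, -2.0, -1.0]) / 8.0, mode="same")
    squared = deriv * deriv
    win = max(1, int(round(p.integration_ms / 1000.0 * fs)))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = max(1, int(round(p.refractory_ms / 1000.0 * fs)))
    # relative silence floor: numerical ripple in flat stretches is not a
    # candidate; scales with the signal so detection stays scale-invariant
    floor = 1e-10 * float(np.max(mwi))
    candidates, _ = sps.find_peaks(mwi, distance=refractory, height=floor)
    if candidates.size == 0:
        return QrsAnnotation(np.empty(0, dtype=np.int64), fs)

    init = mwi[: int(2 * fs)]
    if np.max(init) <= 0.0:
        return QrsAnnotation(np.empty(0, dtype=np.int64), fs)
    spki = 0.25 * float(np.max(init))  # running signal-peak estimate
    npki = 0.5 * float(np.mean(init))  # running noise-peak estimate

    refine = max(1, int(round(p.refine_ms / 1000.0 * fs)))
    twave_win = int(round(p.twave_ms / 1000.0 * fs))
    accepted: list[int] = []
    last_slope = 0.0

    def _slope(i: int) -> float:
        lo = max(0, i - refine)
        hi = min(len(deriv), i + refine + 1)
        return float(np.max(np.abs(deriv[lo:hi])))

    for c in candidates:
        peak = float(mwi[c])
        threshold = npki + 0.25 * (spki - npki)
        is_signal = peak > threshold
        if is_signal and accepted and (c - accepted[-1]) < twave_win:
            # candidate close to the previous beat: T wave if its maximal
            # slope is less than half the preceding QRS slope
            s = _slope(c)
            if s < 0.5 * last_slope:
                is_signal = False
        if is_signal:
            accepted.append(int(c))
            last_slope = _slope(c)
            spki = 0.125 * peak + 0.875 * spki
        else:
            npki = 0.125 * peak + 0.875 * npki

    # refine to the largest band-passed deflection within ±refine samples
    refined: list[int] = []
    for c in accepted:
        lo = max(0, c - refine)
        hi = min(len(band), c + refine + 1)
        idx = lo + int(np.argmax(np.abs(band[lo:hi])))
        if refined and idx - refined[-1] < refractory:
            continue  # refinement collision: keep the earlier event
        refined.append(idx)
    return QrsAnnotation(np.asarray(refined, dtype=np.int64), fs)
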