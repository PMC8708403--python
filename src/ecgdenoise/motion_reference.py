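"""Motion-sensitive reference-noise construction for the adaptive filter.

Candidates are the three accelerometer channels Ax, Ay, Az and the combined
magnitude Axyz = sqrt(Ax² + Ay² + Az²), each min–max normalized. The one
whose Pearson correlation with the AEMDR noise estimate s(n) is farthest
from zero (largest |ρ|) is selected, and the final reference is
X(n) = s(n) + activity(n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import AccelTriplet, TimedSignal
from .errors import ContractError, DegenerateSignalError
from .preprocess import minmax

__all__ = [
    "ActivityCandidate",
    "ReferenceNoise",
    "combine_axes",
    "pearson",
    "select_activity",
    "build_reference",
]

log = logging.getLogger(__name__)


@dataclass
class ActivityCandidate:
    name: str  # one of "x", "y", "z", "xyz"
    signal: TimedSignal
    rho: float


@dataclass
class ReferenceNoise:
    x_ref: TimedSignal
    chosen: str


def combine_axes(accel: AccelTriplet) -> TimedSignal:
    """Euclidean magnitude of the three channels, sample by sample."""
    mag = np.sqrt(
        accel.ax.samples**2 + accel.ay.samples**2 + accel.az.samples**2
    )
    return TimedSignal(mag, accel.fs, label="axyz")


def pearson(a: TimedSignal, b: TimedSignal) -> float:
    """Sample correlation coefficient ((N−1)-normalized)."""
    if len(a) != len(b):
        raise ContractError("pearson requires equal lengths")
    if len(a) < 2:
        raise ContractError("pearson requires at least 2 samples")
    sa = float(np.std(a.samples, ddof=1))
    sb = float(np.std(b.samples, ddof=1))
    if sa == 0.0 or sb == 0.0:
        raise DegenerateSignalError("constant signal: correlation undefined")
    za = (a.samples - np.mean(a.samples)) / sa
    zb = (b.samples - np.mean(b.samples)) / sb
    rho = float(np.sum(za * zb) / (len(a) - 1))
    return max(-1.0, min(1.0, rho))


def select_activity(target: TimedSignal, accel: AccelTriplet) -> ActivityCandidate:
    """Pick the activity candidate with the largest |ρ| against ``target``.

    ``target`` is the signal the reference noise should resemble. The
    pipeline passes the original (normalized) ECG segment: in-band motion
    artifacts ride on the measured signal but are largely routed to the
    *clean* side by the IMF selection, so the AEMDR noise estimate alone is
    blind to them and cannot identify the coupled axis.

    Ties break in the order x, y, z, xyz. Constant candidates are skipped;
    if all four are constant a degenerate-signal error is raised.
    """
    noise = target
    if len(accel) != len(noise):
        raise ContractError("accelerometer must be aligned with the correlation target")
    raw = {
        "x": accel.ax,
        "y": accel.ay,
        "z": accel.az,
        "xyz": combine_axes(accel),
    }
    best: ActivityCandidate | None = None
    rhos = {}
    for name in ("x", "y", "z", "xyz"):
        try:
            normed, _ = minmax(raw[name])
            rho = pearson(normed, noise)
        except DegenerateSignalError:
            continue
        rhos[name] = rho
        if best is None or abs(rho) > abs(best.rho):
            best = ActivityCandidate(name, normed, rho)
    if best is None:
        raise DegenerateSignalError("all activity candidates are constant")
    log.info("activity selection: %s -> chose %s", rhos, best.name)
    return best


def build_reference(noise: TimedSignal, chosen: ActivityCandidate) -> ReferenceNoise:
    """X(n) = s(n) + activity(n), elementwise."""
    if len(noise) != len(chosen.signal):
        raise ContractError("noise and activity must have equal length")
    return ReferenceNoise(
        x_ref=noise.with_samples(noise.samples + chosen.signal.samples, label="x_ref"),
        chosen=chosen.name,
    )
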