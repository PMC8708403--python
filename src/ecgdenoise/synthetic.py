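"""Seedable generator of ground-truthed ambulatory ECG + accelerometer data.

The generator emulates a wearable recording session: a beat-periodic ECG
(each beat a fixed sum of five Gaussian bumps for P, Q, R, S, T; R amplitude
1.0) at 250 Hz; additive low-frequency baseline wander (a mixture of
sinusoids below 0.5 Hz); Poisson-timed motion-artifact bursts of band-passed
noise inside the ECG band with 0.5–2 s envelopes; a 50 Hz 3-axis
accelerometer whose channels carry a gravity offset, slow postural sway,
a coupled copy of the artifact process (envelope plus in-band waveform,
scaled by a per-axis coupling coefficient — an accelerometer on a moving
electrode sees both the posture change and the vibration), and independent
sensor noise; and occasional contact-loss windows in which the ECG is
replaced by a mostly-flat floor with a few high-amplitude broadband
transients, labeled unusable.

Everything is deterministic given ``seed``; ground-truth components, true R
locations and usability labels are returned alongside the noisy recording,
which is what makes every downstream stage testable without real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core_io import AccelTriplet, TimedSignal
from .errors import ContractError
from .qrs_pantompkins import QrsAnnotation

__all__ = [
    "SynthSpec",
    "GroundTruthBundle",
    "gen_ecg",
    "gen_bundle",
    "gen_quality_corpus",
]

# beat morphology: (time offset from R in s, amplitude, Gaussian sigma in s);
# P peak 140 ms before R (PR interval ~160 ms onset-to-onset), T peak 250 ms after
_WAVES = (
    ("P", -0.140, 0.15, 0.030),
    ("Q", -0.035, -0.12, 0.012),
    ("R", 0.000, 1.00, 0.016),
    ("S", 0.035, -0.20, 0.014),
    ("T", 0.250, 0.30, 0.060),
)

_FIRST_BEAT_S = 0.4  # first R placed here; 12 beats fit 10 s at mean RR 0.824 s


@dataclass
class SynthSpec:
    """Study conditions for one synthetic recording."""

    fs_ecg: float = 250.0
    fs_accel: float = 50.0
    duration_s: float = 60.0
    hr_bpm: float = 72.8  # mean RR ≈ 0.824 s
    hr_sd: float = 0.02  # beat-to-beat RR jitter, seconds
    # noise mix sized so total noise power ~= clean ECG power (SNR ~ 0 dB)
    wander: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.08, 0.26), (0.21, 0.17), (0.37, 0.10)]
    )
    artifact_rate: float = 10.0  # bursts per minute
    artifact_band: tuple[float, float] = (1.0, 10.0)
    artifact_amp: float = 0.8  # burst peaks comparable to the R amplitude
    coupling: tuple[float, float, float] = (0.8, 0.1, 0.1)
    sway_amp: float = 0.15  # postural sway amplitude on each accel axis
    contact_loss_prob: float = 0.0
    window_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs_ecg <= 0 or self.fs_accel <= 0:
            raise ContractError("rates and duration must be positive")
        if any(f >= 0.5 for f, _ in self.wander):
            raise ContractError("wander frequencies must stay below 0.5 Hz")
        if min(self.artifact_rate, self.artifact_amp) < 0:
            raise ContractError("rates and amplitudes must be >= 0")


@dataclass
class GroundTruthBundle:
    clean: TimedSignal
    noisy: TimedSignal
    wander_component: TimedSignal
    artifact_component: TimedSignal
    accel: AccelTriplet
    r_peaks_true: QrsAnnotation
    usable_labels: list[bool]
    spec: SynthSpec


def gen_ecg(spec: SynthSpec) -> tuple[TimedSignal, QrsAnnotation]:
    """Beat train with jittered RR intervals; exact R locations returned."""
    rng = np.random.default_rng(spec.seed)
    rr_mean = 60.0 / spec.hr_bpm
    beat_times = []
    t = _FIRST_BEAT_S
    while t < spec.duration_s:
        beat_times.append(t)
        rr = rr_mean + (rng.normal(0.0, spec.hr_sd) if spec.hr_sd > 0 else 0.0)
        t += max(0.3, rr)
    n = int(round(spec.duration_s * spec.fs_ecg))
    tt = np.arange(n) / spec.fs_ecg
    ecg = np.zeros(n)
    for bt in beat_times:
        for _, off, amp, sigma in _WAVES:
            center = bt + off
            lo = max(0, int((center - 5 * sigma) * spec.fs_ecg))
            hi = min(n, int((center + 5 * sigma) * spec.fs_ecg) + 1)
            if hi > lo:
                ecg[lo:hi] += amp * np.exp(-((tt[lo:hi] - center) ** 2) / (2 * sigma**2))
    peaks = np.round(np.asarray(beat_times) * spec.fs_ecg).astype(np.int64)
    peaks = peaks[peaks < n]
    return TimedSignal(ecg, spec.fs_ecg, label="ecg_clean"), QrsAnnotation(peaks, spec.fs_ecg)


def _artifact_process(
    spec: SynthSpec, rng: np.random.Generator, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Return (unit-amplitude artifact waveform, burst envelope) at fs_ecg."""
    envelope = np.zeros(n)
    n_bursts = rng.poisson(spec.artifact_rate * spec.duration_s / 60.0)
    for _ in range(n_bursts):
        dur = rng.uniform(0.5, 2.0)
        start = rng.uniform(0.0, max(1e-6, spec.duration_s - dur))
        i0 = int(start * spec.fs_ecg)
        i1 = min(n, i0 + max(2, int(dur * spec.fs_ecg)))
        envelope[i0:i1] = np.maximum(envelope[i0:i1], np.hanning(i1 - i0))
    white = rng.standard_normal(n)
    lo, hi = spec.artifact_band
    sos = sps.butter(4, [lo, min(hi, 0.45 * spec.fs_ecg)], btype="band",
                     fs=spec.fs_ecg, output="sos")
    carrier = sps.sosfiltfilt(sos, white)
    std = carrier.std()
    if std > 0:
        carrier = carrier / std
    return envelope * carrier, envelope


def _contact_loss_pattern(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Detached-electrode pattern: a flat rail with a few broadband pops.

    When contact is lost the front-end reads an essentially constant rail;
    brief wideband transients appear when the loose lead taps the skin.
    """
    out = np.zeros(n)
    for _ in range(rng.integers(1, 4)):
        dur = int(rng.uniform(0.2, 0.5) * fs)
        i0 = rng.integers(0, max(1, n - dur))
        out[i0 : i0 + dur] += 1.5 * rng.standard_normal(dur) * np.hanning(dur)
    return out


def gen_bundle(spec: SynthSpec) -> GroundTruthBundle:
    """Full ground-truthed recording: ECG + noise components + accelerometer."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    clean, r_true = gen_ecg(spec)
    n = len(clean)
    tt = np.arange(n) / spec.fs_ecg

    wander = np.zeros(n)
    for freq, amp in spec.wander:
        wander += amp * np.sin(2 * np.pi * freq * tt + rng.uniform(0, 2 * np.pi))

    artifact_wave, envelope = _artifact_process(spec, rng, n)
    artifact = spec.artifact_amp * artifact_wave
    noisy = clean.samples + wander + artifact

    # accelerometer at its native (lower) rate
    na = int(round(spec.duration_s * spec.fs_accel))
    ta = np.arange(na) / spec.fs_accel
    env_a = np.interp(ta, tt, envelope)
    wave_a = np.interp(ta, tt, artifact_wave)
    offsets = (0.05, 0.05, 1.0)  # gravity mostly on z
    channels = []
    for axis, (coup, offset) in enumerate(zip(spec.coupling, offsets)):
        # postural sway during activity; independent frequency/phase per axis
        sway = spec.sway_amp * np.sin(2 * np.pi * rng.uniform(0.15, 0.35) * ta + rng.uniform(0, 2 * np.pi))
        sensor_noise = 0.02 * rng.standard_normal(na)
        channels.append(
            TimedSignal(
                offset + sway + coup * (env_a + wave_a) + sensor_noise,
                spec.fs_accel,
                label=("ax", "ay", "az")[axis],
            )
        )
    accel = AccelTriplet(*channels)

    # contact-loss windows replace the noisy ECG and flip the label
    win = int(round(spec.window_s * spec.fs_ecg))
    n_windows = n // win
    labels = [True] * n_windows
    for i in range(n_windows):
        if rng.random() < spec.contact_loss_prob:
            labels[i] = False
            noisy[i * win : (i + 1) * win] = _contact_loss_pattern(rng, win, spec.fs_ecg)

    return GroundTruthBundle(
        clean=clean,
        noisy=TimedSignal(noisy, spec.fs_ecg, label="ecg_noisy"),
        wander_component=TimedSignal(wander, spec.fs_ecg, label="wander"),
        artifact_component=TimedSignal(artifact, spec.fs_ecg, label="artifact"),
        accel=accel,
        r_peaks_true=r_true,
        usable_labels=labels,
        spec=spec,
    )


def gen_quality_corpus(
    n_usable: int,
    n_unusable: int,
    seed: int = 0,
    window_s: float = 10.0,
) -> tuple[list[TimedSignal], list[bool]]:
    """Labeled 10-s segments for training/testing the signal-quality gate.

    Usable segments come from default-condition recordings (wander + bursts);
    unusable ones are contact-loss windows. Segments are returned raw
    (unnormalized); labels are generator ground truth.
    """
    segments: list[TimedSignal] = []
    labels: list[bool] = []
    rec = 0
    while sum(labels) < n_usable or (len(labels) - sum(labels)) < n_unusable:
        want_unusable = (len(labels) - sum(labels)) < n_unusable
        spec = SynthSpec(
            duration_s=6 * window_s,
            window_s=window_s,
            contact_loss_prob=1.0 if want_unusable else 0.0,
            seed=seed * 100_003 + rec,
        )
        rec += 1
        bundle = gen_bundle(spec)
        win = int(round(window_s * spec.fs_ecg))
        for i, usable in enumerate(bundle.usable_labels):
            if usable and sum(labels) >= n_usable:
                continue
            if not usable and (len(labels) - sum(labels)) >= n_unusable:
                continue
            seg = TimedSignal(
                bundle.noisy.samples[i * win : (i + 1) * win], spec.fs_ecg
            )
            segments.append(seg)
            labels.append(usable)
    return segments, labels
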