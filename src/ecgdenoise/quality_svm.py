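"""Signal-quality gate: spectral features, Gaussian-kernel SVM, metrics.

A 10-s segment is summarized by eight 90%-power frequencies: f0 of the
segment itself, f1–f3 of its first three EMD IMFs, and rf0–rf3 of the
AEMDR-reconstructed clean signal and its first three IMFs. Usable segments
concentrate power in the cardiac band while contact-loss segments push f0
far above it, which makes the classes nearly separable.

Training uses a soft-margin SVM with the parameter-free Gaussian kernel
G(x_j, x_k) = exp(−‖x_j − x_k‖²) on standardized features (the kernel has
no bandwidth knob, so feature scale is controlled by standardization, whose
statistics are stored in the model). Prediction is recomputed directly from
the stored support vectors, dual coefficients and bias, so a serialized
model is self-contained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import periodogram
from sklearn.svm import SVC

from .aemdr import AemdrParams, aemdr_filter
from .core_io import TimedSignal
from .decomposition import EmdParams, emd_decompose
from .errors import ContractError, DegenerateSignalError, EcgDenoiseError, TrainingError
from .qrs_pantompkins import QrsParams, detect_qrs

__all__ = [
    "QualityFeatures",
    "ConfusionCounts",
    "SvmModel",
    "power_frequency_90",
    "extract_features",
    "label_segment_by_qrs",
    "svm_train",
    "svm_predict",
    "confusion_metrics",
]


@dataclass
class QualityFeatures:
    f0: float
    f1: float
    f2: float
    f3: float
    rf0: float
    rf1: float
    rf2: float
    rf3: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.f0, self.f1, self.f2, self.f3, self.rf0, self.rf1, self.rf2, self.rf3]
        )


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ContractError("counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ContractError("at least one count required")


def power_frequency_90(x: TimedSignal, fraction: float = 0.90) -> float:
    """Smallest frequency below which the cumulative periodogram power
    reaches ``fraction`` of the total (rectangular window, one-sided)."""
    if len(x) < 16:
        raise ContractError("need at least 16 samples")
    freqs, power = periodogram(x.samples, fs=x.fs, window="boxcar")
    total = float(power.sum())
    if total <= 0.0:
        raise DegenerateSignalError("zero-power signal: 90%-power frequency undefined")
    idx = int(np.searchsorted(np.cumsum(power), fraction * total))
    idx = min(idx, freqs.size - 1)
    return float(freqs[idx])


def _imf_features(imfs: list[np.ndarray], fs: float, fallback: float) -> list[float]:
    """90%-power frequencies of IMFs 1–3, repeating the last available value."""
    values: list[float] = []
    for imf in imfs[:3]:
        try:
            values.append(power_frequency_90(TimedSignal(imf, fs)))
        except (DegenerateSignalError, ContractError):
            values.append(values[-1] if values else fallback)
    while len(values) < 3:
        values.append(values[-1] if values else fallback)
    return values


def extract_features(
    segment: TimedSignal,
    params: AemdrParams | None = None,
) -> QualityFeatures:
    """The 8-vector (f0..f3, rf0..rf3) for one normalized segment."""
    p = params or AemdrParams()
    f0 = power_frequency_90(segment)
    dec = emd_decompose(segment, p.emd)
    f1, f2, f3 = _imf_features(dec.imfs, segment.fs, f0)
    try:
        pair, _, _ = aemdr_filter(segment, p, decomposition=dec)
        clean = pair.clean
        rf0 = power_frequency_90(clean)
        rdec = emd_decompose(clean, p.emd)
        rf1, rf2, rf3 = _imf_features(rdec.imfs, segment.fs, rf0)
    except EcgDenoiseError:
        # reconstruction degenerate (e.g. no beats at all, or all IMFs noisy
        # leaving a zero clean signal): mirror the raw features so the
        # 8-vector stays total and the segment stays scoreable
        rf0, rf1, rf2, rf3 = f0, f1, f2, f3
    return QualityFeatures(f0, f1, f2, f3, rf0, rf1, rf2, rf3)


def label_segment_by_qrs(
    segment: TimedSignal,
    expected_hr_bpm: float,
    qrs_params: QrsParams | None = None,
) -> bool:
    """Usable iff the detected beat count reaches 60% of the expected count."""
    if expected_hr_bpm <= 0:
        raise ContractError("expected_hr_bpm must be positive")
    expected = segment.duration_s * expected_hr_bpm / 60.0
    try:
        count = len(detect_qrs(segment, qrs_params))
    except ContractError:
        count = 0
    return count >= 0.60 * expected


@dataclass
class SvmModel:
    """A trained Gaussian-kernel SVM, self-contained for prediction."""

    support_vectors: np.ndarray  # rows in standardized feature space
    dual_coefficients: np.ndarray
    bias: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray

    def decision(self, features: QualityFeatures) -> float:
        vec = features.as_array()
        if vec.shape != (8,):
            raise ContractError("feature vector must have length 8")
        z = (vec - self.feature_mean) / self.feature_sd
        d2 = np.sum((self.support_vectors - z) ** 2, axis=1)
        return float(self.dual_coefficients @ np.exp(-d2) + self.bias)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coefficients": self.dual_coefficients.tolist(),
            "bias": self.bias,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SvmModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            support_vectors=np.asarray(doc["support_vectors"], dtype=np.float64),
            dual_coefficients=np.asarray(doc["dual_coefficients"], dtype=np.float64),
            bias=float(doc["bias"]),
            feature_mean=np.asarray(doc["feature_mean"], dtype=np.float64),
            feature_sd=np.asarray(doc["feature_sd"], dtype=np.float64),
        )


def svm_train(
    features: list[QualityFeatures],
    labels: list[bool],
    C: float = 1.0,
) -> SvmModel:
    """Train the gate. Positive class = usable. Deterministic given inputs."""
    if len(features) != len(labels):
        raise ContractError("features and labels must have equal length")
    if len(features) < 4:
        raise ContractError("need at least 4 training examples")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise TrainingError("both classes must be present in the training labels")
    X = np.vstack([f.as_array() for f in features])
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0.0] = 1.0
    Z = (X - mean) / sd
    clf = SVC(C=C, kernel="rbf", gamma=1.0)
    clf.fit(Z, y)
    return SvmModel(
        support_vectors=clf.support_vectors_.copy(),
        dual_coefficients=clf.dual_coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        feature_mean=mean,
        feature_sd=sd,
    )


def svm_predict(model: SvmModel, features: QualityFeatures) -> bool:
    """Usable iff the decision function is positive."""
    return model.decision(features) > 0.0


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) as percentages.

    SEN = TP/(TP+FN), SPC = TN/(FP+TN), ACC = (TP+TN)/total.
    """
    if c.tp + c.fn == 0 or c.fp + c.tn == 0:
        raise DegenerateSignalError("zero denominator in confusion metrics")
    sen = 100.0 * c.tp / (c.tp + c.fn)
    spc = 100.0 * c.tn / (c.fp + c.tn)
    acc = 100.0 * (c.tp + c.tn) / (c.tp + c.fp + c.tn + c.fn)
    return sen, spc, acc
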