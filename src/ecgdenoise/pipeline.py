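"""End-to-end orchestration of the five denoising stages.

Per 10-s segment: z-score the ECG and min–max the (already resampled)
accelerometer channels → quality gate (SVM model, QRS-count rule, or off)
→ AEMDR split into clean reconstruction and noise estimate → activity-axis
selection and reference-noise construction → LMS adaptive filtering of the
measured segment → VMD smoothing. Rejected or failed segments become
explicit NaN gaps in the assembled output (never zeros, which would mimic
asystole) and every segment — including rejected ones — gets a report row.
"""

from __future__ import annotations

import configparser
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .aemdr import AemdrParams, aemdr_filter
from .core_io import AccelTriplet, TimedSignal, segment_recording
from .decomposition import VmdParams, vmdr_denoise
from .errors import EcgDenoiseError
from .lms_filter import LmsConfig, lms_run
from .motion_reference import ReferenceNoise, build_reference, select_activity
from .preprocess import ResampleSpec, minmax, resample_rational, zscore
from .qrs_pantompkins import QrsParams
from .quality_svm import SvmModel, extract_features, label_segment_by_qrs, svm_predict

__all__ = ["PipelineConfig", "SegmentReport", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    window_s: float = 10.0
    gate: str = "qrs-rule"  # "svm" | "qrs-rule" | "off"
    svm_model_path: str | None = None
    expected_hr_bpm: float = 72.0
    enable_lms: bool = True
    enable_vmdr: bool = True
    vmd_K: int | str = "auto"  # "auto": number of EMD IMFs, floored at 3
    n_bins: int = 50
    resample: ResampleSpec = field(default_factory=ResampleSpec)
    qrs: QrsParams = field(default_factory=QrsParams)
    aemdr: AemdrParams = field(default_factory=AemdrParams)
    lms: LmsConfig = field(default_factory=LmsConfig)
    vmd: VmdParams = field(default_factory=VmdParams)

    @classmethod
    def from_ini(cls, path: str | Path) -> "PipelineConfig":
        """Load from a flat key=value INI file with per-module sections."""
        parser = configparser.ConfigParser()
        with open(path) as fh:
            parser.read_file(fh)
        cfg = cls()
        g = parser["pipeline"] if parser.has_section("pipeline") else {}
        cfg.window_s = float(g.get("window_s", cfg.window_s))
        cfg.gate = str(g.get("gate", cfg.gate))
        cfg.svm_model_path = g.get("svm_model_path", cfg.svm_model_path) or None
        cfg.expected_hr_bpm = float(g.get("expected_hr_bpm", cfg.expected_hr_bpm))
        cfg.enable_lms = str(g.get("enable_lms", cfg.enable_lms)).lower() in ("1", "true", "yes")
        cfg.enable_vmdr = str(g.get("enable_vmdr", cfg.enable_vmdr)).lower() in ("1", "true", "yes")
        if parser.has_section("preprocess"):
            s = parser["preprocess"]
            cfg.resample = ResampleSpec(
                kaiser_beta=float(s.get("kaiser_beta", cfg.resample.kaiser_beta)),
                taps_per_phase=int(s.get("taps_per_phase", cfg.resample.taps_per_phase)),
            )
        if parser.has_section("qrs"):
            s = parser["qrs"]
            cfg.qrs = QrsParams(
                band_low_hz=float(s.get("band_low_hz", cfg.qrs.band_low_hz)),
                band_high_hz=float(s.get("band_high_hz", cfg.qrs.band_high_hz)),
                integration_ms=float(s.get("integration_ms", cfg.qrs.integration_ms)),
                refractory_ms=float(s.get("refractory_ms", cfg.qrs.refractory_ms)),
                searchback=str(s.get("searchback", "false")).lower() in ("1", "true", "yes"),
            )
            cfg.aemdr.qrs = cfg.qrs
        if parser.has_section("aemdr"):
            s = parser["aemdr"]
            cfg.aemdr.match_ms = float(s.get("match_ms", cfg.aemdr.match_ms))
            cfg.aemdr.max_recursion = int(s.get("max_recursion", cfg.aemdr.max_recursion))
        if parser.has_section("emd"):
            s = parser["emd"]
            cfg.aemdr.emd.sift_sd = float(s.get("sift_sd", cfg.aemdr.emd.sift_sd))
            cfg.aemdr.emd.max_imfs = int(s.get("max_imfs", cfg.aemdr.emd.max_imfs))
            cfg.aemdr.emd.max_sifts = int(s.get("max_sifts", cfg.aemdr.emd.max_sifts))
        if parser.has_section("lms"):
            s = parser["lms"]
            cfg.lms = LmsConfig(
                mu=float(s.get("mu", cfg.lms.mu)), order=int(s.get("order", cfg.lms.order))
            )
        if parser.has_section("vmd"):
            s = parser["vmd"]
            cfg.vmd = VmdParams(
                alpha=float(s.get("alpha", cfg.vmd.alpha)),
                tau=float(s.get("tau", cfg.vmd.tau)),
                tol=float(s.get("tol", cfg.vmd.tol)),
            )
            k = s.get("K", "auto")
            cfg.vmd_K = "auto" if str(k) == "auto" else int(k)
        if parser.has_section("eval"):
            cfg.n_bins = int(parser["eval"].get("n_bins", cfg.n_bins))
        return cfg


@dataclass
class SegmentReport:
    index: int
    gate_verdict: str  # "usable" | "rejected" | "error"
    chosen_activity_axis: str | None = None
    imf_total: int = 0
    imf_clean: int = 0
    imf_noisy: int = 0
    detail: str = ""


def _gate(segment: TimedSignal, cfg: PipelineConfig, model: SvmModel | None) -> bool:
    if cfg.gate == "off":
        return True
    if cfg.gate == "svm":
        if model is None:
            raise EcgDenoiseError("gate=svm but no model supplied")
        return svm_predict(model, extract_features(segment, cfg.aemdr))
    return label_segment_by_qrs(segment, cfg.expected_hr_bpm, cfg.qrs)


def run_pipeline(
    ecg: TimedSignal,
    accel: AccelTriplet | None,
    cfg: PipelineConfig | None = None,
) -> tuple[TimedSignal, list[SegmentReport]]:
    """Denoise a recording; returns the cleaned signal (NaN gaps at rejected
    segments) and one report per segment.

    When no accelerometer is supplied the adaptive-filter stage degrades to a
    reference of the AEMDR noise estimate alone (logged as a deviation).
    """
    cfg = cfg or PipelineConfig()
    model = SvmModel.from_json(cfg.svm_model_path) if (
        cfg.gate == "svm" and cfg.svm_model_path
    ) else None

    if accel is not None:
        if accel.fs != ecg.fs:
            accel = accel.map(lambda ch: resample_rational(ch, ecg.fs, cfg.resample))
        n = min(len(ecg), len(accel))
        ecg = TimedSignal(ecg.samples[:n], ecg.fs, ecg.label)
        accel = accel.map(lambda ch: TimedSignal(ch.samples[:n], ch.fs, ch.label))
    else:
        log.warning("no accelerometer: adaptive filter will use the noise estimate alone")
        zeros = TimedSignal(np.zeros(len(ecg)), ecg.fs)
        accel = AccelTriplet(zeros, zeros, zeros)

    pairs = segment_recording(ecg, accel, cfg.window_s)
    win = int(round(cfg.window_s * ecg.fs))
    out = np.full(win * len(pairs), np.nan)
    reports: list[SegmentReport] = []

    for pair in pairs:
        report = SegmentReport(index=pair.index, gate_verdict="error")
        try:
            seg, _ = zscore(pair.ecg)
            try:
                accel_n = pair.accel.map(lambda ch: minmax(ch)[0])
            except EcgDenoiseError:
                accel_n = pair.accel  # constant (absent) accel: keep as-is
            if not _gate(seg, cfg, model):
                report.gate_verdict = "rejected"
                reports.append(report)
                log.info("segment %d rejected by gate", pair.index)
                continue
            report.gate_verdict = "usable"

            clean_noise, selection, dec = aemdr_filter(seg, cfg.aemdr)
            report.imf_total = len(dec.imfs)
            report.imf_clean = len(selection.clean_indices)
            report.imf_noisy = len(selection.noisy_indices)

            if cfg.enable_lms:
                try:
                    cand = select_activity(seg, accel_n)
                    ref = build_reference(clean_noise.noise, cand)
                    report.chosen_activity_axis = cand.name
                except EcgDenoiseError:
                    ref = ReferenceNoise(clean_noise.noise, chosen="none")
                # scale the reference so the expected tap-vector energy is 1:
                # the LMS step size is fixed at the stated mu, and with a
                # unit-power reference 2*mu*|X|^2 would make the filter an
                # aggressive tracker that cancels the QRS itself
                ref_std = float(ref.x_ref.samples.std())
                scale = np.sqrt(cfg.lms.order) * (ref_std if ref_std > 0 else 1.0)
                ref_scaled = ReferenceNoise(
                    ref.x_ref.with_samples(ref.x_ref.samples / scale), ref.chosen
                )
                stage_out = lms_run(seg, ref_scaled, cfg.lms).cleaned
            else:
                stage_out = clean_noise.clean

            if cfg.enable_vmdr:
                k = max(10, len(dec.imfs)) if cfg.vmd_K == "auto" else int(cfg.vmd_K)
                stage_out = vmdr_denoise(stage_out, k, cfg.vmd)

            out[pair.index * win : (pair.index + 1) * win] = stage_out.samples
            reports.append(report)
        except EcgDenoiseError as exc:
            report.detail = str(exc)
            reports.append(report)
            log.warning("segment %d failed: %s", pair.index, exc)

    if not out.size:
        out = np.array([np.nan])
    cleaned = TimedSignal(out, ecg.fs, label="cleaned", allow_gaps=True)
    return cleaned, reports
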