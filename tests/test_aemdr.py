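import itertools

import numpy as np
import pytest

from ecgdenoise.aemdr import AemdrParams, _verdict, aemdr_filter, classify_imfs, match_qrs
from ecgdenoise.core_io import TimedSignal
from ecgdenoise.decomposition import emd_decompose
from ecgdenoise.errors import GateViolationError
from ecgdenoise.preprocess import zscore
from ecgdenoise.qrs_pantompkins import QrsAnnotation, detect_qrs
from ecgdenoise.synthetic import SynthSpec, gen_bundle, gen_ecg

from conftest import zs

FS = 250.0


def _ann(peaks):
    return QrsAnnotation(np.asarray(peaks, dtype=np.int64), FS)


def _brute_force_tp(ref, cand, tol):
    """Maximum one-to-one matching within tolerance, by exhaustive assignment."""
    best = 0
    ref = list(ref)
    cand = list(cand)
    k = min(len(ref), len(cand))
    for size in range(k, -1, -1):
        for csub in itertools.combinations(range(len(cand)), size):
            for rperm in itertools.permutations(range(len(ref)), size):
                if all(abs(cand[c] - ref[r]) <= tol for c, r in zip(csub, rperm)):
                    return size
    return best


class TestMatchQrs:
    def test_identity(self):
        a = _ann([100, 400, 800])
        assert match_qrs(a, a, 150.0) == (3, 0)

    def test_empty_candidate(self):
        assert match_qrs(_ann([100, 200]), _ann([]), 150.0) == (0, 0)

    def test_documented_example(self):
        tp, fp = match_qrs(_ann([250, 500]), _ann([252, 500, 900]), 150.0)
        assert (tp, fp) == (2, 1)

    def test_greedy_matches_brute_force(self):
        """Greedy nearest matching achieves the brute-force optimal TP count
        on small random annotation pairs."""
        rng = np.random.default_rng(0)
        tol = 0.150 * FS
        for _ in range(30):
            ref = np.unique(rng.integers(0, 2500, size=rng.integers(1, 5)))
            cand = np.unique(rng.integers(0, 2500, size=rng.integers(1, 5)))
            tp, fp = match_qrs(_ann(ref), _ann(cand), 150.0)
            assert tp == _brute_force_tp(ref, cand, tol)
            assert fp == len(cand) - tp


class TestClassificationRules:
    @pytest.mark.parametrize(
        "tp,fp,total,expected",
        [
            (7, 2, 12, "clean"),  # 7 > 6 and 2 < 6
            (5, 0, 12, "noisy"),  # rule 1 fails regardless of fp
            (7, 6, 12, "re-decompose"),  # fp ties at 50% -> not clean
            (6, 2, 12, "noisy"),  # tp ties at 50% -> noisy (strict >)
        ],
    )
    def test_verdict_rule(self, tp, fp, total, expected):
        assert _verdict(tp, fp, total) == expected

    def test_gate_violation_for_silent_segment(self):
        flat = TimedSignal(np.zeros(2500), FS)
        dec = emd_decompose(flat)
        with pytest.raises(GateViolationError):
            classify_imfs(flat, dec)

    def test_wander_imfs_noisy_qrs_imf_clean(self, clean_ecg_10s):
        """With a 0.2 Hz sinusoid at 2x the R amplitude added, the slow IMFs
        carrying the wander are rejected while a QRS-bearing IMF survives."""
        ecg, _ = clean_ecg_10s
        t = np.arange(len(ecg)) / FS
        noisy, _ = zscore(ecg.with_samples(ecg.samples + 2.0 * np.sin(2 * np.pi * 0.2 * t)))
        dec = emd_decompose(noisy)
        sel = classify_imfs(noisy, dec)
        wander_band = [
            i for i, c in enumerate(dec.center_frequencies)
            if c < 0.5 and dec.imfs[i].std() > 0.1
        ]
        assert wander_band and all(i in sel.noisy_indices for i in wander_band)
        assert sel.clean_indices  # at least one QRS-bearing IMF kept


class TestAemdrFilter:
    def test_clean_input_mostly_preserved(self, default_ecg_10s):
        ecg, _ = default_ecg_10s
        seg, _ = zscore(ecg)
        pair, sel, _ = aemdr_filter(seg)
        # the beat-locked T-wave mode is discarded by the rules, which caps
        # the fidelity below a perfect reconstruction
        assert np.corrcoef(pair.clean.samples, seg.samples)[0, 1] > 0.85

    def test_wander_removal_improves_correlation(self, clean_ecg_10s):
        ecg, _ = clean_ecg_10s
        t = np.arange(len(ecg)) / FS
        rng = np.random.default_rng(5)
        wander = sum(
            a * np.sin(2 * np.pi * f * t + rng.uniform(0, 7))
            for f, a in [(0.05, 0.5), (0.2, 0.4), (0.4, 0.3)]
        )
        noisy, _ = zscore(ecg.with_samples(ecg.samples + wander))
        pair, _, _ = aemdr_filter(noisy)
        truth = zs(ecg.samples)
        assert (
            np.corrcoef(pair.clean.samples, truth)[0, 1]
            > np.corrcoef(noisy.samples, truth)[0, 1]
        )

    def test_conservation(self, noisy_bundle):
        b = noisy_bundle
        for i in range(3):
            seg, _ = zscore(TimedSignal(b.noisy.samples[i * 2500 : (i + 1) * 2500], FS))
            pair, _, _ = aemdr_filter(seg)
            tol = 1e-8 * np.ptp(seg.samples)
            np.testing.assert_allclose(
                pair.clean.samples + pair.noise.samples, seg.samples, atol=tol
            )

    def test_qrs_count_preserved_on_corpus(self):
        """Beat counts on the clean reconstruction stay within +-1 of the
        input on >= 90% of default-condition (SNR ~ 0 dB) segments."""
        ok = total = 0
        for seed in range(4):
            b = gen_bundle(SynthSpec(duration_s=30.0, seed=seed))
            for i in range(3):
                seg, _ = zscore(TimedSignal(b.noisy.samples[i * 2500 : (i + 1) * 2500], FS))
                pair, _, _ = aemdr_filter(seg)
                total += 1
                ok += abs(len(detect_qrs(pair.clean)) - len(detect_qrs(seg))) <= 1
        assert ok / total >= 0.9

    def test_baseline_suppressed_in_clean_output(self, clean_ecg_10s):
        """On wander-contaminated segments the clean output's 2-s window means
        stay below 25% of the R amplitude."""
        ecg, _ = clean_ecg_10s
        t = np.arange(len(ecg)) / FS
        noisy, _ = zscore(ecg.with_samples(ecg.samples + 2.0 * np.sin(2 * np.pi * 0.2 * t)))
        pair, _, _ = aemdr_filter(noisy)
        r_amp = np.max(pair.clean.samples)
        win = int(2 * FS)
        for start in range(0, len(ecg) - win, win // 2):
            assert abs(pair.clean.samples[start : start + win].mean()) < 0.25 * r_amp
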