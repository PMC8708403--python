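import numpy as np
import pytest

from ecgdenoise.core_io import AccelTriplet, TimedSignal, segment_recording
from ecgdenoise.preprocess import minmax, resample_rational, zscore
from ecgdenoise.synthetic import SynthSpec, gen_bundle, gen_ecg

FS = 250.0


def zs(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


@pytest.fixture(scope="session")
def clean_ecg_10s():
    """Jitter-free 10-s clean ECG at 60 bpm with ground-truth R peaks."""
    spec = SynthSpec(duration_s=10.0, hr_bpm=60.0, hr_sd=0.0, seed=1)
    return gen_ecg(spec)


@pytest.fixture(scope="session")
def default_ecg_10s():
    """10-s clean ECG at the default study conditions (72.8 bpm, jittered)."""
    return gen_ecg(SynthSpec(duration_s=10.0, seed=1))


@pytest.fixture(scope="session")
def reference_segment():
    """10-s segment with mean RR 0.824 s (12 beats), mirroring a resting trace."""
    spec = SynthSpec(duration_s=10.0, hr_bpm=60.0 / 0.824, hr_sd=0.0, seed=1)
    return gen_ecg(spec)


@pytest.fixture(scope="session")
def noisy_bundle():
    """30-s default-condition bundle (wander + bursts, SNR ~ 0 dB)."""
    return gen_bundle(SynthSpec(duration_s=30.0, seed=3))


def resample_accel(bundle):
    """Accelerometer brought to the ECG rate and trimmed to its length."""
    n = len(bundle.noisy)
    return bundle.accel.map(
        lambda ch: TimedSignal(
            resample_rational(ch, bundle.noisy.fs).samples[:n], bundle.noisy.fs, ch.label
        )
    )


def normalized_pairs(bundle, window_s: float = 10.0):
    """Z-scored ECG segments paired with min-max normalized accel segments."""
    pairs = segment_recording(bundle.noisy, resample_accel(bundle), window_s)
    out = []
    for p in pairs:
        seg, _ = zscore(p.ecg)
        accel_n = p.accel.map(lambda ch: minmax(ch)[0])
        out.append((p.index, seg, accel_n))
    return out
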