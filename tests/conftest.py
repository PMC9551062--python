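import numpy as np
import pandas as pd
import pytest

from watchwalk import preprocess, steps
from watchwalk.io import RawRecording
from watchwalk.preprocess import ProcessedSignal
from watchwalk.simulate import simulate_walk

FS = 100.0


def make_recording(xyz: np.ndarray, fs: float = FS, **kw) -> RawRecording:
    return RawRecording(
        subject_id=kw.pop("subject_id", "test"),
        start_time=pd.Timestamp("2013-06-03 00:00:00"),
        fs=fs,
        samples=xyz,
        **kw,
    )


def make_signal(x: np.ndarray, fs: float = FS) -> ProcessedSignal:
    """A ProcessedSignal whose every norm channel is the given 1-D series
    (for tests that exercise one channel in isolation)."""
    x = np.asarray(x, dtype=float)
    axes = np.column_stack([np.zeros_like(x), np.zeros_like(x), x])
    return ProcessedSignal(
        fs=fs, en_crude=x, en_static_removed=x, en_lowpass=x, en_band=x, axes=axes
    )


@pytest.fixture(scope="session")
def clean_walk():
    """A 120-s arm-swing walk at 110 spm with low noise, preprocessed."""
    rec, gt = simulate_walk(cadence_spm=110, duration_s=120, noise_sd_g=0.02, seed=42)
    ps = preprocess.compute_channels(rec)
    return rec, gt, ps


@pytest.fixture(scope="session")
def clean_walk_bout(clean_walk):
    rec, gt, ps = clean_walk
    bout = steps.WalkingBout(0.0, rec.duration_s, [], "walk_armswing")
    return steps.detect_steps(bout, ps)
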