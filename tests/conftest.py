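import numpy as np
import pandas as pd
import pytest

from gazescene.core import GazeRecording, TrialDesign
from gazescene.simulate import start_position_deg

RATE = 120.0
DT_MS = 1000.0 / RATE


def make_recording(x, y, blink=None, trial_id="T1", noise=None, rng=None):
    """Binocular recording from one cyclopean trajectory (both eyes equal,
    unless per-eye noise is requested)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    t = np.arange(n) * DT_MS
    if noise:
        rng = rng or np.random.default_rng(0)
        e = rng.normal(0, noise, size=(n, 4))
    else:
        e = np.zeros((n, 4))
    blink = np.zeros(n, dtype=int) if blink is None else np.asarray(blink)
    xl, yl = x + e[:, 0], y + e[:, 1]
    xr, yr = x + e[:, 2], y + e[:, 3]
    m = blink == 1
    xl = np.where(m, np.nan, xl)
    yl = np.where(m, np.nan, yl)
    xr = np.where(m, np.nan, xr)
    yr = np.where(m, np.nan, yr)
    samples = pd.DataFrame(
        {"t_ms": t, "xl": xl, "yl": yl, "xr": xr, "yr": yr, "blink": blink}
    )
    design = TrialDesign(1, 1, "A", "Free_Viewing", "Chin_Rest", 8,
                         start_position_deg(8))
    rec = GazeRecording(samples=samples, design=design)
    return rec


def ramp_with_saccade(n=240, onset=100, sacc_len=5, step=2.0):
    """Constant position with one linear gaze shift of `step` deg/sample."""
    x = np.zeros(n)
    x[onset:onset + sacc_len] = step * np.arange(1, sacc_len + 1)
    x[onset + sacc_len:] = step * sacc_len
    y = np.zeros(n)
    return x, y


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
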