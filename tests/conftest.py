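import numpy as np
import pandas as pd
import pytest

from vswim import ExtractionConfig, make_profile, simulate_session
from vswim.records import make_records


@pytest.fixture(scope="session")
def profile7():
    return make_profile("7dpf")


@pytest.fixture(scope="session")
def quiet_profile():
    """7 dpf parameters with every noise term switched off."""
    return make_profile(
        "7dpf",
        ibi_lognoise_sigma=0.0,
        initial_pitch_jitter=0.0,
        attack_resid_sd=0.0,
        righting_resid_sd=0.0,
    )


@pytest.fixture(scope="session")
def quiet_session(quiet_profile):
    """Noise-free simulated session (~60 bouts) shared across tests."""
    return simulate_session(quiet_profile, 120.0, seed=42, epoch_break_rate=0.02)


@pytest.fixture(scope="session")
def short_session(profile7):
    """~8 s session for rendering/tracking tests (stays inside the frame)."""
    return simulate_session(profile7, 8.0, seed=5)


@pytest.fixture(scope="session")
def no_smoothing_cfg():
    return ExtractionConfig(speed_smoothing=1)


def records_from_speed(speed, fps=100.0, pitch=0.0, epoch_id=0, length=4.0, t0=0.0):
    """Build a record table whose computed per-frame speed equals ``speed``.

    Positions are the cumulative sum of the speed profile along x (the
    first frame's speed is, by convention, inherited from its successor).
    """
    speed = np.asarray(speed, dtype=float)
    n = len(speed)
    dt = 1.0 / fps
    x = np.concatenate([[0.0], np.cumsum(speed[1:]) * dt])
    pitch = np.broadcast_to(np.asarray(pitch, dtype=float), n).copy()
    return make_records(
        time=t0 + np.arange(n) * dt,
        body_x=x,
        body_z=np.zeros(n),
        head_x=x + 2.0,
        head_z=np.zeros(n),
        pitch=pitch,
        epoch_id=np.full(n, epoch_id, dtype=int),
        length=np.full(n, length),
    )


@pytest.fixture
def make_speed_records():
    return records_from_speed


def concat_records(*frames) -> pd.DataFrame:
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def stack_records():
    return concat_records
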