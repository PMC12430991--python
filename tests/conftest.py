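import numpy as np
import pandas as pd
import pytest

from vrstress import Session


def make_motion(t_end=20.0, fs=90.0, base=(0.3, 1.0, 0.4)):
    t = np.arange(0.0, t_end, 1.0 / fs)
    pos = np.tile(np.asarray(base, dtype=float), (t.size, 1))
    return pd.DataFrame({"t": t, "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2]})


def make_events(rows):
    return pd.DataFrame(rows, columns=["t", "kind", "task_id"])


def make_gsr(t_end=20.0, fs=5.0, level=0.5):
    t = np.arange(0.0, t_end, 1.0 / fs)
    return pd.DataFrame({"t": t, "conductance_uS": np.full(t.size, float(level))})


@pytest.fixture
def quiet_session():
    """Baseline session: drifting controller, prompt answered fast, low GSR."""
    motion = make_motion()
    # slow steady drift so the inactivity detector sees continuous activity
    motion["x"] += 0.01 * motion["t"]
    events = make_events([
        (2.0, "prompt", "a"), (2.5, "action", "a"), (3.0, "success", "a"),
        (8.0, "prompt", "b"), (8.4, "action", "b"), (9.0, "success", "b"),
        (14.0, "prompt", "c"), (14.5, "action", "c"), (15.0, "success", "c"),
    ])
    return Session(
        id="quiet", condition="baseline", class_label="Negative",
        motion=motion, events=events,
        stressors=pd.DataFrame(columns=["t_onset", "kind", "duration"]),
        gsr=make_gsr(level=0.5),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
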