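"""Behavioral stress indicators extracted from VR telemetry.

Four binary indicators are computed per trial — hesitation, repeated errors,
inactivity, and trembling — and summed into the behavioral score ``Sb``
(range 0-4).  Hesitation and inactivity thresholds are strict (delay > 2 s,
no input for > 3 s); repeated errors require at least two failed attempts;
trembling fires when the high-pass-filtered controller jitter exceeds
0.03 tracker units RMS.

The "jitter" signal is the controller position minus its centered moving
average over a short window (0.5 s by default): a parameter-light high-pass
that passes physiological tremor (4-12 Hz) while removing voluntary reach
motion.  The dominant tremor frequency is estimated from the zero-crossing
rate of the first jitter axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .session import TrialRecord, Session


@dataclass(frozen=True)
class BehaviorThresholds:
    """Thresholds for the four behavioral indicators (all strictly positive)."""

    hesitation_s: float = 2.0       # reaction delay, seconds (strict >)
    min_failures: int = 2           # failed attempts per trial (inclusive >=)
    inactivity_s: float = 3.0       # quiet gap, seconds (strict >)
    jitter_units: float = 0.03      # tremor RMS, tracker units (strict >)
    highpass_window_s: float = 0.5  # moving-average window for the jitter high-pass
    motion_eps: float = 1e-4        # minimum speed counting as activity, units/s

    def __post_init__(self) -> None:
        for name in ("hesitation_s", "min_failures", "inactivity_s",
                     "jitter_units", "highpass_window_s", "motion_eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class BehavioralIndicators:
    """Per-trial indicator values: four binary flags plus their raw features."""

    hesitation_delay: float
    hesitation_flag: int
    failure_count: int
    error_flag: int
    max_inactivity_gap: float
    inactivity_flag: int
    tremor_rms: float
    tremor_freq: float
    tremor_flag: int

    @property
    def Sb(self) -> int:
        return behavioral_score(
            self.hesitation_flag, self.error_flag,
            self.inactivity_flag, self.tremor_flag,
        )


def hesitation(trial: TrialRecord, thresholds: BehaviorThresholds) -> tuple[float, int]:
    """Reaction delay and its flag.

    Delay is time from prompt to first action; a trial with no action takes
    the full trial duration (hesitation is never undefined).
    """
    if trial.t_first_action is not None:
        delay = trial.t_first_action - trial.t_prompt
    else:
        delay = trial.t_end - trial.t_prompt
    return delay, int(delay > thresholds.hesitation_s)


def repeated_failures(trial: TrialRecord, thresholds: BehaviorThresholds) -> tuple[int, int]:
    """Failed-attempt count and its flag (>= min_failures)."""
    return trial.failure_count, int(trial.failure_count >= thresholds.min_failures)


def inactivity(
    motion: pd.DataFrame,
    events: pd.DataFrame,
    window: tuple[float, float],
    thresholds: BehaviorThresholds,
) -> tuple[float, int]:
    """Longest quiet gap inside ``window`` and its flag.

    A time is "active" when an input event occurs or the controller's
    finite-difference speed exceeds ``motion_eps``.  The gap is measured
    between consecutive active times, bounded by the window edges.
    """
    w0, w1 = window
    if w1 <= w0:
        raise ValueError(f"empty inactivity window [{w0}, {w1}]")

    active = []
    if len(events):
        et = events["t"].to_numpy(dtype=float)
        active.append(et[(et >= w0) & (et <= w1)])
    if len(motion) >= 2:
        t = motion["t"].to_numpy(dtype=float)
        pos = motion[["x", "y", "z"]].to_numpy(dtype=float)
        dt = np.diff(t)
        speed = np.linalg.norm(np.diff(pos, axis=0), axis=1) / dt
        tm = t[1:]
        mask = (tm >= w0) & (tm <= w1) & (speed > thresholds.motion_eps)
        active.append(tm[mask])

    marks = np.sort(np.concatenate([[w0], *active, [w1]]))
    max_gap = float(np.max(np.diff(marks)))
    return max_gap, int(max_gap > thresholds.inactivity_s)


def moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    s = pd.Series(x)
    return s.rolling(n, center=True, min_periods=1).mean().to_numpy()


def tremor(
    motion: pd.DataFrame,
    window: tuple[float, float],
    thresholds: BehaviorThresholds,
) -> tuple[float, float, int]:
    """Tremor RMS (tracker units), dominant frequency (Hz) and flag.

    The jitter signal is the per-axis position minus its centered moving
    average over ``highpass_window_s``, combined as a Euclidean magnitude.
    Dominant frequency is the zero-crossing rate of the first jitter axis
    divided by two.
    """
    w0, w1 = window
    t = motion["t"].to_numpy(dtype=float)
    sel = (t >= w0) & (t <= w1)
    t = t[sel]
    if t.size < 4:
        raise ValueError(f"too few motion samples ({t.size}) in tremor window")
    fs = 1.0 / float(np.median(np.diff(t)))
    if t.size < 2 * thresholds.highpass_window_s * fs:
        raise ValueError(
            f"tremor window shorter than twice the high-pass window "
            f"({t.size} samples at {fs:.1f} Hz)"
        )

    pos = motion.loc[sel, ["x", "y", "z"]].to_numpy(dtype=float)
    n = int(round(thresholds.highpass_window_s * fs))
    n = max(3, n + (1 - n % 2))  # odd, >= 3
    jitter = pos - np.column_stack([moving_average(pos[:, k], n) for k in range(3)])
    mag = np.linalg.norm(jitter, axis=1)
    rms = float(np.sqrt(np.mean(mag**2)))

    jx = jitter[:, 0]
    crossings = int(np.sum(np.signbit(jx[:-1]) != np.signbit(jx[1:])))
    span = t[-1] - t[0]
    freq = crossings / span / 2.0 if span > 0 else 0.0
    return rms, float(freq), int(rms > thresholds.jitter_units)


def behavioral_score(*flags: int) -> int:
    """Sum of the four binary indicator flags: ``Sb`` in {0..4}."""
    if len(flags) != 4:
        raise ValueError("behavioral_score expects exactly four flags")
    for f in flags:
        if f not in (0, 1):
            raise ValueError(f"flag must be binary, got {f!r}")
    return int(sum(flags))


def indicators_for_trial(
    session: Session,
    trial: TrialRecord,
    thresholds: Optional[BehaviorThresholds] = None,
) -> BehavioralIndicators:
    """All four indicators evaluated over one trial's window."""
    thresholds = thresholds or BehaviorThresholds()
    delay, h_flag = hesitation(trial, thresholds)
    count, e_flag = repeated_failures(trial, thresholds)
    window = (trial.t_prompt, trial.t_end)
    gap, i_flag = inactivity(session.motion, session.events, window, thresholds)
    try:
        rms, freq, t_flag = tremor(session.motion, window, thresholds)
    except ValueError:
        rms, freq, t_flag = 0.0, 0.0, 0
    return BehavioralIndicators(
        hesitation_delay=delay, hesitation_flag=h_flag,
        failure_count=count, error_flag=e_flag,
        max_inactivity_gap=gap, inactivity_flag=i_flag,
        tremor_rms=rms, tremor_freq=freq, tremor_flag=t_flag,
    )


def extract_features(
    session: Session,
    thresholds: Optional[BehaviorThresholds] = None,
) -> pd.DataFrame:
    """Per-trial feature table for a session.

    Columns: session_id, task_id, delay_s, failures, gap_s, tremor_rms,
    tremor_freq_hz, the four flags, Sb, and (when GSR is present) the mean
    conductance over the trial window as gsr_uS.
    """
    thresholds = thresholds or BehaviorThresholds()
    rows = []
    for trial in session.trials():
        ind = indicators_for_trial(session, trial, thresholds)
        row = {
            "session_id": session.id,
            "task_id": trial.task_id,
            "class_label": session.class_label,
            "delay_s": ind.hesitation_delay,
            "failures": ind.failure_count,
            "gap_s": ind.max_inactivity_gap,
            "tremor_rms": ind.tremor_rms,
            "tremor_freq_hz": ind.tremor_freq,
            "hesitation_flag": ind.hesitation_flag,
            "error_flag": ind.error_flag,
            "inactivity_flag": ind.inactivity_flag,
            "tremor_flag": ind.tremor_flag,
            "Sb": ind.Sb,
        }
        if session.gsr is not None and len(session.gsr):
            gt = session.gsr["t"].to_numpy(dtype=float)
            gv = session.gsr["conductance_uS"].to_numpy(dtype=float)
            m = (gt >= trial.t_prompt) & (gt < trial.t_end)
            row["gsr_uS"] = float(gv[m].mean()) if m.any() else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
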