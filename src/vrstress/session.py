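"""Session data model and file I/O for VR stress-detection telemetry.

A :class:`Session` bundles the multi-rate traces recorded during one VR run:
a controller motion trace (timestamped 3-D positions in tracker units), a
discrete input-event log (prompts, actions, successes, failures), an optional
galvanic skin response (GSR) trace in microsiemens, and the stressor schedule
that was active during the run.  All traces share a single clock measured in
seconds from session start.

On disk a session is a directory bundle of plain CSV tables plus a JSON
manifest; ``read_session`` and ``write_session`` are exact inverses on valid
sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

CONDITIONS = ("baseline", "red_light", "time_pressure", "high_stress")
CLASS_LABELS = ("Negative", "Neutral", "Positive")
EVENT_KINDS = ("prompt", "action", "success", "failure")
STRESSOR_KINDS = ("red_light", "alarm", "time_pressure")

MOTION_COLS = ["t", "x", "y", "z"]
EVENT_COLS = ["t", "kind", "task_id"]
GSR_COLS = ["t", "conductance_uS"]
STRESSOR_COLS = ["t_onset", "kind", "duration"]


class SessionError(ValueError):
    """Raised when a session violates a structural invariant."""


@dataclass
class TrialRecord:
    """One prompted task attempt, reconstructed from the event log.

    The trial window is half-open: ``[t_prompt, next prompt or session end)``.
    ``t_first_action`` is ``None`` for trials in which the user never acted.
    """

    task_id: str
    t_prompt: float
    t_first_action: Optional[float]
    t_end: float
    failure_count: int
    outcome: str  # success | failure | timeout

    @property
    def duration(self) -> float:
        return self.t_end - self.t_prompt


@dataclass
class Session:
    """In-memory container for one VR session's traces.

    ``gsr`` may be ``None`` (behavior-only mode: detection from interaction
    data alone).  A baseline-condition session must have an empty stressor
    schedule.
    """

    id: str
    condition: str
    motion: pd.DataFrame
    events: pd.DataFrame
    stressors: pd.DataFrame
    gsr: Optional[pd.DataFrame] = None
    class_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise SessionError(f"unknown condition {self.condition!r}")
        if self.class_label is not None and self.class_label not in CLASS_LABELS:
            raise SessionError(f"unknown class_label {self.class_label!r}")

        _check_columns(self.motion, MOTION_COLS, "motion")
        _check_columns(self.events, EVENT_COLS, "events")
        _check_columns(self.stressors, STRESSOR_COLS, "stressors")
        if self.gsr is not None:
            _check_columns(self.gsr, GSR_COLS, "gsr")

        _check_time_axis(self.motion["t"], "motion", strict=True)
        _check_time_axis(self.events["t"], "events", strict=False)
        bad = [k for k in self.events["kind"] if k not in EVENT_KINDS]
        if bad:
            raise SessionError(f"unknown event kind(s) {sorted(set(bad))!r}")

        if self.gsr is not None:
            _check_time_axis(self.gsr["t"], "gsr", strict=True)
            neg = np.flatnonzero(self.gsr["conductance_uS"].to_numpy() < 0)
            if neg.size:
                raise SessionError(
                    f"gsr row {neg[0]}: negative conductance "
                    f"{self.gsr['conductance_uS'].iloc[neg[0]]}"
                )

        bad = [k for k in self.stressors["kind"] if k not in STRESSOR_KINDS]
        if bad:
            raise SessionError(f"unknown stressor kind(s) {sorted(set(bad))!r}")
        if len(self.stressors):
            dur = self.stressors["duration"].to_numpy(dtype=float)
            if (dur <= 0).any():
                raise SessionError("stressor duration must be > 0")
            onsets = self.stressors["t_onset"].to_numpy(dtype=float)
            if (onsets < 0).any() or (onsets > self.t_end).any():
                raise SessionError("stressor onset outside session span")
        if self.condition == "baseline" and len(self.stressors):
            raise SessionError("baseline condition must have no stressors")

    @property
    def t_end(self) -> float:
        """Last timestamp covered by any trace."""
        ends = [0.0]
        if len(self.motion):
            ends.append(float(self.motion["t"].iloc[-1]))
        if len(self.events):
            ends.append(float(self.events["t"].iloc[-1]))
        if self.gsr is not None and len(self.gsr):
            ends.append(float(self.gsr["t"].iloc[-1]))
        return max(ends)

    def trials(self) -> list[TrialRecord]:
        return derive_trials(self.events, session_end=self.t_end)


def _check_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SessionError(f"{name} table missing required column(s) {missing}")


def _check_time_axis(t: pd.Series, name: str, strict: bool) -> None:
    tv = t.to_numpy(dtype=float)
    if tv.size and tv[0] < 0:
        raise SessionError(f"{name} row 0: negative timestamp {tv[0]}")
    d = np.diff(tv)
    bad = np.flatnonzero(d < 0 if not strict else d <= 0)
    if bad.size:
        i = int(bad[0]) + 1
        raise SessionError(
            f"{name} row {i}: timestamp {tv[i]} out of order (previous {tv[i - 1]})"
        )


# -- bundle I/O ----------------------------------------------------------


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session bundle (manifest + CSV tables) under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "id": session.id,
        "condition": session.condition,
        "class_label": session.class_label,
        "has_gsr": session.gsr is not None,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    session.motion.to_csv(path / "motion.csv", index=False)
    session.events.to_csv(path / "events.csv", index=False)
    session.stressors.to_csv(path / "stressors.csv", index=False)
    if session.gsr is not None:
        session.gsr.to_csv(path / "gsr.csv", index=False)
    return path


def read_session(path: str | Path) -> Session:
    """Read and validate a session bundle written by :func:`write_session`."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise SessionError(f"no manifest.json under {path}")
    manifest = json.loads(manifest_path.read_text())

    motion = _read_table(path / "motion.csv", MOTION_COLS, {"kind": str})
    events = _read_table(path / "events.csv", EVENT_COLS, {"kind": str, "task_id": str})
    stressors = _read_table(path / "stressors.csv", STRESSOR_COLS, {"kind": str})
    gsr = None
    if (path / "gsr.csv").exists():
        gsr = _read_table(path / "gsr.csv", GSR_COLS, {})

    return Session(
        id=str(manifest["id"]),
        condition=manifest["condition"],
        class_label=manifest.get("class_label"),
        motion=motion,
        events=events,
        stressors=stressors,
        gsr=gsr,
    )


def _read_table(path: Path, cols: list[str], dtypes: dict) -> pd.DataFrame:
    if not path.exists():
        raise SessionError(f"missing required table {path.name}")
    df = pd.read_csv(path, dtype=dtypes)
    _check_columns(df, cols, path.stem)
    return df[cols]


# -- trial derivation ----------------------------------------------------


def derive_trials(events: pd.DataFrame, session_end: Optional[float] = None) -> list[TrialRecord]:
    """Segment the event log into one :class:`TrialRecord` per prompt.

    Each action/success/failure event is assigned to the prompt whose
    half-open window ``[t_prompt, next prompt or session end)`` contains it
    and must carry the same ``task_id``; anything else is an orphan and an
    error.
    """
    ev = events.reset_index(drop=True)
    prompt_idx = ev.index[ev["kind"] == "prompt"].tolist()
    if session_end is None:
        session_end = float(ev["t"].iloc[-1]) if len(ev) else 0.0

    orphans = ev.iloc[: prompt_idx[0]] if prompt_idx else ev
    bad = orphans[orphans["kind"] != "prompt"]
    if len(bad):
        raise SessionError(
            "orphan event(s) before first prompt for task_id(s) "
            f"{sorted(set(bad['task_id']))}"
        )

    trials: list[TrialRecord] = []
    for j, pi in enumerate(prompt_idx):
        t_prompt = float(ev["t"].iloc[pi])
        task_id = str(ev["task_id"].iloc[pi])
        hi = prompt_idx[j + 1] if j + 1 < len(prompt_idx) else len(ev)
        t_end = float(ev["t"].iloc[hi]) if hi < len(ev) else float(session_end)
        window = ev.iloc[pi + 1 : hi]
        stray = window[window["task_id"].astype(str) != task_id]
        if len(stray):
            raise SessionError(
                f"orphan event(s) with task_id {sorted(set(stray['task_id']))} "
                f"inside trial {task_id!r}"
            )
        actions = window[window["kind"] == "action"]
        t_first_action = float(actions["t"].iloc[0]) if len(actions) else None
        failure_count = int((window["kind"] == "failure").sum())
        if (window["kind"] == "success").any():
            outcome = "success"
        elif failure_count > 0:
            outcome = "failure"
        else:
            outcome = "timeout" if t_first_action is None else "success"
        trials.append(
            TrialRecord(
                task_id=task_id,
                t_prompt=t_prompt,
                t_first_action=t_first_action,
                t_end=t_end,
                failure_count=failure_count,
                outcome=outcome,
            )
        )
    return trials
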