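"""Rule-based fusion of behavioral and physiological stress evidence.

Three decision layers, all threshold rules:

* the fused score ``Sf = alpha * Sb + beta * Sp`` with a stress trigger at
  ``Sf >= 3`` (inclusive, so two behavioral flags plus a GSR rise, or three
  behavioral flags alone, declare stress);
* a three-tier online policy — tier 1 issues an immediate alert on a single
  overwhelming signal (tremor dominant frequency above 30 Hz or smoothed GSR
  above 0.7 uS), tier 2 fuses partial evidence as ``S = 0.6 B + 0.4 Gnorm``
  (with ``B = Sb / 4``) and alerts when ``S > 0.65`` (strict), and tier 3
  stays idle when every indicator is quiet;
* a three-class rule classifier: scaled nearest-centroid over (hesitation
  time, tremble amplitude, GSR), with centroids at the per-class medians and
  per-feature scales equal to the inter-class median range.

The :class:`StreamDetector` applies the tier policy online, one decision per
GSR tick (5 Hz), with bounded work per sample; batch detection feeds the
same state machine, so online and offline decisions agree exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .behavior import (
    BehavioralIndicators,
    BehaviorThresholds,
    hesitation,
    inactivity,
    repeated_failures,
    tremor,
)
from .gsr import GsrParams, GsrSeries, GsrState, NormalizationContext, level_flag, ols_slope
from .session import Session, TrialRecord, derive_trials


@dataclass(frozen=True)
class FusionParams:
    """Weights and thresholds of the fusion rules (baseline model defaults)."""

    alpha: float = 1.0            # weight on the behavioral score Sb
    beta: float = 1.5             # weight on the physiological flag Sp
    trigger: float = 3.0          # Sf stress trigger (inclusive >=)
    w_b: float = 0.6              # tier-2 weight on B
    w_g: float = 0.4              # tier-2 weight on Gnorm
    s_thresh: float = 0.65        # tier-2 alert threshold (strict >)
    tier1_gsr: float = 0.7        # uS, tier-1 immediate-alert level (strict >)
    tier1_tremor_freq: float = 30.0  # Hz, tier-1 tremor frequency (strict >)

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.w_b < 0 or self.w_g < 0:
            raise ValueError("fusion weights must be nonnegative")
        for name in ("trigger", "s_thresh", "tier1_gsr", "tier1_tremor_freq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class StressDecision:
    """One decision of the tiered policy. ``stress`` is the tier alert."""

    Sf: float
    stress: bool
    tier: int
    S: Optional[float]
    reason: str
    t: Optional[float] = None
    Sb: int = 0
    Sp: int = 0

    def __post_init__(self) -> None:
        if self.tier == 1 and not self.stress:
            raise ValueError("tier 1 implies an alert")
        if self.tier == 3 and self.stress:
            raise ValueError("tier 3 implies no alert")


def fuse(Sb: int, Sp: int, params: Optional[FusionParams] = None) -> tuple[float, bool]:
    """Fused score ``Sf = alpha*Sb + beta*Sp``; stress iff ``Sf >= trigger``."""
    params = params or FusionParams()
    if Sb not in (0, 1, 2, 3, 4):
        raise ValueError(f"Sb must be in 0..4, got {Sb!r}")
    if Sp not in (0, 1):
        raise ValueError(f"Sp must be binary, got {Sp!r}")
    Sf = params.alpha * Sb + params.beta * Sp
    return Sf, Sf >= params.trigger


def normalized_behavior(Sb: int) -> float:
    """Map the 0-4 behavioral score onto [0, 1]: ``B = Sb / 4``."""
    if Sb not in (0, 1, 2, 3, 4):
        raise ValueError(f"Sb must be in 0..4, got {Sb!r}")
    return Sb / 4.0


def tier_decision(
    behavior: BehavioralIndicators,
    gsr_state: Optional[GsrState],
    params: Optional[FusionParams] = None,
    t: Optional[float] = None,
) -> StressDecision:
    """Apply the three-tier policy to one tick of evidence.

    With ``gsr_state`` absent (behavior-only mode) tier 2 scores ``S = B``
    and tier 1 can fire only on tremor frequency.
    """
    params = params or FusionParams()
    Sb = behavior.Sb
    Sp = gsr_state.Sp if gsr_state is not None else 0
    Sf, _ = fuse(Sb, Sp, params)
    B = normalized_behavior(Sb)

    if behavior.tremor_freq > params.tier1_tremor_freq:
        return StressDecision(
            Sf=Sf, stress=True, tier=1, S=None, t=t, Sb=Sb, Sp=Sp,
            reason=f"tier1: tremor frequency {behavior.tremor_freq:.1f} Hz "
                   f"> {params.tier1_tremor_freq:g} Hz",
        )
    if gsr_state is not None and gsr_state.level > params.tier1_gsr:
        return StressDecision(
            Sf=Sf, stress=True, tier=1, S=None, t=t, Sb=Sb, Sp=Sp,
            reason=f"tier1: GSR {gsr_state.level:.2f} uS > {params.tier1_gsr:g} uS",
        )

    quiet = Sb == 0 and Sp == 0 and (gsr_state is None or gsr_state.level_flag == 0)
    if quiet:
        return StressDecision(Sf=Sf, stress=False, tier=3, S=None, t=t, Sb=Sb, Sp=Sp,
                              reason="tier3: all indicators quiet")

    if gsr_state is None:
        S = B
    else:
        S = params.w_b * B + params.w_g * gsr_state.Gnorm
    alert = S > params.s_thresh
    op = ">" if alert else "<="
    return StressDecision(Sf=Sf, stress=alert, tier=2, S=S, t=t, Sb=Sb, Sp=Sp,
                          reason=f"tier2: S={S:.3f} {op} {params.s_thresh:g}")


# -- three-class rule classifier ----------------------------------------

#: Per-class medians of (hesitation time s, tremble amplitude, GSR uS).
CLASS_MEDIANS = {
    "Negative": (0.99, 0.0060, 0.62),
    "Neutral": (1.69, 0.0160, 0.77),
    "Positive": (0.91, 0.0050, 0.61),
}


@dataclass
class ClassCentroids:
    """Nearest-centroid rule: per-class feature medians and per-feature scales."""

    centroids: dict = field(default_factory=lambda: dict(CLASS_MEDIANS))
    scales: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if len(self.centroids) != 3:
            raise ValueError("expected exactly three classes")
        if self.scales is None:
            arr = np.array(list(self.centroids.values()), dtype=float)
            self.scales = tuple(arr.max(axis=0) - arr.min(axis=0))
        if any(s <= 0 for s in self.scales):
            raise ValueError("per-feature scales must be > 0")


def centroid_scores(
    features: tuple[float, float, float],
    centroids: Optional[ClassCentroids] = None,
) -> dict[str, float]:
    """Continuous per-class scores: negative scaled distance to each centroid."""
    cen = centroids or ClassCentroids()
    x = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite feature in {features!r}")
    s = np.asarray(cen.scales, dtype=float)
    return {
        cls: -float(np.linalg.norm((x - np.asarray(c)) / s))
        for cls, c in cen.centroids.items()
    }


def classify3(
    features: tuple[float, float, float],
    centroids: Optional[ClassCentroids] = None,
) -> str:
    """Nearest-centroid class under per-feature scaled distance; ties -> Neutral."""
    scores = centroid_scores(features, centroids)
    best = max(scores.values())
    winners = [cls for cls, sc in scores.items() if math.isclose(sc, best, abs_tol=1e-12)]
    if len(winners) > 1 and "Neutral" in scores:
        return "Neutral"
    return winners[0]


# -- online detection ----------------------------------------------------


@dataclass(frozen=True)
class DetectorWindows:
    """Trailing analysis windows and the GSR calibration segment, seconds."""

    tremor_s: float = 2.0
    inactivity_s: float = 5.0
    calibration_s: float = 5.0
    buffer_s: float = 12.0  # history kept; must cover the longest window
    gnorm_floor: float = 0.2  # minimum uS span of the min-max range


class StreamDetector:
    """Online tiered stress detection over time-ordered telemetry.

    Feed samples with :meth:`update` (all streams merged, nondecreasing in
    time) and close the run with :meth:`finalize`.  One decision is emitted
    per GSR grid tick (after an initial calibration segment); in
    behavior-only mode one decision is emitted at each trial close.  Work per
    sample is bounded by the fixed trailing windows, so streaming any
    session reproduces the batch decision sequence exactly.
    """

    def __init__(
        self,
        thresholds: Optional[BehaviorThresholds] = None,
        gsr_params: Optional[GsrParams] = None,
        fusion_params: Optional[FusionParams] = None,
        windows: Optional[DetectorWindows] = None,
        gsr_fs: float = 5.0,
        has_gsr: bool = True,
    ) -> None:
        self.thresholds = thresholds or BehaviorThresholds()
        self.gsr_params = gsr_params or GsrParams()
        self.fusion_params = fusion_params or FusionParams()
        self.windows = windows or DetectorWindows()
        self.gsr_fs = gsr_fs
        self.has_gsr = has_gsr

        self._t_last = -np.inf
        self._t_start: Optional[float] = None
        self._motion: list[tuple[float, float, float, float]] = []
        self._events: list[tuple[float, str, str]] = []
        # trial tracking
        self._open_prompt: Optional[tuple[float, str]] = None
        self._open_events: list[tuple[float, str]] = []
        self._last_trial: Optional[TrialRecord] = None
        # gsr state
        self._gsr_t0: Optional[float] = None
        self._gsr_prev: Optional[tuple[float, float]] = None
        self._grid_k = 0
        self._smoothed = 0.0
        self._n_smoothed = 0
        self._slope_buf: list[float] = []
        self._n_slope = int(round(self.gsr_params.slope_window * gsr_fs))
        self._alpha = 1.0 - np.exp(-1.0 / (gsr_fs * self.gsr_params.smooth_tau))
        self._calib_lo = np.inf
        self._calib_hi = -np.inf
        self._ctx: Optional[NormalizationContext] = None
        self.decisions: list[StressDecision] = []

    # -- feeding ---------------------------------------------------------

    def update(
        self,
        motion: Optional[pd.DataFrame] = None,
        events: Optional[pd.DataFrame] = None,
        gsr: Optional[pd.DataFrame] = None,
    ) -> list[StressDecision]:
        """Feed a chunk of samples; returns the decisions it triggered.

        Streams are merged by timestamp (motion before events before GSR on
        ties) and must not move backwards between calls.
        """
        merged: list[tuple[float, int, tuple]] = []
        if motion is not None:
            for row in motion.itertuples(index=False):
                merged.append((float(row.t), 0, (float(row.x), float(row.y), float(row.z))))
        if events is not None:
            for row in events.itertuples(index=False):
                merged.append((float(row.t), 1, (str(row.kind), str(row.task_id))))
        if gsr is not None:
            for row in gsr.itertuples(index=False):
                merged.append((float(row.t), 2, (float(row.conductance_uS),)))
        merged.sort(key=lambda r: (r[0], r[1]))

        before = len(self.decisions)
        for t, stream, payload in merged:
            if t < self._t_last:
                raise ValueError(f"out-of-order sample at t={t} (last {self._t_last})")
            self._t_last = t
            if self._t_start is None:
                self._t_start = t
            if stream == 0:
                self._motion.append((t, *payload))
            elif stream == 1:
                self._ingest_event(t, *payload)
            else:
                self._ingest_gsr(t, payload[0])
            self._prune(t)
        return self.decisions[before:]

    def finalize(self, t_end: Optional[float] = None) -> list[StressDecision]:
        """Close the run: finish the open trial and flush its decision."""
        before = len(self.decisions)
        t_end = self._t_last if t_end is None else t_end
        if self._open_prompt is not None:
            self._close_trial(t_end)
        return self.decisions[before:]

    # -- internals -------------------------------------------------------

    def _prune(self, t_now: float) -> None:
        horizon = t_now - self.windows.buffer_s
        while self._motion and self._motion[0][0] < horizon:
            self._motion.pop(0)
        while self._events and self._events[0][0] < horizon:
            self._events.pop(0)

    def _ingest_event(self, t: float, kind: str, task_id: str) -> None:
        self._events.append((t, kind, task_id))
        if kind == "prompt":
            if self._open_prompt is not None:
                self._close_trial(t)
            self._open_prompt = (t, task_id)
            self._open_events = []
        elif self._open_prompt is not None:
            self._open_events.append((t, kind))

    def _close_trial(self, t_end: float) -> None:
        t_prompt, task_id = self._open_prompt
        actions = [t for t, k in self._open_events if k == "action"]
        failures = sum(1 for _, k in self._open_events if k == "failure")
        succeeded = any(k == "success" for _, k in self._open_events)
        t_first = actions[0] if actions else None
        if succeeded:
            outcome = "success"
        elif failures:
            outcome = "failure"
        else:
            outcome = "timeout" if t_first is None else "success"
        self._last_trial = TrialRecord(
            task_id=task_id, t_prompt=t_prompt, t_first_action=t_first,
            t_end=t_end, failure_count=failures, outcome=outcome,
        )
        self._open_prompt = None
        self._open_events = []
        if not self.has_gsr:
            self._emit(t_end, gsr_state=None)

    def _ingest_gsr(self, t: float, value: float) -> None:
        if self._gsr_t0 is None:
            self._gsr_t0 = t
        while True:
            t_grid = self._gsr_t0 + self._grid_k / self.gsr_fs
            if t_grid > t + 1e-12:
                break
            if self._gsr_prev is None or t_grid >= t - 1e-12:
                v = value
            else:
                tp, vp = self._gsr_prev
                v = vp + (value - vp) * (t_grid - tp) / (t - tp)
            self._on_grid(t_grid, v)
            self._grid_k += 1
        self._gsr_prev = (t, value)

    def _on_grid(self, t_grid: float, raw: float) -> None:
        if self._n_smoothed == 0:
            self._smoothed = raw
        else:
            self._smoothed += self._alpha * (raw - self._smoothed)
        self._n_smoothed += 1
        self._slope_buf.append(self._smoothed)
        if len(self._slope_buf) > self._n_slope:
            self._slope_buf.pop(0)

        in_calib = t_grid <= self._gsr_t0 + self.windows.calibration_s + 1e-12
        if in_calib:
            self._calib_lo = min(self._calib_lo, self._smoothed)
            self._calib_hi = max(self._calib_hi, self._smoothed)
            return
        if self._ctx is None:
            hi = max(self._calib_hi, self._calib_lo + self.windows.gnorm_floor)
            self._ctx = NormalizationContext(
                baseline_mean={"gsr_uS": (self._calib_lo + self._calib_hi) / 2},
                calibration_min=self._calib_lo,
                calibration_max=hi,
            )
        if len(self._slope_buf) < self._n_slope:
            return
        slope = ols_slope(np.asarray(self._slope_buf), self.gsr_fs)
        level = self._smoothed
        rng = self._ctx.calibration_max - self._ctx.calibration_min
        gnorm = float(np.clip((level - self._ctx.calibration_min) / rng, 0.0, 1.0))
        state = GsrState(
            slope=slope,
            Sp=int(slope > self.gsr_params.slope_thresh),
            level_flag=int(level > self.gsr_params.level_thresh),
            Gnorm=gnorm,
            level=level,
        )
        self._emit(t_grid, state)

    def _behavior_at(self, t: float) -> BehavioralIndicators:
        thr = self.thresholds
        if self._last_trial is not None:
            delay, h_flag = hesitation(self._last_trial, thr)
            count, e_flag = repeated_failures(self._last_trial, thr)
        else:
            delay, h_flag, count, e_flag = 0.0, 0, 0, 0

        motion = pd.DataFrame(
            [m for m in self._motion if m[0] <= t + 1e-12],
            columns=["t", "x", "y", "z"],
        )
        events = pd.DataFrame(
            [(et, k, tid) for et, k, tid in self._events if et <= t + 1e-12],
            columns=["t", "kind", "task_id"],
        )
        w0 = max(self._t_start, t - self.windows.inactivity_s)
        if t > w0:
            gap, i_flag = inactivity(motion, events, (w0, t), thr)
        else:
            gap, i_flag = 0.0, 0
        try:
            rms, freq, t_flag = tremor(motion, (t - self.windows.tremor_s, t), thr)
        except ValueError:
            rms, freq, t_flag = 0.0, 0.0, 0
        return BehavioralIndicators(
            hesitation_delay=delay, hesitation_flag=h_flag,
            failure_count=count, error_flag=e_flag,
            max_inactivity_gap=gap, inactivity_flag=i_flag,
            tremor_rms=rms, tremor_freq=freq, tremor_flag=t_flag,
        )

    def _emit(self, t: float, gsr_state: Optional[GsrState]) -> None:
        behavior = self._behavior_at(t)
        self.decisions.append(
            tier_decision(behavior, gsr_state, self.fusion_params, t=t)
        )


def detect_session(
    session: Session,
    thresholds: Optional[BehaviorThresholds] = None,
    gsr_params: Optional[GsrParams] = None,
    fusion_params: Optional[FusionParams] = None,
    windows: Optional[DetectorWindows] = None,
    behavior_only: bool = False,
) -> pd.DataFrame:
    """Batch detection: run the streaming detector over a whole session.

    Returns one row per decision: t, Sb, Sp, Sf, stress_sf, tier, S, alert,
    reason.  ``stress_sf`` is the baseline fused-score rule (Sf >= trigger);
    ``alert`` is the tiered policy's output.
    """
    has_gsr = session.gsr is not None and not behavior_only
    det = StreamDetector(
        thresholds=thresholds, gsr_params=gsr_params, fusion_params=fusion_params,
        windows=windows, has_gsr=has_gsr,
    )
    det.update(
        motion=session.motion,
        events=session.events,
        gsr=session.gsr if has_gsr else None,
    )
    det.finalize(session.t_end)
    return decisions_frame(det.decisions, det.fusion_params)


def decisions_frame(decisions: list[StressDecision], params: FusionParams) -> pd.DataFrame:
    rows = [
        {
            "t": d.t,
            "Sb": d.Sb,
            "Sp": d.Sp,
            "Sf": d.Sf,
            "stress_sf": d.Sf >= params.trigger,
            "tier": d.tier,
            "S": d.S if d.S is not None else np.nan,
            "alert": d.stress,
            "reason": d.reason,
        }
        for d in decisions
    ]
    return pd.DataFrame(
        rows,
        columns=["t", "Sb", "Sp", "Sf", "stress_sf", "tier", "S", "alert", "reason"],
    )


def continuous_score(
    session: Session,
    fusion_params: Optional[FusionParams] = None,
    **kwargs,
) -> pd.DataFrame:
    """Per-tick ranking scores (Sf, and S where defined) for ROC analysis."""
    df = detect_session(session, fusion_params=fusion_params, **kwargs)
    return df[["t", "Sf", "S"]]
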