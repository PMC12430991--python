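"""Galvanic skin response (GSR) conditioning and physiological flags.

The raw conductance trace is resampled onto a uniform 5 Hz grid, smoothed
with a first-order exponential filter (causal, streaming-compatible), and
scanned by a slope detector: an ordinary-least-squares slope over a trailing
3 s window that sets the physiological flag ``Sp`` when the rise exceeds
0.05 uS/s.  A separate level flag fires when the smoothed conductance
exceeds 0.7 uS, the minimum event-related skin conductance response
magnitude used by the tier-1 decision rule.  ``Gnorm`` is a per-user min-max
normalization of the smoothed signal onto [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class GsrSeries:
    """Uniformly sampled conductance series (``values[i]`` at ``t0 + i/fs``)."""

    t0: float
    fs: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be > 0")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    @property
    def duration(self) -> float:
        return (self.values.size - 1) / self.fs if self.values.size else 0.0


@dataclass(frozen=True)
class GsrParams:
    slope_thresh: float = 0.05  # uS/s, strict >
    slope_window: float = 3.0   # s (15 samples at 5 Hz)
    level_thresh: float = 0.7   # uS, strict >
    smooth_tau: float = 1.0     # s, exponential smoothing time constant

    def __post_init__(self) -> None:
        for name in ("slope_thresh", "slope_window", "level_thresh", "smooth_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class GsrState:
    """Physiological evidence at one decision tick."""

    slope: float        # uS/s over the trailing slope window
    Sp: int             # 1 iff slope > slope_thresh
    level_flag: int     # 1 iff smoothed level > level_thresh
    Gnorm: float        # min-max normalized smoothed level, clamped to [0, 1]
    level: float = 0.0  # smoothed conductance, uS


@dataclass
class NormalizationContext:
    """Per-user calibration: feature baselines and the GSR min-max range."""

    baseline_mean: dict
    calibration_min: float
    calibration_max: float

    def __post_init__(self) -> None:
        if self.calibration_max <= self.calibration_min:
            raise ValueError("calibration_max must exceed calibration_min")


def resample(raw: pd.DataFrame, fs: float = 5.0) -> GsrSeries:
    """Linearly interpolate raw (t, conductance_uS) samples onto a 1/fs grid.

    The grid spans [first, last] raw timestamp; interpolation of an affine
    signal is exact.
    """
    t = np.asarray(raw["t"], dtype=float)
    v = np.asarray(raw["conductance_uS"], dtype=float)
    if t.size < 2:
        raise ValueError("resample needs at least 2 raw samples")
    n = int(np.floor((t[-1] - t[0]) * fs + 1e-9)) + 1
    grid = t[0] + np.arange(n) / fs
    return GsrSeries(t0=float(t[0]), fs=fs, values=np.interp(grid, t, v))


def smooth(series: GsrSeries, tau: float) -> GsrSeries:
    """First-order exponential smoothing with time constant ``tau`` seconds.

    Discretized as y[i] = y[i-1] + (1 - exp(-dt/tau)) (x[i] - y[i-1]) with
    y[0] = x[0]; a unit step therefore reaches 1 - 1/e of its height exactly
    one tau after the edge.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    alpha = 1.0 - np.exp(-1.0 / (series.fs * tau))
    out = np.empty_like(series.values)
    acc = 0.0
    for i, x in enumerate(series.values):
        acc = x if i == 0 else acc + alpha * (x - acc)
        out[i] = acc
    return replace(series, values=out)


def ols_slope(values: np.ndarray, fs: float) -> float:
    """Least-squares slope of ``values`` against time at sample rate ``fs``."""
    n = values.size
    t = np.arange(n) / fs
    t = t - t.mean()
    return float(t @ (values - values.mean()) / (t @ t))


def slope_flag(series: GsrSeries, params: Optional[GsrParams] = None) -> tuple[float, int]:
    """OLS slope over the trailing slope window and the flag ``Sp``."""
    params = params or GsrParams()
    n = int(round(params.slope_window * series.fs))
    if series.values.size < n:
        raise ValueError(
            f"series ({series.values.size} samples) shorter than slope window ({n})"
        )
    slope = ols_slope(series.values[-n:], series.fs)
    return slope, int(slope > params.slope_thresh)


def level_flag(series: GsrSeries, params: Optional[GsrParams] = None) -> int:
    """1 iff the current (last) value strictly exceeds the level threshold."""
    params = params or GsrParams()
    if not series.values.size:
        raise ValueError("empty series")
    return int(series.values[-1] > params.level_thresh)


def normalize(values: np.ndarray | float, ctx: NormalizationContext) -> np.ndarray | float:
    """Min-max normalization onto [0, 1], clamped."""
    rng = ctx.calibration_max - ctx.calibration_min
    out = np.clip((np.asarray(values, dtype=float) - ctx.calibration_min) / rng, 0.0, 1.0)
    return float(out) if np.isscalar(values) else out


def relative_change(value: float, baseline: float) -> float:
    """Baseline-relative change (value - baseline) / baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return (value - baseline) / baseline


NON_STRESS_CLASSES = ("Negative", "Neutral")


def baseline_from_dataset(
    features: pd.DataFrame,
    feature_cols: tuple[str, ...] = ("gsr_uS", "hesitation_s", "tremble_units"),
    label_col: str = "class_label",
    gsr_col: str = "gsr_uS",
) -> NormalizationContext:
    """Per-feature baseline means over the non-stress (Negative/Neutral) rows.

    The GSR min/max over those rows anchors the min-max calibration range.
    """
    sub = features[features[label_col].isin(NON_STRESS_CLASSES)]
    if not len(sub):
        raise ValueError("no non-stress (Negative/Neutral) rows in feature table")
    means = {c: float(sub[c].mean()) for c in feature_cols if c in sub.columns}
    lo, hi = float(sub[gsr_col].min()), float(sub[gsr_col].max())
    if hi <= lo:  # degenerate single-row calibration: widen symmetrically
        hi = lo + max(0.1, abs(lo) * 0.1)
    return NormalizationContext(baseline_mean=means, calibration_min=lo, calibration_max=hi)
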