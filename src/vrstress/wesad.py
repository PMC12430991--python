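"""Adapter for WESAD-style wearable recordings (wrist EDA + BVP).

Consumes a long-format CSV export (t, channel, value, label) with wrist
electrodermal activity at 4 Hz and blood volume pulse at 64 Hz, keeps only
the baseline (label 1) and stress (label 2) conditions, estimates heart rate
from BVP by beat detection, and classifies each EDA sample with a
baseline-calibrated z-score threshold.  The native dataset container is
converted to this CSV once, outside the library (see README), keeping the
core free of dataset-specific deserialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

BASELINE, STRESS = 1, 2
EDA_FS = 4.0
BVP_FS = 64.0
HR_VALID = (20.0, 250.0)  # bpm


@dataclass
class WearableRecording:
    """Label-filtered wrist recording: EDA samples with aligned labels + BVP."""

    eda_t: np.ndarray       # seconds, one per retained EDA sample
    eda: np.ndarray         # uS
    labels: np.ndarray      # 1 = baseline, 2 = stress, aligned 1:1 with eda
    bvp_t0: float
    bvp_fs: float
    bvp: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.eda_t) == len(self.eda) == len(self.labels)):
            raise ValueError("EDA samples and labels must align 1:1")


@dataclass
class HrSeries:
    """Heart rate resampled to the EDA clock; invalid beats are NaN."""

    t0: float
    fs: float
    values: np.ndarray  # bpm


def load_recording(path: str | Path) -> WearableRecording:
    """Load a long-format CSV (t, channel, value, label) export.

    Each channel is interpolated onto its declared uniform rate (EDA 4 Hz,
    BVP 64 Hz); EDA samples whose label is outside {1, 2} are dropped.
    """
    df = pd.read_csv(path)
    for col in ("t", "channel", "value", "label"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    chans = set(df["channel"])
    for name in ("EDA", "BVP"):
        if name not in chans:
            raise ValueError(f"missing channel {name!r}")

    eda_rows = df[df["channel"] == "EDA"].sort_values("t")
    bvp_rows = df[df["channel"] == "BVP"].sort_values("t")

    def to_grid(rows: pd.DataFrame, fs: float) -> tuple[np.ndarray, np.ndarray]:
        t = rows["t"].to_numpy(dtype=float)
        v = rows["value"].to_numpy(dtype=float)
        n = int(np.floor((t[-1] - t[0]) * fs + 1e-9)) + 1
        grid = t[0] + np.arange(n) / fs
        return grid, np.interp(grid, t, v)

    eda_grid, eda = to_grid(eda_rows, EDA_FS)
    bvp_grid, bvp = to_grid(bvp_rows, BVP_FS)

    # carry each EDA sample's label to its grid point (previous-value hold)
    lab_t = eda_rows["t"].to_numpy(dtype=float)
    lab_v = eda_rows["label"].to_numpy(dtype=float)
    idx = np.clip(np.searchsorted(lab_t, eda_grid, side="right") - 1, 0, lab_t.size - 1)
    labels = lab_v[idx].astype(int)

    keep = np.isin(labels, (BASELINE, STRESS))
    if not keep.any():
        raise ValueError("no samples left after baseline/stress label filtering")
    return WearableRecording(
        eda_t=eda_grid[keep], eda=eda[keep], labels=labels[keep],
        bvp_t0=float(bvp_grid[0]), bvp_fs=BVP_FS, bvp=bvp,
    )


def hr_from_bvp(
    bvp: np.ndarray,
    fs: float = BVP_FS,
    t0: float = 0.0,
    out_fs: float = EDA_FS,
    prominence_scale: float = 0.3,
) -> HrSeries:
    """Estimate heart rate from the BVP waveform by beat detection.

    Peaks are local maxima at least 0.33 s apart with prominence above a
    noise-scaled floor; instantaneous HR is 60 / inter-beat interval,
    interpolated onto a uniform ``out_fs`` grid.  Beats implying a rate
    outside (20, 250) bpm are flagged invalid (NaN).
    """
    bvp = np.asarray(bvp, dtype=float)
    if bvp.size < 10 * fs:
        raise ValueError("need at least 10 s of BVP")
    floor = prominence_scale * float(np.std(bvp))
    peaks, _ = find_peaks(bvp, distance=max(1, int(round(0.33 * fs))), prominence=floor)
    if peaks.size < 2:
        raise ValueError("no heartbeats found in BVP signal")
    t_peaks = t0 + peaks / fs
    ibi = np.diff(t_peaks)
    hr = 60.0 / ibi
    hr = np.where((hr > HR_VALID[0]) & (hr < HR_VALID[1]), hr, np.nan)
    t_hr = 0.5 * (t_peaks[:-1] + t_peaks[1:])

    n = int(np.floor((bvp.size - 1) / fs * out_fs)) + 1
    grid = t0 + np.arange(n) / out_fs
    ok = ~np.isnan(hr)
    if not ok.any():
        raise ValueError("no valid heartbeats in BVP signal")
    values = np.interp(grid, t_hr[ok], hr[ok])
    return HrSeries(t0=t0, fs=out_fs, values=values)


def baseline_calibration(rec: WearableRecording) -> tuple[float, float]:
    """(mean, sd) of EDA over the baseline-labeled samples."""
    base = rec.eda[rec.labels == BASELINE]
    if base.size == 0:
        raise ValueError("empty baseline calibration segment")
    sd = float(np.std(base))
    return float(np.mean(base)), sd if sd > 0 else 1e-9


def classify_recording(
    rec: WearableRecording,
    hr: Optional[HrSeries] = None,
    calibration: Optional[tuple[float, float]] = None,
    threshold_k: float = 1.0,
    w_eda: float = 0.6,
    w_hr: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample stress prediction and continuous score.

    The score is the baseline z-score of EDA; when an HR series is supplied
    it contributes its own baseline z-score with the tier-2 weighting
    (0.6 EDA / 0.4 HR).  A sample is predicted stress when the score exceeds
    ``threshold_k`` baseline standard deviations.
    """
    mean, sd = calibration if calibration is not None else baseline_calibration(rec)
    if sd <= 0:
        raise ValueError("calibration sd must be > 0")
    score = (rec.eda - mean) / sd
    if hr is not None:
        hr_at_eda = np.interp(rec.eda_t, hr.t0 + np.arange(hr.values.size) / hr.fs,
                              hr.values)
        base_hr = hr_at_eda[rec.labels == BASELINE]
        hsd = float(np.std(base_hr)) or 1e-9
        z_hr = (hr_at_eda - float(np.mean(base_hr))) / hsd
        score = w_eda * score + w_hr * z_hr
    pred = np.where(score > threshold_k, STRESS, BASELINE)
    return pred, score
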