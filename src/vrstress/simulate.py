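"""Calibrated synthetic stress sessions and trial-feature tables.

The generator reproduces the statistical structure reported for the
scripted-user study conditions:

* class-conditional marginals of hesitation time, tremble amplitude and GSR
  with the printed per-class medians (and, where feasible, means), modeled
  as normals truncated below at zero;
* strong cross-feature coupling through a single latent arousal factor
  (Gaussian copula), with loadings calibrated so the pooled Pearson
  correlations are 0.94 (GSR-hesitation) and 0.92 (GSR-tremble);
* event-related GSR responses whose onset latency after each stressor is
  uniform in [1, 3] s, with a linear rise and exponential decay;
* four session scenarios (baseline / red light / time pressure / high
  stress, the last combining red light, alarm and time pressure).

A note on the marginal family: a normal truncated below is always
right-skewed, so its mean cannot fall below its median.  The Neutral class
prints mean < median for hesitation and GSR; for those cells the generator
fits the median exactly and uses a symmetric (negligible-truncation) fit at
the default relative scale, accepting a mean bias under 1.5%.  The Neutral
tremble cell (mean > median) is fitted under a scale cap chosen jointly with
the copula loadings so the pooled correlations remain attainable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .session import Session

FEATURES = ("hesitation_s", "tremble_units", "gsr_uS")

#: Printed per-class statistics: feature -> (median, mean or None).
CLASS_STATS = {
    "Negative": {"hesitation_s": (0.99, None), "tremble_units": (0.0060, None),
                 "gsr_uS": (0.62, None)},
    "Neutral": {"hesitation_s": (1.69, 1.68), "tremble_units": (0.0160, 0.0170),
                "gsr_uS": (0.77, 0.76)},
    "Positive": {"hesitation_s": (0.91, None), "tremble_units": (0.0050, None),
                 "gsr_uS": (0.61, None)},
}

CONDITION_CLASS = {
    "baseline": "Negative",
    "red_light": "Neutral",
    "time_pressure": "Neutral",
    "high_stress": "Positive",
}

CONDITION_STRESSORS = {
    "baseline": (),
    "red_light": ("red_light",),
    "time_pressure": ("time_pressure",),
    "high_stress": ("red_light", "alarm", "time_pressure"),
}


@dataclass
class SimConfig:
    """Study conditions of the synthetic generator (defaults are calibrated)."""

    n_per_class: int = 50
    class_stats: dict = field(default_factory=lambda: {c: dict(v) for c, v in CLASS_STATS.items()})
    lower_bound: float = 0.0
    #: default within-class scale as a fraction of the class median
    rel_scale: dict = field(default_factory=lambda: {
        "hesitation_s": 0.06, "tremble_units": 0.30, "gsr_uS": 0.06})
    #: cap on the fitted scale, as a fraction of the median (None = uncapped)
    rel_scale_cap: dict = field(default_factory=lambda: {"tremble_units": 0.30})
    #: latent-arousal loadings; within-pair latent correlation is the product
    loadings: dict = field(default_factory=lambda: {
        "gsr_uS": 0.99, "hesitation_s": 0.8520, "tremble_units": 0.7559})

    # event-related GSR response shape
    scr_latency_range: tuple[float, float] = (1.0, 2.0)  # onset latency, s
    scr_rise_slope: float = 0.35      # minimum rise slope, uS/s
    scr_rise_slope_max: float = 0.5   # maximum rise slope, uS/s
    scr_rise_duration: float = 1.0    # s; onset latency + rise stays within 3 s
    scr_decay_tau: float = 4.0        # s

    # session layout
    motion_fs: float = 90.0
    gsr_fs: float = 5.0
    tremor_freq_range: tuple[float, float] = (4.0, 12.0)
    session_duration: float = 60.0
    trial_period: float = 6.0
    first_prompt: float = 2.0
    gsr_noise_sd: float = 0.01        # uS, tonic noise
    failure_rate: dict = field(default_factory=lambda: {
        "baseline": 0.2, "red_light": 0.8, "time_pressure": 0.8, "high_stress": 1.8})

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        lo, hi = self.scr_latency_range
        if not (1.0 <= lo <= hi <= 3.0):
            raise ValueError("scr_latency_range must lie within [1, 3] s")
        if lo + self.scr_rise_duration > 3.0 or hi + self.scr_rise_duration > 3.0:
            raise ValueError("onset latency + rise must stay within 3 s of onset")
        for r in (self.motion_fs, self.gsr_fs, self.scr_rise_slope, self.scr_decay_tau):
            if r <= 0:
                raise ValueError("rates and time constants must be > 0")


@dataclass
class TrialFeatures:
    """Latent arousal and the three observable features for one trial."""

    class_label: str
    hesitation_s: float
    tremble_units: float
    gsr_uS: float
    arousal: float

    def __post_init__(self) -> None:
        for f in FEATURES:
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


def _truncnorm(loc: float, scale: float, lower: float) -> stats.rv_continuous:
    return stats.truncnorm((lower - loc) / scale, np.inf, loc=loc, scale=scale)


def fit_location_scale(
    median_target: float,
    mean_target: Optional[float],
    lower_bound: float = 0.0,
    scale_hint: Optional[float] = None,
    max_scale: Optional[float] = None,
) -> tuple[float, float]:
    """Fit a lower-truncated normal to a median (and, when feasible, mean).

    When ``mean_target`` exceeds the median, both moments are matched to
    1e-6 by 2-D root finding (subject to ``max_scale``); otherwise the
    median is matched exactly at ``scale_hint`` (the family cannot place the
    mean below the median).  Returns (location, scale).
    """
    if median_target <= lower_bound:
        raise ValueError("median_target must exceed lower_bound")
    if mean_target is not None and mean_target <= lower_bound:
        raise ValueError("mean_target must exceed lower_bound")

    if mean_target is not None and mean_target > median_target:
        def resid(p):
            d = _truncnorm(p[0], np.exp(p[1]), lower_bound)
            return [d.ppf(0.5) - median_target, d.mean() - mean_target]

        sol = optimize.least_squares(
            resid, [median_target, np.log(0.3 * (median_target - lower_bound))],
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        loc, scale = float(sol.x[0]), float(np.exp(sol.x[1]))
        if max(abs(r) for r in resid(sol.x)) > 1e-6 * max(1.0, median_target):
            raise ValueError(
                f"no truncated-normal fit for median={median_target}, mean={mean_target}"
            )
        if max_scale is None or scale <= max_scale:
            return loc, scale
        scale = max_scale  # capped: keep the median exact, mean best-effort

    if scale_hint is None and max_scale is None:
        raise ValueError("scale_hint required for a median-only fit")
    scale = max_scale if mean_target is not None and mean_target > median_target else scale_hint

    def med_err(loc):
        return _truncnorm(loc, scale, lower_bound).ppf(0.5) - median_target

    loc = optimize.brentq(
        med_err, lower_bound - 10 * scale, median_target + 10 * scale, xtol=1e-12
    )
    return float(loc), float(scale)


def fitted_marginals(config: SimConfig) -> dict[str, dict[str, tuple[float, float]]]:
    """(location, scale) of the truncated-normal marginal per class and feature."""
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for cls, feats in config.class_stats.items():
        out[cls] = {}
        for f, (med, mean) in feats.items():
            cap = config.rel_scale_cap.get(f)
            out[cls][f] = fit_location_scale(
                med, mean, config.lower_bound,
                scale_hint=config.rel_scale[f] * (med - config.lower_bound),
                max_scale=None if cap is None else cap * (med - config.lower_bound),
            )
    return out


def sample_trial_features(
    class_label: str,
    rng: np.random.Generator,
    config: Optional[SimConfig] = None,
    n: int = 1,
    marginals: Optional[dict] = None,
) -> list[TrialFeatures]:
    """Draw coupled trial features for one class.

    A latent arousal ``a ~ N(0,1)`` is shared by all three features; feature
    ``i`` observes ``z_i = g_i a + sqrt(1-g_i^2) e_i`` and maps it through
    its class marginal's quantile function, so marginals are exact and the
    latent correlation between features i and j is ``g_i g_j``.
    """
    config = config or SimConfig()
    if class_label not in config.class_stats:
        raise ValueError(f"unknown class {class_label!r}")
    marg = (marginals or fitted_marginals(config))[class_label]
    a = rng.standard_normal(n)
    feats = {}
    for f in FEATURES:
        g = config.loadings[f]
        z = g * a + np.sqrt(1.0 - g * g) * rng.standard_normal(n)
        loc, scale = marg[f]
        feats[f] = _truncnorm(loc, scale, config.lower_bound).ppf(stats.norm.cdf(z))
    return [
        TrialFeatures(
            class_label=class_label,
            hesitation_s=float(feats["hesitation_s"][i]),
            tremble_units=float(feats["tremble_units"][i]),
            gsr_uS=float(feats["gsr_uS"][i]),
            arousal=float(a[i]),
        )
        for i in range(n)
    ]


def _minimum_jerk(u: np.ndarray) -> np.ndarray:
    """Smooth 0->1 reach profile (zero velocity/acceleration at both ends)."""
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def synth_session(
    condition: str,
    rng: np.random.Generator,
    config: Optional[SimConfig] = None,
    session_id: Optional[str] = None,
) -> Session:
    """Generate one full synthetic session for a stress scenario.

    The motion trace is a sequence of smooth reach trajectories plus
    band-limited (4-12 Hz) tremor bursts around stressor onsets; the event
    log realizes the sampled hesitation delays and failure counts; the GSR
    trace is a tonic level plus one event-related response per stressor.
    """
    config = config or SimConfig()
    if condition not in CONDITION_CLASS:
        raise ValueError(f"unknown condition {condition!r}")
    cls = CONDITION_CLASS[condition]
    marginals = fitted_marginals(config)
    dur = config.session_duration

    # stressor schedule: one onset per 10 s slot, kinds cycling per scenario
    kinds = CONDITION_STRESSORS[condition]
    stressor_rows = []
    if kinds:
        onsets = np.arange(8.0, dur - 8.0, 10.0)
        for i, t_on in enumerate(onsets):
            stressor_rows.append(
                {"t_onset": float(t_on), "kind": kinds[i % len(kinds)], "duration": 4.0}
            )
    stressors = pd.DataFrame(stressor_rows, columns=["t_onset", "kind", "duration"])

    # trials
    n_trials = int((dur - config.first_prompt) // config.trial_period)
    feats = sample_trial_features(cls, rng, config, n=n_trials, marginals=marginals)
    lam = config.failure_rate[condition]
    event_rows = []
    for k, tf in enumerate(feats):
        t_p = config.first_prompt + k * config.trial_period
        t_close = t_p + config.trial_period
        task = f"task{k:02d}"
        event_rows.append({"t": t_p, "kind": "prompt", "task_id": task})
        t_act = t_p + tf.hesitation_s
        if t_act >= t_close - 0.6:
            continue  # timeout trial: no action before the window closes
        event_rows.append({"t": t_act, "kind": "action", "task_id": task})
        n_fail = int(rng.poisson(lam))
        t_cur = t_act
        for _ in range(n_fail):
            t_cur += 0.4
            if t_cur >= t_close - 0.2:
                break
            event_rows.append({"t": t_cur, "kind": "failure", "task_id": task})
        if t_cur + 0.4 < t_close - 0.1:
            event_rows.append({"t": t_cur + 0.4, "kind": "success", "task_id": task})
    events = pd.DataFrame(event_rows, columns=["t", "kind", "task_id"])
    events = events.sort_values("t", kind="stable").reset_index(drop=True)

    # motion trace: rest position + per-trial reaches + tremor bursts
    t = np.arange(0.0, dur, 1.0 / config.motion_fs)
    pos = np.tile(np.array([0.30, 1.00, 0.40]), (t.size, 1))
    for k, tf in enumerate(feats):
        t_p = config.first_prompt + k * config.trial_period
        t_act = t_p + tf.hesitation_s
        if t_act >= t_p + config.trial_period - 0.6:
            continue
        m = (t >= t_act) & (t < t_act + 0.8)
        u = (t[m] - t_act) / 0.8
        pos[m, 0] += 0.25 * _minimum_jerk(u)
        pos[m, 2] -= 0.10 * _minimum_jerk(u)
        back = (t >= t_act + 0.8) & (t < t_act + 1.6)
        ub = (t[back] - (t_act + 0.8)) / 0.8
        pos[back, 0] += 0.25 * (1 - _minimum_jerk(ub))
        pos[back, 2] -= 0.10 * (1 - _minimum_jerk(ub))
    # session-level tremble amplitude: mean of the per-trial feature
    tremble_amp = float(np.mean([tf.tremble_units for tf in feats]))
    for row in stressor_rows:
        f_t = rng.uniform(*config.tremor_freq_range)
        phase = rng.uniform(0, 2 * np.pi)
        b0 = row["t_onset"] + 0.3
        m = (t >= b0) & (t < b0 + 2.0)
        burst = tremble_amp * np.sqrt(2.0) * np.sin(2 * np.pi * f_t * (t[m] - b0) + phase)
        env = np.sin(np.pi * (t[m] - b0) / 2.0) ** 2  # smooth on/off
        pos[m, 0] += burst * env
        pos[m, 1] += 0.4 * burst * env
    motion = pd.DataFrame({"t": t, "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2]})

    # GSR trace: tonic level + noise + one SCR per stressor
    tg = np.arange(0.0, dur, 1.0 / config.gsr_fs)
    tonic = float(np.mean([tf.gsr_uS for tf in feats]))
    g = tonic + rng.normal(0.0, config.gsr_noise_sd, tg.size)
    scr_meta = []
    for row in stressor_rows:
        latency = rng.uniform(*config.scr_latency_range)
        slope = rng.uniform(config.scr_rise_slope, config.scr_rise_slope_max)
        t_on = row["t_onset"] + latency
        rise, amp = config.scr_rise_duration, slope * config.scr_rise_duration
        rel = tg - t_on
        shape = np.where(
            rel < 0, 0.0,
            np.where(rel < rise, slope * rel, amp * np.exp(-(rel - rise) / config.scr_decay_tau)),
        )
        g += shape
        scr_meta.append({"stressor_t": row["t_onset"], "scr_onset_latency": latency,
                         "scr_peak_t": t_on + rise, "rise_slope": slope})
    gsr = pd.DataFrame({"t": tg, "conductance_uS": np.maximum(g, 0.0)})

    sess = Session(
        id=session_id or f"{condition}-{rng.integers(1 << 31)}",
        condition=condition,
        class_label=cls,
        motion=motion,
        events=events,
        stressors=stressors,
        gsr=gsr,
    )
    sess.scr_meta = scr_meta  # generation-time ground truth, for validation
    return sess


def simulate_dataset(
    config: Optional[SimConfig] = None,
    seed: int | np.random.Generator = 0,
    with_sessions: bool = True,
) -> tuple[list[Session], pd.DataFrame]:
    """Labeled feature table (n_per_class trials per class) plus, optionally,
    one synthetic session per scenario.

    Deterministic for a given config and seed.
    """
    config = config or SimConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    marginals = fitted_marginals(config)
    rows = []
    for cls in config.class_stats:
        for tf in sample_trial_features(cls, rng, config, n=config.n_per_class,
                                        marginals=marginals):
            rows.append({
                "class_label": cls,
                "hesitation_s": tf.hesitation_s,
                "tremble_units": tf.tremble_units,
                "gsr_uS": tf.gsr_uS,
                "arousal": tf.arousal,
            })
    features = pd.DataFrame(rows)
    sessions = []
    if with_sessions:
        for cond in CONDITION_CLASS:
            sessions.append(synth_session(cond, rng, config, session_id=f"sim-{cond}"))
    return sessions, features
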