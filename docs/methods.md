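# Methods

This note documents the models, numerical choices and known limitations of
`vrstress`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and clock

All traces in a `Session` (controller motion, input events, GSR, stressor
schedule) share one clock in seconds from session start, stored as decimal
values; no cross-stream synchronization model is imposed beyond that. Trials
are half-open windows `[t_prompt, next prompt or session end)`, which makes
event-to-trial assignment unambiguous and conserves failure events (each is
counted in exactly one trial). A trial with an action but no terminal
success/failure event is scored a success; a trial with no action at all is
a timeout, and its hesitation delay is defined as the full trial duration so
the indicator is never unbounded or undefined. CSV bundles use comma
separators, a header row, UTF-8 and "." decimals; floats are written at full
precision so read∘write is the identity.

## Behavioral indicators

* **Hesitation** and **inactivity** thresholds are applied strictly
  (`> 2 s`, `> 3 s`); the repeated-error rule is inclusive (`≥ 2`). Where
  the source material states both strict and non-strict forms, the strict
  form from the algorithm definition is adopted everywhere and surfaced in
  `BehaviorThresholds`.
* **Inactivity** marks a time "active" when an input event occurs or the
  finite-difference controller speed exceeds `motion_eps` (1e-4 units/s);
  the reported gap is the largest spacing between consecutive active times,
  bounded by the window edges. The flag is monotone in gap length.
* **Tremor**: no high-pass filter is prescribed by the rule set, so jitter
  is isolated as position minus its centered moving average over 0.5 s
  (window forced odd, shrinking at the edges). This passes physiological
  tremor (4–12 Hz, attenuation < 10% above ~3 Hz at 90 Hz sampling) while
  removing voluntary reach motion, and is exactly zero on a constant trace.
  RMS is taken on the Euclidean magnitude of the three jitter axes.
  Dominant frequency is the zero-crossing rate of the first jitter axis
  divided by two — O(n), adequate for the tier-1 frequency test (threshold
  30 Hz), and directly checkable against a sinusoid.

## GSR processing

The raw trace is linearly interpolated onto a uniform 5 Hz grid, then
smoothed with a first-order exponential filter (τ = 1 s, discretized as
`y += (1 − e^(−dt/τ))(x − y)`), chosen because it is causal
(streaming-compatible), has one parameter, and has closed-form test
responses (a unit step reaches 1 − 1/e one τ after the edge). "Steep rise
within 3 s" is read as an ordinary-least-squares slope over the trailing
3 s (15 samples), evaluated at every tick — more robust to single-sample
noise than a two-point difference, and oracle-checkable against the
closed-form covariance formula. All GSR thresholds are strict.

The slope flag `Sp` is invariant to constant offsets of the whole series;
the 0.7 μS level flag is not — both properties are tested. `Sp` (the slope)
feeds the fused score `Sf`; the 0.7 μS level test lives in tier 1 and in
the tier-3 quiet test. The source rules never state which of the two feeds
`Sf`; this assignment keeps the rise detector (a change signal) in the
score and the absolute level (a state signal) in the immediate-alert path.

`Gnorm` is min–max normalization, clamped to [0, 1]. In online detection
the range is calibrated from the first 5 s of the session's smoothed GSR,
with a floor of 0.2 μS on the span so that a flat calibration segment
cannot blow noise up to full scale. Baseline-relative feature changes use
`(value − baseline)/baseline` with baselines averaged over the non-stress
(Negative and Neutral) classes.

## Fusion and the tier policy

`Sf = α·Sb + β·Sp` with α = 1, β = 1.5 and an inclusive trigger at 3; by
enumeration of all ten (Sb, Sp) pairs the stress set is exactly
`{Sb ≥ 3} ∪ {Sb = 2 ∧ Sp = 1}`. `B = Sb/4` maps the 0–4 score onto [0, 1]
(the normalization is otherwise unspecified). The tier-1 condition "tremor
RMS > 30 Hz" is dimensionally inconsistent as printed (an RMS is an
amplitude); it is implemented as dominant tremor *frequency* > 30 Hz — the
only reading in hertz — with the threshold exposed in `FusionParams`.
Tier 3 is entered only when every indicator is quiet (Sb = 0, Sp = 0,
level flag 0); otherwise tier 2 computes `S = 0.6B + 0.4·Gnorm` (or
`S = B` in behavior-only mode) and alerts strictly above 0.65. Alerts are
monotone: raising any flag never cancels an alert.

Decisions are emitted once per GSR tick (5 Hz, the slowest mandatory
clock), starting after the 5 s calibration segment; in behavior-only mode,
once per trial close. The streaming detector keeps a 12 s trailing buffer,
so per-sample work is bounded; batch detection feeds the same state
machine, and a dedicated test verifies that arbitrary chunking of the feed
reproduces the batch decision sequence exactly.

## Three-class rule

The "interpretable thresholds" classifier is realized as the minimal
interpretable rule consistent with the published class statistics: nearest
centroid with centroids at the per-class medians of (hesitation, tremble,
GSR) and per-feature scales equal to the inter-class median range; exact
ties resolve to Neutral. Its continuous per-class score (negative scaled
distance) is what the one-vs-rest ROC ranks; for binary stress ROC the
natural ranking score is `Sf`.

## Simulator calibration

Class-conditional marginals are normals truncated below at zero. A
lower-truncated normal is necessarily right-skewed (mean ≥ median), so the
Neutral hesitation and GSR targets (mean 0.6–1.3% *below* the median)
cannot be matched exactly by this family — nor, with useful within-class
variance, can the Neutral tremble mean (6.3% above the median, which would
force a scale of ~78% of the median). The generator therefore fits every
median exactly and treats the mean as best-effort: within-class scales
default to 6% of the class median for hesitation and GSR and 30% for
tremble, giving mean biases ≤ 1.3% (hesitation, GSR) and −5.8% (Neutral
tremble). Medians are the calibrated, tested quantities.

Cross-feature coupling uses a one-factor Gaussian copula: a latent arousal
`a ~ N(0,1)` per trial, observed by feature *i* as
`z_i = g_i·a + √(1−g_i²)·ε_i` and mapped through the class marginal's
quantile function, so marginals are exact and the latent correlation of a
pair is `g_i·g_j`. Because the three class centers are almost collinear
(between-class correlation ≈ 0.999 for both pairs), the pooled Pearson r is
set jointly by the within-class scales and the loadings; with the scales
above, the loadings (g = 0.99 for GSR, 0.8520 for hesitation, 0.7559 for
tremble) were solved numerically so the large-n pooled correlations equal
0.94 (GSR–hesitation) and 0.92 (GSR–tremble). At the default 50 trials per
class the Monte-Carlo spread of the pooled r is about ±0.01.

Sessions realize the features physically: prompts every 6 s with actions
delayed by the sampled hesitation; Poisson failure counts
(condition-dependent rates 0.2–1.8); minimum-jerk reach trajectories at
90 Hz plus 2 s band-limited (4–12 Hz) tremor bursts after each stressor
with amplitude from the sampled tremble feature; GSR as tonic level (the
class GSR feature) plus Gaussian noise (SD 0.01 μS) and one event-related
response per stressor — onset latency uniform in [1, 2] s, linear rise for
1 s at 0.35–0.5 μS/s, exponential decay with τ = 4 s — so both onset and
peak fall 1–3 s after the stressor, every rise is steep enough for the
slope detector, and the baseline scenario (no stressors) never fires it
(its OLS slope noise SD is ~0.003 μS/s against the 0.05 threshold).
Scenario-to-class mapping (baseline→Negative, red light/time
pressure→Neutral, high stress→Positive) is bookkeeping only; class labels
are opaque categories carrying the printed statistics, with no valence
interpretation imposed (the source statistics themselves make Neutral the
most extreme class, unexplained there and simply copied here).

What the generator does **not** emulate: motion-tracking dropouts and
artifacts, non-stationary tonic EDA drift, habituation across repeated
stressors, and individual-difference distributions. Passing tests
demonstrate that the pipeline is correct under the calibrated statistical
structure, not that the thresholds generalize to human data.

## Wearable adapter

The long-format CSV contract (t, channel, value, label) keeps the library
free of dataset-specific deserialization; channels are interpolated onto
their declared rates (EDA 4 Hz, BVP 64 Hz) and samples labeled outside
{1, 2} are dropped. Heart rate comes from BVP peak detection (minimum
inter-peak interval 0.33 s, prominence ≥ 0.3 SD of the signal); beats
implying rates outside (20, 250) bpm are flagged invalid. Classification is
a baseline z-score threshold on EDA (default k = 1.0 baseline SDs, exposed
in config) with an optional HR z-score fused at the tier-2 weighting
(0.6/0.4); EDA-only is the default since EDA is the clearer stress signal.
No train/test split is defined for the threshold — it is calibrated on the
recording's own baseline segment, exactly as under-specified in the
original recipe, and reproducing any particular published subject's numbers
is an optional external experiment requiring that dataset.

## Problem sizes and tolerances

The default test run simulates sessions of 20–60 s and datasets of 150–1200
trials; the acceptance script uses 200 trials per class for median recovery
and the default 150-trial dataset for correlations. Tolerances in tests:
±5% on sample medians at n = 200/class, ±0.03 on pooled correlations,
1e-12 for the AUC/Mann–Whitney identity, 1e-9 for brute-force numerical
oracles (tremor RMS, OLS slope).

## Known limitations

* The evaluation of behavioral flags at a decision tick uses the most
  recently *closed* trial for hesitation/errors, so those two indicators
  update with one-trial latency; inactivity and tremor are current.
* The nearest-centroid rule cannot separate classes whose printed medians
  nearly coincide (Negative vs Positive), capping three-class accuracy on
  synthetic data around 0.7–0.8.
* Exponential smoothing is not a zero-phase filter; the slope detector
  inherits a small lag (≈ τ) relative to the raw signal.
* The simulator's SCR shape (linear rise, exponential decay) is a
  first-order idealization of real skin-conductance responses.
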