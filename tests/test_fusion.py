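"""Fusion rules: Sf, the tier policy, the 3-class rule, streaming equivalence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from vrstress import (
    BehavioralIndicators,
    ClassCentroids,
    FusionParams,
    GsrState,
    StreamDetector,
    classify3,
    centroid_scores,
    continuous_score,
    detect_session,
    fuse,
    normalized_behavior,
    tier_decision,
)
from vrstress.fusion import CLASS_MEDIANS, decisions_frame
from vrstress.simulate import SimConfig, synth_session

FP = FusionParams()


def indicators(h=0, e=0, i=0, t=0, freq=0.0):
    return BehavioralIndicators(
        hesitation_delay=0.0, hesitation_flag=h, failure_count=2 * e, error_flag=e,
        max_inactivity_gap=0.0, inactivity_flag=i, tremor_rms=0.0,
        tremor_freq=freq, tremor_flag=t,
    )


def gsr_state(Sp=0, level=0.5, gnorm=0.0):
    return GsrState(slope=0.1 * Sp, Sp=Sp, level_flag=int(level > 0.7),
                    Gnorm=gnorm, level=level)


class TestFuse:
    def test_exhaustive_enumeration_matches_bruteforce(self):
        """All 10 (Sb, Sp) pairs against a brute-force evaluation of the rule.

        With alpha=1, beta=1.5, trigger 3 the stress set is exactly
        {Sb>=3} union {Sb==2 and Sp==1}.
        """
        for Sb, Sp in itertools.product(range(5), range(2)):
            Sf, stress = fuse(Sb, Sp, FP)
            assert Sf == pytest.approx(1.0 * Sb + 1.5 * Sp)
            assert stress == (1.0 * Sb + 1.5 * Sp >= 3.0)
            assert stress == (Sb >= 3 or (Sb == 2 and Sp == 1))

    @pytest.mark.parametrize("Sb, Sp, sf, stress", [
        (2, 1, 3.5, True), (2, 0, 2.0, False), (3, 0, 3.0, True),
    ])
    def test_examples(self, Sb, Sp, sf, stress):
        assert fuse(Sb, Sp, FP) == (pytest.approx(sf), stress)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fuse(5, 0, FP)
        with pytest.raises(ValueError):
            fuse(2, 2, FP)

    def test_monotone_in_sb_and_sp(self):
        for Sb, Sp in itertools.product(range(5), range(2)):
            _, stress = fuse(Sb, Sp, FP)
            if Sb < 4:
                assert fuse(Sb + 1, Sp, FP)[1] >= stress
            if Sp < 1:
                assert fuse(Sb, Sp + 1, FP)[1] >= stress


@pytest.mark.parametrize("sb, b", [(4, 1.0), (0, 0.0), (2, 0.5)])
def test_normalized_behavior(sb, b):
    assert normalized_behavior(sb) == pytest.approx(b)


class TestTierDecision:
    def test_gsr_level_triggers_tier1(self):
        d = tier_decision(indicators(), gsr_state(level=0.75), FP)
        assert d.tier == 1 and d.stress

    def test_tremor_frequency_triggers_tier1(self):
        d = tier_decision(indicators(freq=35.0), None, FP)
        assert d.tier == 1 and d.stress

    def test_full_evidence_alerts_in_tier2(self):
        d = tier_decision(indicators(1, 1, 1, 1), gsr_state(gnorm=1.0, level=0.6), FP)
        assert d.tier == 2
        assert d.S == pytest.approx(1.0)
        assert d.stress

    def test_half_evidence_stays_silent(self):
        d = tier_decision(indicators(1, 1, 0, 0), gsr_state(gnorm=0.5, level=0.6), FP)
        assert d.S == pytest.approx(0.5)
        assert not d.stress

    def test_all_quiet_is_tier3(self):
        d = tier_decision(indicators(), gsr_state(), FP)
        assert d.tier == 3 and not d.stress

    def test_behavior_only_uses_b_alone(self):
        d = tier_decision(indicators(1, 1, 1, 0), None, FP)
        assert d.S == pytest.approx(0.75)
        assert d.stress  # 0.75 > 0.65

    def test_alerts_monotone_in_flags(self):
        """Raising any indicator or Sp never turns an alert off."""
        combos = list(itertools.product(range(2), repeat=4))
        for flags in combos:
            for sp in (0, 1):
                base = tier_decision(indicators(*flags), gsr_state(Sp=sp, gnorm=0.6), FP)
                for j in range(4):
                    if flags[j] == 1:
                        continue
                    raised = list(flags)
                    raised[j] = 1
                    up = tier_decision(indicators(*raised), gsr_state(Sp=sp, gnorm=0.6), FP)
                    assert up.stress >= base.stress
                up_sp = tier_decision(indicators(*flags), gsr_state(Sp=1, gnorm=0.6), FP)
                assert up_sp.stress >= base.stress


class TestClassify3:
    @pytest.mark.parametrize("cls", list(CLASS_MEDIANS))
    def test_centroid_maps_to_own_class(self, cls):
        assert classify3(CLASS_MEDIANS[cls]) == cls

    def test_zero_distance_property_random_centroids(self, rng):
        for _ in range(10):
            cen = ClassCentroids(centroids={
                c: tuple(rng.uniform(0.1, 2.0, 3)) for c in CLASS_MEDIANS
            })
            for c, point in cen.centroids.items():
                assert classify3(point, cen) == c

    def test_tie_goes_to_neutral(self):
        cen = ClassCentroids(
            centroids={"Negative": (0.0, 0.0, 0.0), "Neutral": (2.0, 0.0, 0.0),
                       "Positive": (4.0, 0.0, 0.0)},
            scales=(1.0, 1.0, 1.0),
        )
        # equidistant from Negative and Neutral, farther from Positive
        assert classify3((1.0, 0.0, 0.0), cen) == "Neutral"

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify3((np.nan, 0.01, 0.6))

    def test_scores_are_negative_scaled_distances(self):
        s = centroid_scores((0.99, 0.0060, 0.62))
        assert s["Negative"] == pytest.approx(0.0, abs=1e-12)
        assert all(v <= 0 for v in s.values())


class TestStreaming:
    @pytest.mark.parametrize("condition", ["baseline", "high_stress"])
    def test_chunked_feed_matches_batch(self, condition, rng):
        """Online decisions are identical however the feed is chunked."""
        sess = synth_session(condition, rng, SimConfig(session_duration=30.0))
        batch = detect_session(sess)

        det = StreamDetector(has_gsr=True)
        for lo in np.arange(0.0, 31.0, 3.7):
            hi = lo + 3.7
            m = sess.motion[(sess.motion["t"] >= lo) & (sess.motion["t"] < hi)]
            e = sess.events[(sess.events["t"] >= lo) & (sess.events["t"] < hi)]
            g = sess.gsr[(sess.gsr["t"] >= lo) & (sess.gsr["t"] < hi)]
            det.update(motion=m, events=e, gsr=g)
        det.finalize(sess.t_end)
        streamed = decisions_frame(det.decisions, det.fusion_params)
        pd.testing.assert_frame_equal(streamed, batch)

    def test_empty_update_emits_nothing(self):
        det = StreamDetector()
        assert det.update() == []

    def test_out_of_order_sample_rejected(self):
        det = StreamDetector()
        det.update(motion=pd.DataFrame({"t": [1.0], "x": [0], "y": [0], "z": [0]}))
        with pytest.raises(ValueError, match="out-of-order"):
            det.update(motion=pd.DataFrame({"t": [0.5], "x": [0], "y": [0], "z": [0]}))


class TestContinuousScore:
    def test_quiet_session_scores_zero(self, quiet_session):
        scores = continuous_score(quiet_session)
        assert len(scores)
        assert (scores["Sf"] <= 1.0).all()  # at most stray inactivity flags

    def test_stress_session_reaches_high_scores(self, rng):
        sess = synth_session("high_stress", rng, SimConfig(session_duration=40.0))
        scores = continuous_score(sess)
        assert scores["Sf"].max() >= 2.5
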