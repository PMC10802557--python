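import numpy as np
import pytest

from baitswitch.data_model import BehaviorEvent
from baitswitch.interactions import SocialInteraction
from baitswitch.sequences import (
    TriggeredSequence,
    difference_index,
    extract_triggered_sequences,
    hourly_profile,
    permute_identity,
    subsample_control_triggers,
    subsample_index_distribution,
)
from conftest import make_recording

FPS = 30


def _si(start_s, end_s, male="M2", female="F1"):
    a, b = sorted([male, female])
    return SocialInteraction(a, b, int(start_s * FPS), int(end_s * FPS) - 1, male)


def _base_rec(events, n_frames):
    pos = {
        "M1": np.tile([15.0, 15.0], (n_frames, 1)),
        "M2": np.tile([60.0, 15.0], (n_frames, 1)),
        "F1": np.tile([15.0, 60.0], (n_frames, 1)),
        "F2": np.tile([60.0, 60.0], (n_frames, 1)),
    }
    return make_recording(pos, events=events)


class TestExtraction:
    def test_positive_latency(self):
        # chase ends at t=10.00 s, interaction starts at 11.17 s
        trig = BehaviorEvent("chase", "M1", "M2", 5 * FPS, 10 * FPS - 1)
        rec = _base_rec([trig], 20 * FPS)
        seqs = extract_triggered_sequences(rec, [_si(11.17, 12.0)], "aggression")
        assert len(seqs) == 1
        s = seqs[0]
        assert s.latency_s == pytest.approx(1.17, abs=1 / FPS)
        assert s.male_state == "aggressed"  # M2 was chased
        assert s.male_partner_id == "M2"

    def test_negative_latency_included(self):
        # interaction starts at 9.77 s while the trigger runs until 10.00 s
        trig = BehaviorEvent("chase", "M1", "M2", 5 * FPS, 10 * FPS - 1)
        rec = _base_rec([trig], 20 * FPS)
        seqs = extract_triggered_sequences(rec, [_si(9.77, 10.5)], "aggression")
        assert len(seqs) == 1
        assert seqs[0].latency_s == pytest.approx(-0.23, abs=1 / FPS)

    def test_si_before_trigger_start_excluded(self):
        trig = BehaviorEvent("chase", "M1", "M2", 5 * FPS, 10 * FPS - 1)
        rec = _base_rec([trig], 20 * FPS)
        assert extract_triggered_sequences(rec, [_si(2.0, 4.0)], "aggression") == []

    def test_window_closed_by_next_trigger(self):
        t1 = BehaviorEvent("chase", "M1", "M2", 0, 2 * FPS - 1)
        t2 = BehaviorEvent("flee", "M2", "M1", 10 * FPS, 12 * FPS - 1)
        rec = _base_rec([t1, t2], 30 * FPS)
        # the only interaction falls after t2's start, so t1 gets nothing
        seqs = extract_triggered_sequences(rec, [_si(13.0, 14.0)], "aggression")
        assert len(seqs) == 1
        assert seqs[0].trigger is t2

    def test_first_only_vs_all(self):
        trig = BehaviorEvent("chase", "M1", "M2", 0, 2 * FPS - 1)
        rec = _base_rec([trig], 40 * FPS)
        sis = [_si(3.0, 4.0), _si(6.0, 7.0)]
        assert len(extract_triggered_sequences(rec, sis, "aggression")) == 1
        assert len(
            extract_triggered_sequences(rec, sis, "aggression", pair_with="all")
        ) == 2

    def test_walking_states(self):
        trig = BehaviorEvent("walk", "M1", None, 0, 2 * FPS - 1)
        rec = _base_rec([trig], 20 * FPS)
        seqs = extract_triggered_sequences(rec, [_si(3.0, 4.0, male="M2")], "walking")
        assert seqs[0].male_state == "non_walker"
        seqs = extract_triggered_sequences(rec, [_si(3.0, 4.0, male="M1")], "walking")
        assert seqs[0].male_state == "walker"


class TestSubsample:
    def _events(self, n_walk):
        return [
            BehaviorEvent("walk", "M1", None, 10 * i, 10 * i + 5) for i in range(n_walk)
        ]

    def test_subset_size_and_determinism(self):
        events = self._events(500)
        out1 = subsample_control_triggers(events, "walking", 310, seed=7)
        out2 = subsample_control_triggers(events, "walking", 310, seed=7)
        assert len(out1) == 310
        assert out1 == out2
        assert len(set(id(e) for e in out1)) == 310

    def test_pool_smaller_than_target_returns_all(self, caplog):
        events = self._events(5)
        with caplog.at_level("WARNING"):
            out = subsample_control_triggers(events, "walking", 10, seed=0)
        assert len(out) == 5
        assert any("only 5 available" in r.message for r in caplog.records)


class TestDifferenceIndex:
    @pytest.mark.parametrize("a,b,v", [(10, 10, 0.0), (0, 50, -1.0), (3, 5, -0.25)])
    def test_values(self, a, b, v):
        assert difference_index(a, b).value == pytest.approx(v)

    def test_undefined(self):
        with pytest.raises(ValueError):
            difference_index(0, 0)


def _toy_sequences(n_aggressor, n_aggressed):
    trig = BehaviorEvent("chase", "M1", "M2", 0, 10)
    si = SocialInteraction("F1", "M2", 20, 40, "M2")
    out = []
    for i in range(n_aggressor):
        out.append(TriggeredSequence(trig, "aggression", si, "M1", "F1",
                                     "aggressor", 1.0, 0.7))
    for i in range(n_aggressed):
        out.append(TriggeredSequence(trig, "aggression", si, "M2", "F1",
                                     "aggressed", 0.5, 0.8))
    return out


class TestPermutation:
    def test_forced_all_aggressed(self):
        res = permute_identity(_toy_sequences(0, 40), n_permutations=1000, seed=0)
        assert res.actual_value == -1.0
        assert abs(res.null_mean) < 0.1
        assert res.z < -4

    def test_null_mean_converges_to_zero(self):
        res = permute_identity(_toy_sequences(20, 20), n_permutations=10_000, seed=1)
        # null index mean has sd 1/sqrt(n) per draw; 3 SE of the mean
        se = (1 / np.sqrt(40)) / np.sqrt(10_000)
        assert abs(res.null_mean) < 3 * se

    def test_whole_recording_scheme(self):
        res = permute_identity(
            _toy_sequences(10, 30), scheme="whole_recording", seed=0
        )
        assert set(np.round(res.null_values, 6)) <= {-0.5, 0.5}


class TestSubsampleDistribution:
    def test_forced_all_aggressed(self):
        seqs = {"rec1": _toy_sequences(0, 64)}
        res = subsample_index_distribution(seqs, k=50, n_repeats=200, seed=0)
        assert np.all(res.indices == -1.0)
        assert res.frac_below_zero == 1.0

    def test_recording_below_k_errors(self):
        with pytest.raises(ValueError, match="rec1"):
            subsample_index_distribution({"rec1": _toy_sequences(5, 5)}, k=50)

    def test_null_distribution_straddles_zero(self):
        seqs = {"a": _toy_sequences(40, 40), "b": _toy_sequences(35, 35)}
        res = subsample_index_distribution(seqs, k=50, n_repeats=500, seed=2)
        assert abs(res.z) < 3


class TestHourlyProfile:
    def test_boundary_binning(self):
        dur = 5 * 3600.0
        t1 = BehaviorEvent("chase", "M1", "M2", int(59.9 * 60 * FPS), int(59.9 * 60 * FPS) + 10)
        t2 = BehaviorEvent("chase", "M1", "M2", int(60.1 * 60 * FPS), int(60.1 * 60 * FPS) + 10)
        si = SocialInteraction("F1", "M2", 0, 20, "M2")
        seqs = [
            TriggeredSequence(t1, "aggression", si, "M2", "F1", "aggressed", 1.0, 0.7),
            TriggeredSequence(t2, "aggression", si, "M1", "F1", "aggressor", 1.0, 0.7),
        ]
        prof = hourly_profile(seqs, dur, FPS, n_bins=5)
        assert prof.loc[0, "n_aggressed"] == 1
        assert prof.loc[1, "n_aggressor"] == 1

    def test_all_one_state(self):
        dur = 5 * 3600.0
        seqs = []
        for h in range(5):
            t = BehaviorEvent("chase", "M1", "M2", int((h + 0.5) * 3600 * FPS), int((h + 0.5) * 3600 * FPS) + 10)
            si = SocialInteraction("F1", "M2", 0, 20, "M2")
            seqs.append(
                TriggeredSequence(t, "aggression", si, "M2", "F1", "aggressed", 1.0, 0.7)
            )
        prof = hourly_profile(seqs, dur, FPS, n_bins=5)
        assert (prof["pct_aggressed"] == 100.0).all()
        assert (prof["pct_aggressor"] == 0.0).all()

    def test_trigger_beyond_duration_errors(self):
        t = BehaviorEvent("chase", "M1", "M2", 100 * FPS, 101 * FPS)
        si = SocialInteraction("F1", "M2", 0, 20, "M2")
        seqs = [TriggeredSequence(t, "aggression", si, "M2", "F1", "aggressed", 1.0, 0.7)]
        with pytest.raises(ValueError):
            hourly_profile(seqs, 50.0, FPS)
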