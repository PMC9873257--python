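import numpy as np
import pandas as pd
import pytest

from bittercircuit.exceptions import InvalidParameterError, ProtocolError
from bittercircuit.feeding import segment_sips
from bittercircuit.locomotor import Epoch, StimulusProtocol
from bittercircuit.synthetic import (
    ArenaSimParams,
    CalciumSimParams,
    CircuitSimParams,
    FeedingSimParams,
    generate_arena_trial,
    generate_calcium_trial,
    generate_circuit,
    generate_feeding_session,
)


def light_protocol():
    return StimulusProtocol([Epoch(start=6.0, end=11.0, kind="light")])


class TestDeterminism:
    def test_arena_bitwise_reproducible(self):
        params = ArenaSimParams(n_flies=4, seed=42)
        a, _ = generate_arena_trial(params, light_protocol())
        b, _ = generate_arena_trial(params, light_protocol())
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x, tb.x)
            np.testing.assert_array_equal(ta.forward_velocity, tb.forward_velocity)

    def test_feeding_bitwise_reproducible(self):
        params = FeedingSimParams(session_length=600.0, seed=42)
        a, _ = generate_feeding_session(params)
        b, _ = generate_feeding_session(params)
        pd.testing.assert_frame_equal(a.interactions, b.interactions)

    def test_calcium_bitwise_reproducible(self):
        params = CalciumSimParams(seed=42)
        a, _ = generate_calcium_trial(params, n_trials=2)
        b, _ = generate_calcium_trial(params, n_trials=2)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.f, tb.f)

    def test_circuit_bitwise_reproducible(self):
        params = CircuitSimParams(seed=42)
        a, _ = generate_circuit(params)
        b, _ = generate_circuit(params)
        assert a == b

    def test_different_seeds_differ(self):
        a, _ = generate_feeding_session(FeedingSimParams(session_length=600.0, seed=1))
        b, _ = generate_feeding_session(FeedingSimParams(session_length=600.0, seed=2))
        assert not a.interactions.equals(b.interactions)


class TestArenaGenerator:
    def test_null_parameters_give_constant_speed(self):
        params = ArenaSimParams(
            n_flies=3,
            onset_speed_boost=0.0,
            onset_turn_boost=0.0,
            light_attraction=0.0,
            noise_sd=0.0,
            angular_noise_sd=0.0,
            offset_freeze_prob=0.0,
            seed=0,
        )
        trajs, _ = generate_arena_trial(params, light_protocol())
        for t in trajs:
            np.testing.assert_allclose(t.forward_velocity, params.baseline_speed)

    def test_boost_applied_during_light(self):
        params = ArenaSimParams(
            n_flies=6, noise_sd=0.0, angular_noise_sd=0.0, offset_freeze_prob=0.0, seed=0
        )
        trajs, truth = generate_arena_trial(params, light_protocol())
        fr = int(params.frame_rate)
        during = np.mean([t.forward_velocity[6 * fr : 11 * fr] for t in trajs])
        before = np.mean([t.forward_velocity[: 6 * fr] for t in trajs])
        assert during - before == pytest.approx(truth["onset_speed_boost"])

    def test_positions_stay_inside_arena(self):
        trajs, _ = generate_arena_trial(ArenaSimParams(n_flies=8, seed=3), light_protocol())
        for t in trajs:
            assert np.all(np.hypot(t.x, t.y) <= t.arena_radius + 1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            ArenaSimParams(frame_rate=0.0)
        with pytest.raises(InvalidParameterError):
            ArenaSimParams(offset_freeze_prob=1.5)
        with pytest.raises(InvalidParameterError):
            ArenaSimParams(n_flies=0)

    def test_protocol_beyond_session_rejected(self):
        with pytest.raises(ProtocolError):
            generate_arena_trial(ArenaSimParams(), light_protocol(), session_length=5.0)


class TestFeedingGenerator:
    def test_hierarchy_every_sip_in_one_burst_one_bout(self):
        events, truth = generate_feeding_session(
            FeedingSimParams(opto_suppression_factor=1.0, seed=5)
        )
        seg = segment_sips(
            events,
            intra_burst_gap=truth["burst_gap_threshold"],
            inter_bout_gap=truth["bout_gap_threshold"],
        )
        for ch in events.channels:
            sips = seg.per_channel[ch].sips
            assert sips.groupby("burst_id")["bout_id"].nunique().le(1).all()

    def test_segmentation_recovers_planted_counts(self):
        events, truth = generate_feeding_session(
            FeedingSimParams(opto_suppression_factor=1.0, seed=6)
        )
        seg = segment_sips(events)
        ch = seg.per_channel["control"]
        assert (ch.n_sips, ch.n_bursts, ch.n_bouts) == tuple(
            truth["control_counts"][k] for k in ("n_sips", "n_bursts", "n_bouts")
        )

    def test_full_suppression_leaves_only_first_contact(self):
        events, _ = generate_feeding_session(
            FeedingSimParams(opto_suppression_factor=0.0, seed=7)
        )
        assert len(events.on_channel("opto")) == 1

    def test_null_factor_gives_comparable_channels(self):
        events, _ = generate_feeding_session(
            FeedingSimParams(opto_suppression_factor=1.0, seed=8)
        )
        totals = {
            ch: (events.on_channel(ch)["end"] - events.on_channel(ch)["start"]).sum()
            for ch in events.channels
        }
        assert 0.6 < totals["opto"] / totals["control"] < 1.4

    def test_closed_loop_epochs_cover_stim_interactions(self):
        events, _ = generate_feeding_session(FeedingSimParams(seed=9))
        starts = events.on_channel("opto")["start"]
        for s in starts:
            assert any(lo <= s < hi for lo, hi in events.light_epochs)

    def test_unordered_interval_means_rejected(self):
        with pytest.raises(InvalidParameterError):
            FeedingSimParams(
                intra_burst_interval_mean=5.0,
                inter_burst_interval_mean=1.0,
                inter_bout_interval_mean=60.0,
            )


class TestCalciumGenerator:
    def test_zero_amplitudes_give_flat_dff(self):
        from bittercircuit.calcium import dff

        traces, _ = generate_calcium_trial(
            CalciumSimParams(on_amplitude=0.0, off_amplitude=0.0, noise_sd=0.0, seed=0),
            n_trials=2,
        )
        for t in traces:
            np.testing.assert_allclose(dff(t), 0.0, atol=1e-12)

    def test_planted_peak_in_stimulus_window(self):
        from bittercircuit.calcium import dff

        traces, _ = generate_calcium_trial(
            CalciumSimParams(on_amplitude=0.7, noise_sd=0.0, seed=0), n_trials=1
        )
        t = traces[0]
        d = dff(t)
        assert d[t.stim_onset_frame : t.stim_offset_frame].max() == pytest.approx(0.7)

    def test_baseline_frame_requirement_enforced(self):
        with pytest.raises(InvalidParameterError):
            generate_calcium_trial(CalciumSimParams(seed=0), n_trials=1, stim_onset=1.0)

    def test_invalid_habituation_factor_rejected(self):
        with pytest.raises(InvalidParameterError):
            CalciumSimParams(habituation_factor_on=0.0)


class TestCircuitGenerator:
    def test_planted_memberships_recovered(self):
        from bittercircuit.connectome import downstream_layer

        graph, truth = generate_circuit(CircuitSimParams(seed=11))
        l2 = downstream_layer(graph, truth["seed_ids"], edge_min=3)
        assert l2.member_ids - truth["seed_ids"] == truth["layer2_members"]
        l3 = downstream_layer(graph, truth["layer2_members"], edge_min=3)
        assert l3.member_ids == truth["layer3_members"]

    def test_planted_motif_recovered(self):
        from bittercircuit.connectome import interconnection_matrix

        graph, truth = generate_circuit(CircuitSimParams(seed=12))
        matrix = interconnection_matrix(graph, cells=truth["seed_ids"], edge_min=5)
        pd.testing.assert_frame_equal(matrix, truth["motif_matrix"], check_names=False)

    def test_zero_feedback_fraction_gives_no_feedback(self):
        from bittercircuit.connectome import downstream_layer, feedback_detect

        graph, truth = generate_circuit(CircuitSimParams(feedback_fraction=0.0, seed=13))
        l4 = downstream_layer(graph, truth["layer3_members"], edge_min=3)
        assert feedback_detect(l4, truth["seed_ids"]) == {}

    def test_feedback_targets_recovered(self):
        from bittercircuit.connectome import downstream_layer, feedback_detect

        graph, truth = generate_circuit(CircuitSimParams(feedback_fraction=0.3, seed=14))
        l4 = downstream_layer(graph, truth["layer3_members"], edge_min=3)
        assert set(feedback_detect(l4, truth["seed_ids"])) == truth["feedback_targets"]

    def test_mismatched_subtype_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            CircuitSimParams(seed_subtypes=(("A", 3),), n_seed=5)
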