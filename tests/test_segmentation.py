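"""Sliding windows, template recognition, manual edits, and augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitmetrics.errors import ParameterError, TrainingError, ValidationError
from gaitmetrics.segmentation import (
    ActionLabel,
    Segment,
    apply_manual_corrections,
    augment_dataset,
    fit_templates,
    mirror_flip,
    recognize_stream,
    recurrent_recognizer_spec,
    sliding_windows,
    time_warp,
    window_accuracy,
)
from gaitmetrics.skeleton import JointId, MotionSequence, N_JOINTS
from gaitmetrics.synthetic import (
    DEFAULT_SESSION_SCRIPT,
    ParticipantProfile,
    generate_jumping_jack,
    generate_session,
)


def _make_seq(n, rng=None, rate=30.0):
    rng = rng or np.random.default_rng(0)
    pos = rng.normal(0, 0.3, (n, N_JOINTS, 3))
    pos[:, :, 1] += 1.0
    pos[:, int(JointId.Head), 1] += 0.5
    return MotionSequence(np.arange(n) / rate, pos, nominal_rate=rate)


class TestLabels:
    def test_exactly_ten_labels(self):
        assert len(ActionLabel) == 10

    def test_label_names_match_the_scripted_moves(self):
        assert {l.value for l in ActionLabel} == {
            "jumping jack", "jump forward", "jump backward", "jump right",
            "jump left", "walk", "step forward", "step back", "touch nose",
            "idle",
        }


class TestSlidingWindows:
    @pytest.mark.parametrize(
        "n,expected_starts",
        [
            (60, [0]),
            (59, []),
            (120, [0, 15, 30, 45, 60]),
        ],
    )
    def test_window_starts(self, n, expected_starts):
        wins = sliding_windows(_make_seq(max(n, 1)))
        assert [w.start for w in wins] == expected_starts

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        n=st.integers(1, 400),
        length=st.integers(1, 100),
        hop=st.integers(1, 50),
    )
    def test_count_matches_closed_form(self, n, length, hop):
        wins = sliding_windows(_make_seq(n), length=length, hop=hop)
        expected = (n - length) // hop + 1 if n >= length else 0
        assert len(wins) == expected
        # brute-force enumeration of valid starts
        assert [w.start for w in wins] == [
            s for s in range(0, n, hop) if s + length <= n
        ]


class TestTemplates:
    def test_model_covers_all_ten_labels(self, template_model):
        assert set(template_model.templates) == set(ActionLabel)

    def test_missing_label_coverage_is_training_error(self):
        p = ParticipantProfile(seed=1)
        pair = generate_session([ActionLabel.IDLE, ActionLabel.WALK], p)
        with pytest.raises(TrainingError, match="jumping jack"):
            fit_templates([pair])

    def test_duplicated_exemplars_leave_centroid_unchanged(self):
        p = ParticipantProfile(seed=2)
        pair = generate_session(list(DEFAULT_SESSION_SCRIPT), p)
        single = fit_templates([pair])
        double = fit_templates([pair, pair])
        for lbl in ActionLabel:
            np.testing.assert_allclose(
                single.templates[lbl], double.templates[lbl], atol=1e-12
            )

    def test_centroid_is_elementwise_mean_of_two_profiles(self):
        pairs = [
            generate_session(
                [ActionLabel.IDLE], ParticipantProfile(height=h, seed=s)
            )
            for h, s in [(1.5, 3), (1.7, 4)]
        ]
        only_idle = [ActionLabel.IDLE]
        joint = fit_templates(pairs, length=30, labels=only_idle)
        singles = [fit_templates([p], length=30, labels=only_idle) for p in pairs]
        expected = 0.5 * (
            singles[0].templates[ActionLabel.IDLE]
            + singles[1].templates[ActionLabel.IDLE]
        )
        np.testing.assert_allclose(
            joint.templates[ActionLabel.IDLE], expected, atol=1e-12
        )

    def test_json_round_trip(self, template_model, tmp_path):
        path = tmp_path / "model.json"
        template_model.to_json(path)
        back = type(template_model).from_json(path)
        for lbl in ActionLabel:
            np.testing.assert_allclose(
                back.templates[lbl], template_model.templates[lbl], atol=1e-9
            )


class TestRecognition:
    def test_pure_idle_stream_is_one_idle_segment(self, template_model):
        p = ParticipantProfile(seed=20, noise_sd=0.002)
        seq, _ = generate_session([ActionLabel.IDLE] * 3, p)
        segments = recognize_stream(seq, template_model)
        assert len(segments) == 1
        assert segments[0].label is ActionLabel.IDLE

    def test_jj_between_idles_found_with_tight_boundaries(self, template_model):
        p = ParticipantProfile(seed=21, noise_sd=0.003, timing_jitter=0.03)
        seq, truth = generate_session(
            [ActionLabel.IDLE, ActionLabel.JUMPING_JACK, ActionLabel.IDLE],
            p,
            jj_cycles=3,
        )
        segments = recognize_stream(seq, template_model)
        jj = [s for s in segments if s.label is ActionLabel.JUMPING_JACK]
        assert len(jj) == 1
        true_jj = truth.segments[1]
        assert abs(jj[0].start_frame - true_jj.start_frame) <= 15
        assert abs(jj[0].end_frame - true_jj.end_frame) <= 15

    def test_held_out_profiles_window_accuracy(self, template_model):
        accs = []
        for seed, h in [(11, 1.52), (12, 1.68)]:
            p = ParticipantProfile(
                height=h, seed=seed, noise_sd=0.004, timing_jitter=0.05,
                rl_amplitude_ratio=0.85, rl_lag=0.05, jj_frequency=0.55,
            )
            seq, truth = generate_session(list(DEFAULT_SESSION_SCRIPT), p)
            accs.append(window_accuracy(seq, truth.segments, template_model))
        assert min(accs) >= 0.90

    def test_recognizer_is_deterministic(self, template_model):
        p = ParticipantProfile(seed=22, noise_sd=0.003)
        seq, _ = generate_session(
            [ActionLabel.IDLE, ActionLabel.WALK], p
        )
        a = recognize_stream(seq, template_model)
        b = recognize_stream(seq, template_model)
        assert [(s.label, s.start_frame, s.end_frame) for s in a] == [
            (s.label, s.start_frame, s.end_frame) for s in b
        ]


class TestManualCorrections:
    SEGS = [
        Segment(ActionLabel.IDLE, 0, 60),
        Segment(ActionLabel.JUMPING_JACK, 60, 150),
        Segment(ActionLabel.IDLE, 150, 200),
    ]

    def test_boundary_shift_marks_manual(self):
        out = apply_manual_corrections(
            self.SEGS, [{"op": "update", "index": 1, "start_frame": 65}]
        )
        assert out[1].start_frame == 65 and out[1].source == "manual"
        assert out[0].source == "auto"

    def test_delete_shortens_list(self):
        out = apply_manual_corrections(self.SEGS, [{"op": "delete", "index": 0}])
        assert len(out) == 2

    def test_overlapping_edit_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            apply_manual_corrections(
                self.SEGS, [{"op": "update", "index": 1, "end_frame": 170}]
            )


class TestMirrorFlip:
    def test_involution(self):
        seq = _make_seq(20)
        back = mirror_flip(mirror_flip(seq))
        np.testing.assert_allclose(back.positions, seq.positions, atol=1e-12)

    def test_left_wrist_maps_to_negated_right_wrist(self):
        seq = _make_seq(5)
        seq.positions[:, int(JointId.WristLeft)] = [0.3, 1.2, 0.4]
        out = mirror_flip(seq)
        np.testing.assert_allclose(
            out.positions[:, int(JointId.WristRight)],
            np.tile([-0.3, 1.2, 0.4], (5, 1)),
        )

    def test_symmetric_pose_is_fixed_point(self, symmetric_jj):
        seq, _ = symmetric_jj
        out = mirror_flip(seq)
        np.testing.assert_allclose(out.positions, seq.positions, atol=1e-9)


class TestTimeWarp:
    def test_identity_factor_keeps_frames(self):
        seq = _make_seq(100)
        assert time_warp(seq, 1.0).n_frames == 100

    def test_300_frames_at_1p2_gives_250(self, symmetric_profile):
        seq, _ = generate_jumping_jack(symmetric_profile, n_cycles=5)
        assert seq.n_frames == 300
        assert time_warp(seq, 1.2).n_frames == 250

    def test_dominant_frequency_scales_with_factor(self):
        n = 600
        t = np.arange(n) / 30.0
        pos = np.zeros((n, N_JOINTS, 3))
        pos[:, :, 1] = np.sin(2 * np.pi * 0.5 * t)[:, None]
        pos[:, int(JointId.Head), 1] += 1.5
        seq = MotionSequence(t, pos, nominal_rate=30.0)
        out = time_warp(seq, 1.1)
        y = out.positions[:, 0, 1] - np.mean(out.positions[:, 0, 1])
        spec = np.abs(np.fft.rfft(y))
        freqs = np.fft.rfftfreq(out.n_frames, 1 / 30.0)
        peak = freqs[np.argmax(spec[1:]) + 1]
        bin_width = 30.0 / out.n_frames
        assert abs(peak - 0.55) <= bin_width

    def test_round_trip_recovers_channels(self):
        p = ParticipantProfile(seed=30, noise_sd=0.0)
        seq, _ = generate_jumping_jack(p, n_cycles=4)
        back = time_warp(time_warp(seq, 1.15), 1 / 1.15)
        n = min(back.n_frames, seq.n_frames)
        orig = seq.positions[:n].reshape(n, -1)
        rec = back.positions[:n].reshape(n, -1)
        rng_span = orig.max(axis=0) - orig.min(axis=0) + 1e-9
        rms = np.sqrt(np.mean((orig - rec) ** 2, axis=0))
        assert np.all(rms < 0.02 * rng_span + 1e-6)

    def test_non_positive_factor_rejected(self):
        with pytest.raises(ParameterError):
            time_warp(_make_seq(10), 0.0)


class TestAugmentation:
    def test_one_sample_yields_twelve(self):
        out = augment_dataset([_make_seq(20)])
        assert len(out) == 12

    def test_ten_samples_yield_120(self):
        samples = [_make_seq(15, np.random.default_rng(i)) for i in range(10)]
        assert len(augment_dataset(samples)) == 120

    def test_wrong_factor_count_rejected_unless_overridden(self):
        with pytest.raises(ParameterError):
            augment_dataset([_make_seq(15)], warp_factors=[1.0, 1.1])
        assert len(
            augment_dataset(
                [_make_seq(15)], warp_factors=[1.0, 1.1], allow_any_factors=True
            )
        ) == 4


class TestRecurrentSpec:
    def test_architecture_description(self):
        spec = recurrent_recognizer_spec()
        lstm = [l for l in spec["layers"] if l["type"] == "lstm"]
        assert len(lstm) == 3 and all(l["units"] == 20 for l in lstm)
        assert spec["layers"][-1] == {"type": "softmax", "units": 10}
        assert spec["input_shape"] == (60, 52)

    def test_feature_count_echoed(self):
        assert recurrent_recognizer_spec(75)["input_shape"] == (60, 75)
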