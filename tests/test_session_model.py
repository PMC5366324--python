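"""Domain types, scoring schema, and EDF/TSV serialization."""

import dataclasses

import numpy as np
import pytest

from eegnaming.session_model import (
    CHANNELS_9,
    DEFAULT_LAYOUT,
    ChannelLayout,
    EEGSession,
    ResponseCategory,
    TrialEvent,
    category_is_self_corrected,
    category_schema,
    read_session,
    write_session,
)


class TestSchema:
    def test_ten_categories_bijective_keypad_codes(self):
        cats = list(ResponseCategory)
        assert len(cats) == 10
        assert sorted(int(c) for c in cats) == list(range(10))

    def test_exactly_three_self_corrected(self):
        flags = [category_is_self_corrected(c) for c in ResponseCategory]
        assert sum(flags) == 3
        assert category_is_self_corrected(ResponseCategory.SELF_CORRECTED_SEMANTIC)
        assert not category_is_self_corrected(ResponseCategory.CORRECT)

    def test_schema_export_lists_all_codes(self):
        schema = category_schema()
        assert len(schema["categories"]) == 10
        assert {c["keypad_value"] for c in schema["categories"]} == set(range(10))


class TestLayout:
    def test_default_layout_contains_required_subsets(self):
        for ch in CHANNELS_9:
            assert ch in DEFAULT_LAYOUT.names
        assert len(DEFAULT_LAYOUT.names) == 16

    def test_missing_required_channel_rejected(self):
        names = tuple(n if n != "Fz" else "X1" for n in DEFAULT_LAYOUT.names)
        with pytest.raises(ValueError, match="Fz"):
            ChannelLayout(names=names)

    def test_positions_available_for_topography(self):
        assert all(n in DEFAULT_LAYOUT.positions for n in DEFAULT_LAYOUT.names)


class TestTrialEvent:
    def test_no_response_iff_absent_onset(self):
        t = TrialEvent(0, None, ResponseCategory.CORRECT, "cat", 1)
        with pytest.raises(ValueError, match="NO_RESPONSE"):
            t.validate(256)
        t2 = TrialEvent(0, 300, ResponseCategory.NO_RESPONSE, "cat", 1)
        with pytest.raises(ValueError):
            t2.validate(256)

    def test_response_within_display_window(self):
        late = TrialEvent(0, 2561, ResponseCategory.CORRECT, "cat", 1)
        with pytest.raises(ValueError, match="10-s"):
            late.validate(256)

    def test_no_response_epoch_spans_full_display(self):
        t = TrialEvent(100, None, ResponseCategory.NO_RESPONSE, "cat", 1)
        assert t.epoch(256) == (100, 100 + 2560)


class TestSerialization:
    def test_round_trip_signal_and_events(self, tiny_session, tmp_path):
        eeg, ev = tmp_path / "s.edf", tmp_path / "s.tsv"
        write_session(tiny_session, eeg, ev)
        back = read_session(eeg, ev)
        assert back.trials == tiny_session.trials
        assert back.fs == 256
        assert back.layout.names == tiny_session.layout.names
        # 16-bit quantization bound: per-channel range / 65535
        step = (
            2 * np.ceil(np.maximum(np.abs(tiny_session.signal).max(axis=1), 1))
            / 65535
        )
        err = np.abs(back.signal - tiny_session.signal).max(axis=1)
        assert np.all(err <= step)

    def test_zero_signal_round_trip(self, tmp_path):
        sess = EEGSession(
            signal=np.zeros((16, 2560)),
            fs=256,
            layout=DEFAULT_LAYOUT,
            trials=[],
            participant_id="z",
            session_index=1,
        )
        write_session(sess, tmp_path / "z.edf", tmp_path / "z.tsv")
        back = read_session(tmp_path / "z.edf", tmp_path / "z.tsv")
        assert np.allclose(back.signal, 0.0, atol=1e-4)

    def test_all_categories_survive_round_trip(self, tmp_path):
        trials = [
            TrialEvent(
                stimulus_onset=i * 4000,
                response_onset=None
                if c == ResponseCategory.NO_RESPONSE
                else i * 4000 + 512,
                category=c,
                item=f"item{i}",
                set_index=1 + i // 4,
            )
            for i, c in enumerate(ResponseCategory)
        ]
        n = trials[-1].stimulus_onset + 2560 + 256
        sess = EEGSession(
            signal=np.random.default_rng(0).normal(0, 20, (16, n)),
            fs=256,
            layout=DEFAULT_LAYOUT,
            trials=trials,
            participant_id="allcats",
            session_index=2,
        )
        write_session(sess, tmp_path / "a.edf", tmp_path / "a.tsv")
        back = read_session(tmp_path / "a.edf", tmp_path / "a.tsv")
        assert [t.category for t in back.trials] == list(ResponseCategory)

    def test_no_response_serializes_empty_field(self, tmp_path):
        sess = EEGSession(
            signal=np.zeros((16, 2560 + 512)),
            fs=256,
            layout=DEFAULT_LAYOUT,
            trials=[
                TrialEvent(0, None, ResponseCategory.NO_RESPONSE, "mug", 1)
            ],
            participant_id="nr",
            session_index=1,
        )
        write_session(sess, tmp_path / "n.edf", tmp_path / "n.tsv")
        data_line = [
            l
            for l in (tmp_path / "n.tsv").read_text().splitlines()
            if not l.startswith("#")
        ][1]
        fields = data_line.split("\t")
        assert fields[2] == ""  # response_onset_sample column

    def test_inconsistent_event_table_rejected(self, tmp_path):
        sess = EEGSession(
            signal=np.zeros((16, 2560 + 512)),
            fs=256,
            layout=DEFAULT_LAYOUT,
            trials=[TrialEvent(0, 512, ResponseCategory.CORRECT, "mug", 1)],
            participant_id="bad",
            session_index=1,
        )
        write_session(sess, tmp_path / "b.edf", tmp_path / "b.tsv")
        # blank out the response onset while keeping category = Correct
        text = (tmp_path / "b.tsv").read_text().replace("\t512\t", "\t\t")
        (tmp_path / "b.tsv").write_text(text)
        with pytest.raises(ValueError, match="NO_RESPONSE"):
            read_session(tmp_path / "b.edf", tmp_path / "b.tsv")

    def test_onset_beyond_signal_rejected(self, tiny_session, tmp_path):
        bad = dataclasses.replace(
            tiny_session.trials[-1],
            stimulus_onset=tiny_session.signal.shape[1] - 100,
            response_onset=tiny_session.signal.shape[1] - 50,
        )
        sess = EEGSession(
            signal=tiny_session.signal,
            fs=256,
            layout=tiny_session.layout,
            trials=list(tiny_session.trials[:-1]) + [bad],
            participant_id="oob",
            session_index=1,
        )
        with pytest.raises(ValueError, match="beyond"):
            sess.validate()
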