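"""Canonical representation of a picture-naming EEG session.

A session couples a continuous 16-channel scalp recording (10-20 montage,
referenced to the right ear, 256 Hz) with a per-trial event table.  Every
trial shows one photograph for 10 s; the participant's naming attempt is
scored into one of ten response categories, three of which mark errors the
speaker corrected on their own within the display window.

Sample indices are 0-based and epochs are half-open ``[start, end)``.
Signals are stored in microvolts.  On disk a session is an EDF file plus a
tab-separated event table; EDF quantizes to 16 bits, events round-trip
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CANONICAL_FS = 256
STIMULUS_DURATION_S = 10.0

#: midline subset used for the primary (3-channel) analysis
CHANNELS_3 = ("Fz", "Cz", "Pz")
#: fronto-centro-parietal grid used for the extended (9-channel) analysis
CHANNELS_9 = ("F3", "Fz", "F4", "C3", "Cz", "C4", "P3", "Pz", "P4")


class ResponseCategory(IntEnum):
    """Ten-way scoring of a naming attempt.

    Keypad numeric values are assigned 0-9 in schema row order; the scorer
    entered these on a numeric keypad during the session.  "Correct" requires
    the target noun on the first production attempt; the three
    ``SELF_CORRECTED_*`` categories are initial errors corrected by the
    speaker before the 10-s display window elapsed.
    """

    NO_RESPONSE = 0
    CORRECT = 1
    SELF_CORRECTED_FRAGMENT = 2
    FRAGMENT_INCORRECT = 3
    SEMANTIC_ERROR = 4
    SELF_CORRECTED_SEMANTIC = 5
    CIRCUMLOCUTION = 6
    PHONOLOGICAL_NEOLOGISTIC = 7
    SELF_CORRECTED_PHONOLOGICAL = 8
    PERSEVERATION = 9


SELF_CORRECTED = frozenset(
    {
        ResponseCategory.SELF_CORRECTED_FRAGMENT,
        ResponseCategory.SELF_CORRECTED_SEMANTIC,
        ResponseCategory.SELF_CORRECTED_PHONOLOGICAL,
    }
)

#: plain (uncorrected) error families and their self-corrected counterparts
ERROR_FAMILIES = {
    ResponseCategory.FRAGMENT_INCORRECT: ResponseCategory.SELF_CORRECTED_FRAGMENT,
    ResponseCategory.SEMANTIC_ERROR: ResponseCategory.SELF_CORRECTED_SEMANTIC,
    ResponseCategory.PHONOLOGICAL_NEOLOGISTIC: ResponseCategory.SELF_CORRECTED_PHONOLOGICAL,
}


def category_is_self_corrected(category: ResponseCategory) -> bool:
    """True exactly for the three self-corrected categories."""
    return ResponseCategory(category) in SELF_CORRECTED


def category_schema() -> dict:
    """JSON-serializable enumeration of the scoring schema."""
    return {
        "categories": [
            {
                "code": c.name,
                "keypad_value": int(c),
                "self_corrected": category_is_self_corrected(c),
            }
            for c in ResponseCategory
        ]
    }


def write_category_schema(path) -> None:
    Path(path).write_text(json.dumps(category_schema(), indent=2) + "\n")


# standard top-view 10-20 coordinates (unit head radius), for topographies
_POSITIONS_1020 = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.46, 0.52), "Fz": (0.0, 0.50),
    "F4": (0.46, 0.52), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.46, -0.52), "Pz": (0.0, -0.50),
    "P4": (0.46, -0.52), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "Oz": (0.0, -1.0), "O2": (0.31, -0.95),
}


@dataclass(frozen=True)
class ChannelLayout:
    """Electrode montage: ordered labels, reference, 2-D scalp positions."""

    names: tuple
    reference: str = "A2"
    positions: dict = field(default_factory=dict)

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) != 16 or len(set(names)) != 16:
            raise ValueError("layout requires 16 unique channel labels")
        for required in CHANNELS_9:
            if required not in names:
                raise ValueError(f"montage is missing required channel {required}")
        if not self.positions:
            object.__setattr__(
                self,
                "positions",
                {n: _POSITIONS_1020[n] for n in names if n in _POSITIONS_1020},
            )

    def index(self, name: str) -> int:
        return self.names.index(name)

    def subset_indices(self, names: Sequence[str]) -> list:
        return [self.index(n) for n in names]


#: default 16-channel montage; the study used 16 unspecified 10-20 sites, so
#: a symmetric fronto-temporo-parietal grid covering the required nine is used
DEFAULT_LAYOUT = ChannelLayout(
    names=(
        "F7", "F3", "Fz", "F4", "F8",
        "T3", "C3", "Cz", "C4", "T4",
        "T5", "P3", "Pz", "P4", "T6",
        "Oz",
    )
)


@dataclass(frozen=True)
class TrialEvent:
    """One naming trial.

    ``response_onset`` is absent exactly when the participant gave no
    response within the 10-s display window (category NO_RESPONSE).
    """

    stimulus_onset: int
    response_onset: Optional[int]
    category: ResponseCategory
    item: str
    set_index: int

    def validate(self, fs: int) -> None:
        if (self.response_onset is None) != (
            self.category == ResponseCategory.NO_RESPONSE
        ):
            raise ValueError(
                f"trial {self.item!r}: response_onset must be absent iff "
                f"category is NO_RESPONSE (got {self.category.name})"
            )
        if self.response_onset is not None:
            if self.response_onset <= self.stimulus_onset:
                raise ValueError("response_onset must follow stimulus_onset")
            if self.response_onset - self.stimulus_onset > STIMULUS_DURATION_S * fs:
                raise ValueError("response_onset beyond the 10-s display window")

    def epoch(self, fs: int) -> tuple:
        """Half-open feature epoch: stimulus onset up to the response, or the
        full 10-s display when there was no response."""
        end = (
            self.response_onset
            if self.response_onset is not None
            else self.stimulus_onset + int(round(STIMULUS_DURATION_S * fs))
        )
        return self.stimulus_onset, end


@dataclass
class EEGSession:
    """Continuous multi-channel EEG plus its scored trial events."""

    signal: np.ndarray  # channels x samples, microvolts
    fs: int
    layout: ChannelLayout
    trials: list
    participant_id: str
    session_index: int

    def validate(self) -> "EEGSession":
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2 or sig.shape[0] != len(self.layout.names):
            raise ValueError("signal must be (n_channels, n_samples)")
        if self.fs != CANONICAL_FS:
            raise ValueError(f"canonical sessions are sampled at {CANONICAL_FS} Hz")
        if not 1 <= self.session_index <= 3:
            raise ValueError("session_index must be 1-3")
        n = sig.shape[1]
        prev_end = -1
        for t in self.trials:
            t.validate(self.fs)
            start, end = t.epoch(self.fs)
            if start < 0 or start + int(STIMULUS_DURATION_S * self.fs) > n:
                raise ValueError("trial extends beyond the recorded signal")
            if start <= prev_end:
                raise ValueError("trials must be time-ordered and non-overlapping")
            prev_end = start + int(STIMULUS_DURATION_S * self.fs) - 1
        self.signal = sig
        return self

    def channel(self, name: str) -> np.ndarray:
        return self.signal[self.layout.index(name)]


_EVENT_COLUMNS = [
    "trial_id",
    "stimulus_onset_sample",
    "response_onset_sample",
    "category_code",
    "item",
    "set_index",
]


def write_session(
    session: EEGSession, eeg_path, events_path, header_comments: Sequence[str] = ()
) -> None:
    """Serialize a session as EDF (signal) + TSV (events).

    The TSV is event-lossless; the EDF quantizes each channel to 16 bits over
    its own physical range.  The exact sample count is recorded in a header
    comment so the zero-padding added to complete the last one-second EDF
    record can be trimmed on read.
    """
    from . import _edf

    session.validate()
    _edf.write_edf(
        eeg_path,
        session.signal,
        session.fs,
        session.layout.names,
        patient_id=str(session.participant_id),
        recording_id=f"session {session.session_index}",
    )
    rows = []
    for i, t in enumerate(session.trials):
        rows.append(
            {
                "trial_id": i,
                "stimulus_onset_sample": t.stimulus_onset,
                "response_onset_sample": (
                    "" if t.response_onset is None else t.response_onset
                ),
                "category_code": int(t.category),
                "item": t.item,
                "set_index": t.set_index,
            }
        )
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    with open(events_path, "w", encoding="utf-8") as fh:
        fh.write(f"# participant_id={session.participant_id}\n")
        fh.write(f"# session_index={session.session_index}\n")
        fh.write(f"# n_samples={session.signal.shape[1]}\n")
        fh.write(f"# reference={session.layout.reference}\n")
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_events_header(events_path) -> dict:
    meta = {}
    with open(events_path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def read_session(eeg_path, events_path) -> EEGSession:
    """Load and validate a session written by :func:`write_session`.

    Raises if the EDF montage does not cover the required 10-20 subset, if an
    event's response onset is inconsistent with its category, or if any onset
    lies outside the recorded signal.
    """
    import mne

    raw = mne.io.read_raw_edf(eeg_path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # mne returns volts
    names = tuple(raw.ch_names)
    layout = ChannelLayout(names=names)
    fs = int(round(raw.info["sfreq"]))

    meta = _read_events_header(events_path)
    df = pd.read_csv(events_path, sep="\t", comment="#", dtype={"item": str})
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")

    n_samples = int(meta.get("n_samples", signal.shape[1]))
    signal = signal[:, :n_samples]

    trials = []
    for _, row in df.iterrows():
        resp = row["response_onset_sample"]
        resp = None if pd.isna(resp) or resp == "" else int(resp)
        trials.append(
            TrialEvent(
                stimulus_onset=int(row["stimulus_onset_sample"]),
                response_onset=resp,
                category=ResponseCategory(int(row["category_code"])),
                item=str(row["item"]),
                set_index=int(row["set_index"]),
            )
        )

    session = EEGSession(
        signal=signal,
        fs=fs,
        layout=layout,
        trials=trials,
        participant_id=meta.get("participant_id", "unknown"),
        session_index=int(meta.get("session_index", 1)),
    )
    return session.validate()


def with_reference_layout(session: EEGSession, layout: ChannelLayout) -> EEGSession:
    """Reorder a session's channels to match ``layout`` (names must agree)."""
    if set(layout.names) != set(session.layout.names):
        raise ValueError("channel sets differ")
    order = [session.layout.index(n) for n in layout.names]
    return replace(
        session, signal=session.signal[order], layout=layout
    )
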