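"""Minimal EDF (European Data Format) writer.

Only the subset needed for this package is implemented: continuous
multi-channel recordings with a common sampling rate, written as one-second
data records of 16-bit integers.  Reading is delegated to
:func:`mne.io.read_raw_edf`, which serves as an independent check on the
files produced here.

Signals whose length is not a whole number of seconds are zero-padded to the
next record boundary; callers that need the exact length must record it out
of band (the session writer stores it in the event-table header comment).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

DIG_MIN = -32768
DIG_MAX = 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int = 8) -> bytes:
    # shortest representation that fits the fixed-width field
    for fmt in ("%g", "%.6g", "%.4g", "%.2g"):
        s = fmt % value
        if len(s) <= width:
            return _field(s, width)
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(
    path,
    signal: np.ndarray,
    fs: int,
    channel_names: Sequence[str],
    physical_dim: str = "uV",
    patient_id: str = "X",
    recording_id: str = "X",
) -> None:
    """Write ``signal`` (channels x samples, physical units) as plain EDF.

    Each channel is scaled independently to the full 16-bit digital range,
    so the quantization step is ``(phys_max - phys_min) / 65535``.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2:
        raise ValueError("signal must be channels x samples")
    n_ch, n_samp = signal.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length mismatch")
    if fs <= 0 or int(fs) != fs:
        raise ValueError("fs must be a positive integer")
    fs = int(fs)

    n_rec = max(1, math.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samp] = signal

    # per-channel symmetric physical range, integer-valued so the header
    # round-trips exactly through its 8-character ascii field
    phys_max = np.ceil(np.maximum(np.abs(padded).max(axis=1), 1.0))
    phys_min = -phys_max
    scale = (DIG_MAX - DIG_MIN) / (phys_max - phys_min)
    digital = np.rint((padded - phys_min[:, None]) * scale[:, None]) + DIG_MIN
    digital = np.clip(digital, DIG_MIN, DIG_MAX).astype("<i2")

    header = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field("01.01.01", 8),
            _field("00.00.00", 8),
            _field(str(256 * (n_ch + 1)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),
            _field(str(n_ch), 4),
        ]
    )
    blocks = [
        b"".join(_field(name, 16) for name in channel_names),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field(physical_dim, 8) for _ in range(n_ch)),
        b"".join(_num(phys_min[i]) for i in range(n_ch)),
        b"".join(_num(phys_max[i]) for i in range(n_ch)),
        b"".join(_num(DIG_MIN) for _ in range(n_ch)),
        b"".join(_num(DIG_MAX) for _ in range(n_ch)),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field(str(fs), 8) for _ in range(n_ch)),
        b"".join(_field("", 32) for _ in range(n_ch)),
    ]

    with open(path, "wb") as fh:
        fh.write(header)
        for block in blocks:
            fh.write(block)
        # records: for each second, all samples of ch0, then ch1, ...
        recs = digital.reshape(n_ch, n_rec, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(recs).tobytes())
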