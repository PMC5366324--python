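"""AR spectral features for single naming trials.

The feature path: each 1000-ms window of a channel (advanced every 62.5 ms)
is demeaned and fit with a 40th-order autoregressive model by Burg's method;
the model's amplitude spectrum is averaged inside six 4-Hz bands spanning
6-29 Hz; a trial's feature vector is the mean of its window vectors over the
epoch from stimulus onset up to (but not including) the response.  Trials
with no response use the full 10-s display window.

Burg's method is used because it yields stable models (reflection
coefficients strictly inside the unit interval) on windows as short as 256
samples, where Yule-Walker estimates of order 40 are badly biased.  The
recursion is implemented batched over windows, which is what makes whole
sessions tractable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .session_model import (
    CHANNELS_3,
    CHANNELS_9,
    EEGSession,
    TrialEvent,
)

DEFAULT_BANDS = ((6, 9), (10, 13), (14, 17), (18, 21), (22, 25), (26, 29))


@dataclass(frozen=True)
class SpectralConfig:
    """Parameters of the spectral feature extraction.

    ``window_length_ms`` and ``window_step_ms`` must convert to whole sample
    counts at the session's sampling rate (256 and 16 samples at 256 Hz).
    ``eval_resolution`` is the spacing (Hz) of the grid on which the AR
    amplitude spectrum is averaged within each band, endpoints inclusive.
    """

    ar_order: int = 40
    bands: tuple = DEFAULT_BANDS
    window_length_ms: float = 1000.0
    window_step_ms: float = 62.5
    eval_resolution: float = 0.25

    def __post_init__(self):
        los = [b[0] for b in self.bands]
        his = [b[1] for b in self.bands]
        if any(lo >= hi for lo, hi in self.bands):
            raise ValueError("bands must have lo < hi")
        if any(his[i] >= los[i + 1] for i in range(len(self.bands) - 1)):
            raise ValueError("bands must be non-overlapping and ascending")

    def window_samples(self, fs: int) -> int:
        w = self.window_length_ms * fs / 1000.0
        if abs(w - round(w)) > 1e-9:
            raise ValueError("window length is not a whole number of samples")
        return int(round(w))

    def step_samples(self, fs: int) -> int:
        s = self.window_step_ms * fs / 1000.0
        if abs(s - round(s)) > 1e-9:
            raise ValueError("window step is not a whole number of samples")
        return int(round(s))

    def band_grid(self, band) -> np.ndarray:
        lo, hi = band
        n = int(round((hi - lo) / self.eval_resolution)) + 1
        return lo + self.eval_resolution * np.arange(n)

    def band_labels(self) -> list:
        return [f"{lo}-{hi}" for lo, hi in self.bands]


@dataclass(frozen=True)
class ARModel:
    """All-pole model  x_t = sum_k a_k x_{t-k} + e_t,  Var(e) = sigma2.

    A zero-variance (constant) input yields the degenerate model with all
    coefficients and sigma2 equal to zero, whose spectrum is identically
    zero; ``degenerate`` flags it.
    """

    order: int
    coefficients: np.ndarray
    sigma2: float
    fs: float

    @property
    def degenerate(self) -> bool:
        return self.sigma2 == 0.0


class EpochTooShortError(ValueError):
    """Raised when a trial epoch cannot hold a single analysis window."""


def _burg_batch(segments: np.ndarray, order: int):
    """Burg recursion vectorized over rows.

    Parameters
    ----------
    segments : (m, n) array, each row one demeaned segment.
    order : AR order p < n.

    Returns
    -------
    coeffs : (m, p) predictor coefficients (positive convention).
    sigma2 : (m,) innovation variances.
    kmax : (m,) largest absolute reflection coefficient per row.
    """
    segments = np.atleast_2d(np.asarray(segments, dtype=float))
    m, n = segments.shape
    if n <= order:
        raise ValueError(f"segment length {n} must exceed AR order {order}")

    f = segments[:, 1:].copy()
    b = segments[:, :-1].copy()
    E = np.einsum("ij,ij->i", segments, segments) / n
    a = np.zeros((m, order))
    kmax = np.zeros(m)
    for p in range(order):
        if p > 0:
            f = f[:, 1:]
            b = b[:, :-1]
        den = np.einsum("ij,ij->i", f, f) + np.einsum("ij,ij->i", b, b)
        num = 2.0 * np.einsum("ij,ij->i", f, b)
        k = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        # Levinson update of the predictor coefficients
        a_new = a.copy()
        if p > 0:
            a_new[:, :p] = a[:, :p] - k[:, None] * a[:, p - 1 :: -1]
        a_new[:, p] = k
        a = a_new
        f, b = f - k[:, None] * b, b - k[:, None] * f
        E = E * (1.0 - k**2)
        kmax = np.maximum(kmax, np.abs(k))
    return a, np.maximum(E, 0.0), kmax


def fit_ar_burg(segment: np.ndarray, order: int, fs: float = 256.0) -> ARModel:
    """Fit a single demeaned segment by Burg's method.

    The segment mean is removed internally.  A constant segment yields the
    degenerate zero model rather than an error.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ValueError("segment must be one-dimensional")
    if segment.size <= order:
        raise ValueError(
            f"segment of {segment.size} samples is too short for order {order}"
        )
    x = segment - segment.mean()
    if not np.any(x):
        return ARModel(order=order, coefficients=np.zeros(order), sigma2=0.0, fs=fs)
    coeffs, sigma2, _ = _burg_batch(x[None, :], order)
    return ARModel(
        order=order, coefficients=coeffs[0], sigma2=float(sigma2[0]), fs=fs
    )


def reflection_coefficients(segment: np.ndarray, order: int) -> np.ndarray:
    """Per-stage Burg reflection coefficients (for stability checks)."""
    segment = np.asarray(segment, dtype=float)
    x = segment - segment.mean()
    f = x[1:].copy()
    b = x[:-1].copy()
    ks = []
    for p in range(order):
        if p > 0:
            f = f[1:]
            b = b[:-1]
        den = f @ f + b @ b
        k = 0.0 if den == 0 else 2.0 * (f @ b) / den
        ks.append(k)
        f, b = f - k * b, b - k * f
    return np.array(ks)


def _spectrum_batch(
    coeffs: np.ndarray, sigma2: np.ndarray, fs: float, freqs: np.ndarray
) -> np.ndarray:
    """Amplitude spectra (rows x freqs) of batched AR models.

    power(f) = sigma2 / fs / |1 - sum_k a_k exp(-i 2 pi f k / fs)|^2,
    amplitude = sqrt(power).
    """
    order = coeffs.shape[1]
    k = np.arange(1, order + 1)
    ph = np.exp(-2j * np.pi * np.outer(k, freqs) / fs)  # (order, nf)
    denom = np.abs(1.0 - coeffs @ ph) ** 2
    power = (sigma2[:, None] / fs) / np.where(denom > 0, denom, np.inf)
    return np.sqrt(power)


def ar_spectrum(model: ARModel, freqs) -> np.ndarray:
    """Amplitude spectrum of an AR model on a frequency grid (Hz)."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs <= 0) or np.any(freqs >= model.fs / 2):
        raise ValueError("frequencies must lie strictly inside (0, fs/2)")
    if model.degenerate:
        return np.zeros_like(freqs)
    return _spectrum_batch(
        model.coefficients[None, :], np.array([model.sigma2]), model.fs, freqs
    )[0]


def _band_amplitudes_batch(
    coeffs: np.ndarray, sigma2: np.ndarray, fs: float, config: SpectralConfig
) -> np.ndarray:
    grids = [config.band_grid(b) for b in config.bands]
    freqs = np.concatenate(grids)
    amp = _spectrum_batch(coeffs, sigma2, fs, freqs)
    out = np.empty((coeffs.shape[0], len(config.bands)))
    start = 0
    for j, g in enumerate(grids):
        out[:, j] = amp[:, start : start + g.size].mean(axis=1)
        start += g.size
    return out


def band_amplitudes(model: ARModel, config: SpectralConfig = SpectralConfig()):
    """Mean amplitude of the AR spectrum inside each configured band."""
    if model.degenerate:
        return np.zeros(len(config.bands))
    return _band_amplitudes_batch(
        model.coefficients[None, :], np.array([model.sigma2]), model.fs, config
    )[0]


def window_count(epoch_len: int, fs: int, config: SpectralConfig) -> int:
    """Number of fully contained windows: floor((len - L) / S) + 1, 0 if none."""
    L = config.window_samples(fs)
    S = config.step_samples(fs)
    if epoch_len < L:
        return 0
    return (epoch_len - L) // S + 1


def _epoch_windows(x: np.ndarray, L: int, S: int) -> np.ndarray:
    """View of all complete windows of ``x`` as rows (stride trick)."""
    n_win = (x.size - L) // S + 1
    return np.lib.stride_tricks.as_strided(
        x, shape=(n_win, L), strides=(x.strides[0] * S, x.strides[0])
    )


def sliding_window_features(
    session: EEGSession,
    channel: str,
    epoch: tuple,
    config: SpectralConfig = SpectralConfig(),
) -> np.ndarray:
    """Per-window band-amplitude vectors for one channel over ``epoch``.

    Windows are anchored at the epoch start and advance by the configured
    step; only windows fully inside the half-open epoch are analyzed.
    Returns an (n_windows, n_bands) array; an epoch shorter than one window
    yields an empty array with a warning.
    """
    start, end = epoch
    x = session.channel(channel)[start:end]
    L = config.window_samples(session.fs)
    S = config.step_samples(session.fs)
    if x.size < L:
        warnings.warn(
            f"epoch of {x.size} samples is shorter than one {L}-sample window",
            stacklevel=2,
        )
        return np.empty((0, len(config.bands)))
    wins = _epoch_windows(x, L, S)
    wins = wins - wins.mean(axis=1, keepdims=True)
    coeffs, sigma2, _ = _burg_batch(wins, config.ar_order)
    return _band_amplitudes_batch(coeffs, sigma2, session.fs, config)


def feature_labels(channels: Sequence[str], config: SpectralConfig) -> list:
    """Deterministic column order: channel-major, bands ascending."""
    return [f"{ch}_{bl}" for ch in channels for bl in config.band_labels()]


def trial_features(
    session: EEGSession,
    trial: TrialEvent,
    channels: Sequence[str],
    config: SpectralConfig = SpectralConfig(),
) -> np.ndarray:
    """One design-matrix row: per (channel, band) mean across the trial's
    windows, epoch = stimulus onset up to the response (or the full 10-s
    display for no-response trials).

    Raises :class:`EpochTooShortError` when the epoch cannot hold a single
    window; the caller decides the trial's fate (the table builder excludes
    it and logs the reason).
    """
    start, end = trial.epoch(session.fs)
    L = config.window_samples(session.fs)
    S = config.step_samples(session.fs)
    if end - start < L:
        raise EpochTooShortError(
            f"epoch of {end - start} samples cannot hold a {L}-sample window"
        )
    idx = session.layout.subset_indices(channels)
    segs = []
    for ci in idx:
        wins = _epoch_windows(session.signal[ci, start:end], L, S)
        segs.append(wins)
    n_win = segs[0].shape[0]
    stacked = np.vstack(segs)  # (n_channels * n_win, L)
    stacked = stacked - stacked.mean(axis=1, keepdims=True)
    coeffs, sigma2, _ = _burg_batch(stacked, config.ar_order)
    amps = _band_amplitudes_batch(coeffs, sigma2, session.fs, config)
    amps = amps.reshape(len(channels), n_win, len(config.bands))
    return amps.mean(axis=1).ravel()


def resolve_channel_set(channel_set, layout) -> tuple:
    """Map a channel-set spec ('3' | '9' | '16' | explicit names) to labels."""
    if isinstance(channel_set, (list, tuple)):
        return tuple(channel_set)
    key = str(channel_set)
    if key == "3":
        return CHANNELS_3
    if key == "9":
        return CHANNELS_9
    if key == "16":
        return tuple(layout.names)
    raise ValueError(f"unknown channel set {channel_set!r}")


@dataclass
class FeatureTable:
    """Trials x (channel, band) design matrix with aligned trial metadata.

    ``features`` columns follow :func:`feature_labels`; ``meta`` carries
    session_index, trial_id, category_code, item and set_index for the same
    rows (ordered by session then trial).  Trials whose epoch was too short
    for one window are listed in ``exclusions`` as
    (session_index, trial_id, reason).
    """

    features: pd.DataFrame
    meta: pd.DataFrame
    channels: tuple
    config: SpectralConfig
    exclusions: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.features)

    def to_tsv(self, path) -> None:
        pd.concat([self.meta, self.features], axis=1).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, channels, config=SpectralConfig()) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        labels = feature_labels(channels, config)
        meta_cols = [c for c in df.columns if c not in labels]
        return cls(
            features=df[labels],
            meta=df[meta_cols],
            channels=tuple(channels),
            config=config,
        )

    @classmethod
    def concat(cls, tables: Sequence["FeatureTable"]) -> "FeatureTable":
        if not tables:
            raise ValueError("no tables to concatenate")
        first = tables[0]
        for t in tables[1:]:
            if t.channels != first.channels:
                raise ValueError("inconsistent channel sets")
        return cls(
            features=pd.concat(
                [t.features for t in tables], ignore_index=True
            ),
            meta=pd.concat([t.meta for t in tables], ignore_index=True),
            channels=first.channels,
            config=first.config,
            exclusions=[e for t in tables for e in t.exclusions],
        )


def build_feature_table(
    sessions: Sequence[EEGSession],
    channel_set="3",
    config: SpectralConfig = SpectralConfig(),
) -> FeatureTable:
    """Extract the design matrix for one or more sessions.

    Rows are ordered by (session, trial).  All sessions must share the same
    montage.  Excluded trials (epoch shorter than one window) are logged
    with reasons rather than silently dropped.
    """
    if not sessions:
        raise ValueError("no sessions supplied")
    layout = sessions[0].layout
    for s in sessions[1:]:
        if tuple(s.layout.names) != tuple(layout.names):
            raise ValueError("sessions have inconsistent montages")
    channels = resolve_channel_set(channel_set, layout)
    labels = feature_labels(channels, config)

    rows, meta_rows, exclusions = [], [], []
    for sess in sessions:
        for tid, trial in enumerate(sess.trials):
            try:
                row = trial_features(sess, trial, channels, config)
            except EpochTooShortError as exc:
                exclusions.append((sess.session_index, tid, str(exc)))
                continue
            rows.append(row)
            meta_rows.append(
                {
                    "session_index": sess.session_index,
                    "trial_id": tid,
                    "category_code": int(trial.category),
                    "item": trial.item,
                    "set_index": trial.set_index,
                }
            )
    features = pd.DataFrame(np.array(rows).reshape(len(rows), -1), columns=labels)
    return FeatureTable(
        features=features,
        meta=pd.DataFrame(meta_rows),
        channels=channels,
        config=config,
        exclusions=exclusions,
    )
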