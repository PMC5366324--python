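"""Synthetic picture-naming EEG with the statistical structure the analysis
assumes.

No EEG from the original participants is publicly available, so this module
generates sessions that emulate the study design: three sessions of 300
naming trials, each photograph shown for 10 s with at most 5 s between
trials, 16-channel 10-20 EEG at 256 Hz, and per-trial 10-way response
scoring.

Generative model
----------------
Background EEG per channel is a stationary AR(2) resonance (default peak
10 Hz) plus a white noise floor.  Each trial carries a scalar latent state
``s_t ~ N(0, trial_state_sd)``.  At each of the signature's effect
(channel, band) pairs, band-limited Gaussian noise is added during the
stimulus epoch with RMS ``effect_rms * w * (1 + g * s_t)`` (floored at 0),
so the trial-to-trial band amplitude tracks the state.  The same state
drives behavior through a logistic link:

    P(correct first attempt) = logistic(a + b * sum_cb(w_cb) * s_t)

Incorrect trials draw an outcome from the participant's error mixture and
error-family draws are promoted to their self-corrected category with a
per-family probability.  Response latency is lognormal truncated to
(0.25 s, 10 s]; no-response trials have no response onset.  The latency
model is an invention of this package - the study reports no latencies.

Error mixtures can be instantiated from the study's published per-participant
response-type frequency table so synthetic cohorts resemble the study's
behavioral heterogeneity.  The EEG mechanism itself is a stand-in: the study
never characterizes what distinguishes correct from error trials, and its
topographies differ across people.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .session_model import (
    CHANNELS_9,
    DEFAULT_LAYOUT,
    EEGSession,
    ERROR_FAMILIES,
    ResponseCategory,
    TrialEvent,
)
from .spectral_features import DEFAULT_BANDS

#: published response-type frequencies (percent of trials) per participant;
#: rows: Correct, NoResponse, SelfCorrFragment, FragmentIncorrect, Semantic,
#: SelfCorrSemantic, Circumlocution, Phonological, SelfCorrPhonological,
#: Perseveration
RESPONSE_PROFILES = {
    "1501": (84, 3, 1, 0, 5, 0, 0, 6, 1, 0),
    "1503": (26, 14, 1, 6, 20, 0, 2, 20, 11, 0),
    "1601": (26, 26, 0, 1, 19, 1, 23, 2, 1, 0),
    "1602": (75, 2, 0, 0, 15, 5, 1, 0, 1, 0),
    "1603": (34, 24, 0, 1, 26, 0, 1, 11, 1, 1),
    "1605": (78, 3, 0, 0, 8, 2, 0, 3, 5, 0),
    "1606": (94, 0, 0, 0, 3, 2, 1, 0, 0, 0),
    "1607": (74, 7, 0, 0, 11, 3, 2, 1, 2, 0),
}

_PROFILE_ORDER = (
    ResponseCategory.CORRECT,
    ResponseCategory.NO_RESPONSE,
    ResponseCategory.SELF_CORRECTED_FRAGMENT,
    ResponseCategory.FRAGMENT_INCORRECT,
    ResponseCategory.SEMANTIC_ERROR,
    ResponseCategory.SELF_CORRECTED_SEMANTIC,
    ResponseCategory.CIRCUMLOCUTION,
    ResponseCategory.PHONOLOGICAL_NEOLOGISTIC,
    ResponseCategory.SELF_CORRECTED_PHONOLOGICAL,
    ResponseCategory.PERSEVERATION,
)

#: outcomes an incorrect trial can take before self-correction promotion
BASE_ERROR_OUTCOMES = (
    ResponseCategory.NO_RESPONSE,
    ResponseCategory.FRAGMENT_INCORRECT,
    ResponseCategory.SEMANTIC_ERROR,
    ResponseCategory.CIRCUMLOCUTION,
    ResponseCategory.PHONOLOGICAL_NEOLOGISTIC,
    ResponseCategory.PERSEVERATION,
)


@dataclass(frozen=True)
class ParticipantSignature:
    """Participant-specific link between EEG and naming behavior.

    ``effect_weights`` maps (channel, (lo, hi)) pairs - channels restricted
    to the 9-channel fronto-centro-parietal subset - to nonnegative weights.
    ``link_intercept``/``link_slope`` are the a and b of the logistic
    accuracy link; ``amplitude_gain`` is the g of the RMS modulation;
    ``effect_rms`` the baseline RMS (microvolts) of the injected band-limited
    component.  ``error_mix`` is a probability vector over the six
    non-correct, non-self-corrected outcomes; ``self_correction_prob`` gives,
    per correctable error family, the chance an error is promoted to its
    self-corrected category.
    """

    effect_weights: dict
    link_intercept: float
    link_slope: float
    amplitude_gain: float = 0.5
    effect_rms: float = 4.0
    latency_log_mean: float = math.log(2.5)
    latency_log_sd: float = 0.5
    error_mix: dict = field(default_factory=dict)
    self_correction_prob: dict = field(default_factory=dict)

    def __post_init__(self):
        for (ch, band), w in self.effect_weights.items():
            if ch not in CHANNELS_9:
                raise ValueError(f"effect channel {ch} outside the 9-channel subset")
            if tuple(band) not in DEFAULT_BANDS:
                raise ValueError(f"unknown effect band {band}")
            if w < 0:
                raise ValueError("effect weights must be nonnegative")
        if self.error_mix:
            total = sum(self.error_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("error_mix must sum to 1")

    @property
    def total_weight(self) -> float:
        return sum(self.effect_weights.values())


def _mix_from_profile(profile: Sequence[float]):
    """Conditional error mixture + per-family self-correction rates from a
    published response-frequency row (percentages)."""
    pct = dict(zip(_PROFILE_ORDER, profile))
    sc_of = {base: sc for base, sc in ERROR_FAMILIES.items()}
    family_mass = {}
    sc_prob = {}
    for cat in BASE_ERROR_OUTCOMES:
        base = pct[cat]
        sc = pct[sc_of[cat]] if cat in sc_of else 0.0
        family_mass[cat] = base + sc
        if cat in sc_of:
            sc_prob[cat] = sc / (base + sc) if (base + sc) > 0 else 0.0
    total = sum(family_mass.values())
    if total == 0:
        # degenerate all-correct profile: uniform placeholder mixture
        mix = {cat: 1.0 / len(BASE_ERROR_OUTCOMES) for cat in BASE_ERROR_OUTCOMES}
    else:
        mix = {cat: m / total for cat, m in family_mass.items()}
    return mix, sc_prob, pct[ResponseCategory.CORRECT] / sum(profile)


def generate_signature(
    seed: int,
    null_effect: bool = False,
    profile: Optional[str] = None,
    n_effects: Optional[int] = None,
    link_slope: float = 1.5,
    amplitude_gain: float = 0.5,
    effect_rms: float = 4.0,
) -> ParticipantSignature:
    """Draw a reproducible participant signature.

    ``profile`` selects a published response-frequency row (participant id)
    for the error mixture and baseline accuracy; the default is the mean
    profile of the eight published rows (mean accuracy about 61%).
    ``null_effect=True`` zeroes all effect weights, giving a participant
    whose EEG carries no information about behavior.
    """
    rng = np.random.default_rng(seed)
    if profile is None:
        rows = np.array(list(RESPONSE_PROFILES.values()), dtype=float)
        prof = tuple(rows.mean(axis=0))
    else:
        prof = RESPONSE_PROFILES[str(profile)]
    mix, sc_prob, p_correct = _mix_from_profile(prof)
    a = math.log(p_correct / (1.0 - p_correct)) if 0 < p_correct < 1 else 0.0

    weights = {}
    if not null_effect:
        k = int(n_effects) if n_effects is not None else int(rng.integers(2, 5))
        cells = [(ch, band) for ch in CHANNELS_9 for band in DEFAULT_BANDS]
        idx = rng.choice(len(cells), size=k, replace=False)
        raw = rng.uniform(0.5, 1.0, size=k)
        raw /= raw.sum()
        weights = {cells[i]: float(w) for i, w in zip(idx, raw)}

    return ParticipantSignature(
        effect_weights=weights,
        link_intercept=a,
        link_slope=0.0 if null_effect else link_slope,
        amplitude_gain=amplitude_gain,
        effect_rms=effect_rms,
        error_mix=mix,
        self_correction_prob=sc_prob,
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the generator.

    Defaults are the study's conditions: 3 sessions x 300 trials (900 naming
    trials per participant), 256 Hz, 10-s stimulus display, inter-trial gap
    drawn uniformly from (1 s, 5 s].  The background profile applies to every
    channel: an AR(2) resonance (peak frequency / bandwidth / RMS) plus a
    white noise floor, in microvolts.
    """

    n_sessions: int = 3
    trials_per_session: int = 300
    fs: int = 256
    stimulus_duration: float = 10.0
    max_iti: float = 5.0
    min_iti: float = 1.0
    background_peak_hz: float = 10.0
    background_bandwidth_hz: float = 4.0
    background_rms: float = 10.0
    noise_floor_rms: float = 5.0
    trial_state_sd: float = 1.0
    pre_roll: float = 2.0
    post_roll: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if min(
            self.stimulus_duration, self.max_iti, self.min_iti,
            self.pre_roll, self.post_roll,
        ) <= 0:
            raise ValueError("all durations must be positive")
        if self.max_iti <= self.min_iti:
            raise ValueError("max_iti must exceed min_iti")
        if self.n_sessions < 1 or self.trials_per_session < 1:
            raise ValueError("invalid session/trial counts")


def _ar2_coefficients(peak_hz: float, bandwidth_hz: float, fs: float):
    theta = 2.0 * math.pi * peak_hz / fs
    r = math.exp(-math.pi * bandwidth_hz / fs)
    return 2.0 * r * math.cos(theta), -(r**2)


def _ar2_stationary_sd(a1: float, a2: float) -> float:
    # variance of an AR(2) process with unit innovation variance
    var = (1 - a2) / ((1 + a2) * ((1 - a2) ** 2 - a1**2))
    return math.sqrt(var)


def _truncated_lognormal(rng, log_mean, log_sd, lo=0.25, hi=10.0) -> float:
    for _ in range(1000):
        v = math.exp(rng.normal(log_mean, log_sd))
        if lo < v <= hi:
            return v
    return min(max(math.exp(log_mean), lo + 1e-6), hi)


def generate_session(
    signature: ParticipantSignature,
    config: GeneratorConfig,
    session_index: int,
    items: Optional[Sequence[str]] = None,
    participant_id: str = "sim",
) -> EEGSession:
    """Simulate one session; byte-identical events for identical inputs.

    The session RNG stream is seeded by (config.seed, session_index), so
    sessions of one participant differ but the whole participant is
    reproducible from the config seed.
    """
    fs = config.fs
    n_trials = config.trials_per_session
    if items is not None and len(items) != n_trials:
        raise ValueError("items must match trials_per_session")
    rng = np.random.default_rng((int(config.seed), int(session_index)))

    stim_len = int(round(config.stimulus_duration * fs))
    cursor = int(round(config.pre_roll * fs))
    onsets = []
    for _ in range(n_trials):
        onsets.append(cursor)
        iti = rng.uniform(config.min_iti, config.max_iti)
        cursor += stim_len + int(round(iti * fs))
    n_samples = cursor + int(round(config.post_roll * fs))
    # pad to a whole number of seconds so EDF records need no trimming
    n_samples = int(math.ceil(n_samples / fs) * fs)

    layout = DEFAULT_LAYOUT
    n_ch = len(layout.names)
    sig = np.empty((n_ch, n_samples))
    a1, a2 = _ar2_coefficients(
        config.background_peak_hz, config.background_bandwidth_hz, fs
    )
    ar_scale = config.background_rms / _ar2_stationary_sd(a1, a2)
    for ci in range(n_ch):
        innov = rng.standard_normal(n_samples + 4 * fs)
        colored = sps.lfilter([1.0], [1.0, -a1, -a2], innov)[4 * fs :]
        sig[ci] = ar_scale * colored
        sig[ci] += rng.normal(0.0, config.noise_floor_rms, n_samples)

    # latent per-trial states and the injected band-limited trial effects
    states = rng.normal(0.0, config.trial_state_sd, n_trials)
    sos_cache = {
        band: sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
        for (_, band) in signature.effect_weights
    }
    for t, onset in enumerate(onsets):
        for (ch, band), w in signature.effect_weights.items():
            target = signature.effect_rms * w * (
                1.0 + signature.amplitude_gain * states[t]
            )
            if target <= 0:
                continue
            noise = sps.sosfilt(
                sos_cache[band], rng.standard_normal(stim_len + fs)
            )[fs:]
            rms = noise.std()
            if rms > 0:
                sig[layout.index(ch), onset : onset + stim_len] += (
                    target / rms
                ) * noise

    # behavior through the logistic link
    total_w = signature.total_weight
    logits = signature.link_intercept + signature.link_slope * total_w * states
    p_correct = 1.0 / (1.0 + np.exp(-logits))
    mix_cats = list(BASE_ERROR_OUTCOMES)
    mix_p = np.array([signature.error_mix.get(c, 0.0) for c in mix_cats])
    if mix_p.sum() == 0:
        mix_p = np.full(len(mix_cats), 1.0 / len(mix_cats))
    mix_p = mix_p / mix_p.sum()

    trials = []
    sets_per_session = 3
    per_set = max(1, math.ceil(n_trials / sets_per_session))
    for t, onset in enumerate(onsets):
        if rng.random() < p_correct[t]:
            category = ResponseCategory.CORRECT
        else:
            category = mix_cats[rng.choice(len(mix_cats), p=mix_p)]
            if category in ERROR_FAMILIES and rng.random() < (
                signature.self_correction_prob.get(category, 0.0)
            ):
                category = ERROR_FAMILIES[category]
        if category == ResponseCategory.NO_RESPONSE:
            response_onset = None
        else:
            lat = _truncated_lognormal(
                rng, signature.latency_log_mean, signature.latency_log_sd,
                hi=config.stimulus_duration,
            )
            response_onset = onset + max(1, int(round(lat * fs)))
        set_index = sets_per_session * (session_index - 1) + 1 + t // per_set
        name = (
            items[t]
            if items is not None
            else f"item_s{session_index}_{t:03d}"
        )
        trials.append(
            TrialEvent(
                stimulus_onset=onset,
                response_onset=response_onset,
                category=category,
                item=name,
                set_index=set_index,
            )
        )

    return EEGSession(
        signal=sig,
        fs=fs,
        layout=layout,
        trials=trials,
        participant_id=participant_id,
        session_index=session_index,
    ).validate()


def generate_participant(
    signature: ParticipantSignature,
    config: GeneratorConfig,
    participant_id: str = "sim",
) -> list:
    """All sessions of one participant (session_index 1..n_sessions)."""
    return [
        generate_session(signature, config, si, participant_id=participant_id)
        for si in range(1, config.n_sessions + 1)
    ]


def planted_benchmark_signature(
    seed: int,
    channels: Sequence[str] = ("Fz", "Cz", "Pz"),
    link_slope: float = 2.0,
    amplitude_gain: float = 0.6,
    effect_rms: float = 6.0,
) -> ParticipantSignature:
    """Signature with one strong planted effect for detectability benchmarks.

    A single (channel, band) cell is drawn - by default from the midline
    channels the primary analysis uses - and given weight 1 with a strong
    behavioral link, the regime in which the pipeline is expected to recover
    the planted cell and generalize across sessions.
    """
    rng = np.random.default_rng(seed)
    ch = channels[int(rng.integers(0, len(channels)))]
    band = DEFAULT_BANDS[int(rng.integers(0, len(DEFAULT_BANDS)))]
    return replace(
        generate_signature(seed),
        effect_weights={(ch, band): 1.0},
        link_slope=link_slope,
        amplitude_gain=amplitude_gain,
        effect_rms=effect_rms,
    )


# ---------------------------------------------------------------------------
# stimulus pool handling


@dataclass(frozen=True)
class StimulusItem:
    """A normed photograph: name, naming agreement in [0, 1], familiarity
    rating in [1, 5]."""

    name: str
    naming_agreement: float
    familiarity: float

    def __post_init__(self):
        if not 0.0 <= self.naming_agreement <= 1.0:
            raise ValueError("naming_agreement must lie in [0, 1]")
        if not 1.0 <= self.familiarity <= 5.0:
            raise ValueError("familiarity must lie in [1, 5]")


def filter_stimulus_items(items: Sequence[StimulusItem]) -> list:
    """Retain items with naming agreement >= 20% and familiarity >= 3.75/5
    (both thresholds inclusive: the exclusion rule is strictly-less-than)."""
    return [
        it
        for it in items
        if it.naming_agreement >= 0.20 and it.familiarity >= 3.75
    ]


def make_stimulus_pool(
    n_items: int = 1469, seed: int = 0, duplicate_name_fraction: float = 0.03
) -> list:
    """Synthetic photograph norms pool: unique object names with a small
    fraction of repeated names (distinct photos of same-named objects), and
    agreement/familiarity spread so the retention filter actually bites."""
    rng = np.random.default_rng(seed)
    items = []
    for i in range(n_items):
        if i > 0 and rng.random() < duplicate_name_fraction:
            name = items[int(rng.integers(0, len(items)))].name
        else:
            name = f"object{i:04d}"
        items.append(
            StimulusItem(
                name=name,
                naming_agreement=float(rng.uniform(0.05, 1.0)),
                familiarity=float(rng.uniform(3.4, 5.0)),
            )
        )
    return items


def write_stimulus_items(items: Sequence[StimulusItem], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\tnaming_agreement\tfamiliarity\n")
        for it in items:
            fh.write(f"{it.name}\t{it.naming_agreement:.4f}\t{it.familiarity:.4f}\n")


def read_stimulus_items(path) -> list:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        StimulusItem(str(r["name"]), float(r["naming_agreement"]),
                     float(r["familiarity"]))
        for _, r in df.iterrows()
    ]


def partition_stimulus_sets(
    items: Sequence[StimulusItem], seed: int = 0, max_swaps: int = 10_000
) -> list:
    """Split exactly 900 retained items into 9 disjoint sets of 100.

    Items get random sort keys and are dealt into sets of 100.  Sets 1-3 are
    administered in session 1, 4-6 in session 2, 7-9 in session 3; within
    each session's three sets no item name may repeat.  Conflicts are
    resolved by deterministically trading the offending item with an item
    from a set of another session; an unsatisfiable pool (too many copies of
    one name) raises after the bounded swap budget.
    """
    items = list(items)
    if len(items) != 900:
        raise ValueError(f"need exactly 900 items, got {len(items)}")
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random(900), kind="stable")
    sets = [[items[i] for i in order[s * 100 : (s + 1) * 100]] for s in range(9)]
    sessions = [(0, 1, 2), (3, 4, 5), (6, 7, 8)]

    def find_violation():
        for g, group in enumerate(sessions):
            seen = {}
            for si in group:
                for pos, it in enumerate(sets[si]):
                    if it.name in seen:
                        return g, si, pos
                    seen[it.name] = (si, pos)
        return None

    def session_names(g, skip=None):
        names = set()
        for si in sessions[g]:
            for pos, it in enumerate(sets[si]):
                if (si, pos) != skip:
                    names.add(it.name)
        return names

    def session_of(si):
        return si // 3

    for _ in range(max_swaps):
        viol = find_violation()
        if viol is None:
            return sets
        g, si, pos = viol
        offender = sets[si][pos]
        here = session_names(g, skip=(si, pos))
        swapped = False
        for sj in range(9):
            if session_of(sj) == g:
                continue
            there = session_names(session_of(sj))
            if offender.name in there:
                continue
            for qos, cand in enumerate(sets[sj]):
                names_minus_cand = there - {cand.name} if sum(
                    1 for sk in sessions[session_of(sj)]
                    for it in sets[sk] if it.name == cand.name
                ) == 1 else there
                if cand.name in here or offender.name in names_minus_cand:
                    continue
                sets[si][pos], sets[sj][qos] = cand, offender
                swapped = True
                break
            if swapped:
                break
        if not swapped:
            raise ValueError(
                f"cannot place repeated name {offender.name!r}; "
                "too many duplicates for a conflict-free partition"
            )
    raise ValueError("swap budget exhausted before resolving repeated names")
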