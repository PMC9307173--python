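"""Synthetic narcoleptic-mouse EEG/EMG generator.

Vigilance-state sequences come from a semi-Markov chain over
{Wake, NREM, REM, Cataplexy} with gamma-distributed bout durations, at 1-s
label resolution.  Orexin-knockout-like fragmentation is emulated by short
wake/NREM bouts and a cataplexy hazard acting on sustained wakefulness; an
OX2R-agonist "drug effect" is modelled as a multiplicative lengthening of
wake bouts plus a multiplicative suppression of the cataplexy hazard.

Signals are realised from the state sequence as mixtures of band-limited
noise (delta 1-4 Hz, theta 6-9 Hz, fast 10-30 Hz) whose relative powers are
state-conditioned, plus Gaussian EMG with state-conditioned RMS (atonia
during REM and cataplexy-like states).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

WAKE = "Wake"
NREM = "NREM"
REM = "REM"
CATAPLEXY = "Cataplexy"
STATES = (WAKE, NREM, REM, CATAPLEXY)

#: EEG bands used throughout: (low, high) in Hz, inclusive 1-Hz bins.
BANDS = {"delta": (1, 4), "theta": (6, 9), "fast": (10, 30)}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_mean_bout() -> dict[str, float]:
    # Fragmented dark-phase architecture: short wake/NREM bouts.
    return {WAKE: 120.0, NREM: 100.0, REM: 60.0}


def _default_bout_shape() -> dict[str, float]:
    return {WAKE: 2.0, NREM: 2.0, REM: 2.0}


def _default_band_weights() -> dict[str, tuple[float, float, float]]:
    # (delta, theta, fast) relative power per state; each sums to 1.
    return {
        WAKE: (0.25, 0.25, 0.50),
        NREM: (0.60, 0.15, 0.25),
        REM: (0.15, 0.65, 0.20),
        CATAPLEXY: (0.15, 0.65, 0.20),
    }


def _default_emg_level() -> dict[str, float]:
    # RMS uV: atonia < NREM < wake.
    return {"wake": 40.0, "nrem": 12.0, "atonia": 4.0}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic recording generator.

    Durations are seconds, rates are events per hour of sustained
    wakefulness, EMG levels are RMS microvolts.  ``mean_bout`` may be
    ``math.inf`` for a state to force a single bout spanning the whole
    recording (degenerate one-state chain).
    """

    sampling_rate: float = 250.0
    duration_s: float = 10800.0
    zt_origin: float = 12.0
    mean_bout: Mapping[str, float] = field(default_factory=_default_mean_bout)
    bout_shape: Mapping[str, float] = field(default_factory=_default_bout_shape)
    rem_entry_prob: float = 0.15
    cataplexy_hazard: float = 2.0
    cataplexy_mean_s: float = 40.0
    cataplexy_min_s: float = 10.0
    min_wake_before_cataplexy_s: float = 40.0
    decoy_fraction: float = 0.10
    band_weights: Mapping[str, tuple[float, float, float]] = field(
        default_factory=_default_band_weights
    )
    eeg_rms_uv: float = 50.0
    emg_level_uv: Mapping[str, float] = field(default_factory=_default_emg_level)
    emg_wake_cv: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.duration_s > 0 and float(self.duration_s).is_integer()):
            raise ConfigError("duration_s must be a positive whole number of seconds")
        if self.sampling_rate <= 0 or not float(self.sampling_rate).is_integer():
            raise ConfigError("sampling_rate must be a positive integer Hz")
        for st in (WAKE, NREM, REM):
            if st not in self.mean_bout or st not in self.bout_shape:
                raise ConfigError(f"mean_bout/bout_shape missing state {st!r}")
        for st, m in self.mean_bout.items():
            if st not in STATES:
                raise ConfigError(f"unknown state key {st!r}")
            if not m > 0:
                raise ConfigError("mean bout durations must be positive")
        if any(s <= 0 for s in self.bout_shape.values()):
            raise ConfigError("bout shapes must be positive")
        if not 0.0 <= self.rem_entry_prob <= 1.0:
            raise ConfigError("rem_entry_prob must lie in [0, 1]")
        if self.cataplexy_hazard < 0:
            raise ConfigError("cataplexy_hazard must be non-negative")
        if self.cataplexy_min_s <= 0 or self.cataplexy_mean_s < self.cataplexy_min_s:
            raise ConfigError("cataplexy durations must satisfy 0 < min <= mean")
        if self.min_wake_before_cataplexy_s <= 0:
            raise ConfigError("min_wake_before_cataplexy_s must be positive")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise ConfigError("decoy_fraction must lie in [0, 1]")
        for st, w in self.band_weights.items():
            if st not in STATES:
                raise ConfigError(f"unknown state key {st!r} in band_weights")
            if len(w) != 3 or any(x < 0 for x in w):
                raise ConfigError("band_weights must be 3 non-negative numbers")
            if abs(sum(w) - 1.0) > 1e-6:
                raise ConfigError(f"band_weights for {st!r} must sum to 1")
        lv = self.emg_level_uv
        if not (0 < lv["atonia"] < lv["nrem"] < lv["wake"]):
            raise ConfigError("emg levels must satisfy atonia < nrem < wake")
        if self.emg_wake_cv < 0:
            raise ConfigError("emg_wake_cv must be non-negative")


@dataclass(frozen=True)
class StateTrack:
    """Per-second ground-truth vigilance labels (half-open 1-s bins from t=0)."""

    labels: np.ndarray  # dtype <U9, one label per second
    zt_origin: float = 12.0

    def __post_init__(self) -> None:
        bad = set(np.unique(self.labels)) - set(STATES)
        if bad:
            raise ConfigError(f"labels outside the four-state alphabet: {bad}")

    @property
    def duration_s(self) -> int:
        return int(len(self.labels))


@dataclass(frozen=True)
class Recording:
    """Two-channel sampled signal in microvolts."""

    eeg: np.ndarray
    emg: np.ndarray
    sampling_rate: float
    zt_origin: float = 12.0

    def __post_init__(self) -> None:
        if len(self.eeg) != len(self.emg):
            raise ConfigError("eeg and emg must have equal length")

    @property
    def duration_s(self) -> float:
        return len(self.eeg) / self.sampling_rate


def apply_drug_effect(
    config: SimConfig,
    wake_bout_multiplier: float,
    cataplexy_hazard_multiplier: float,
) -> SimConfig:
    """Return a config with wake bouts lengthened and cataplexy hazard scaled.

    Emulates the effect of an OX2R agonist: longer wake episodes (hence fewer
    wake<->NREM transitions) and a suppressed cataplexy hazard.
    """
    if wake_bout_multiplier <= 0 or cataplexy_hazard_multiplier <= 0:
        raise ConfigError("multipliers must be positive")
    mean_bout = dict(config.mean_bout)
    mean_bout[WAKE] = mean_bout[WAKE] * wake_bout_multiplier
    return replace(
        config,
        mean_bout=mean_bout,
        cataplexy_hazard=config.cataplexy_hazard * cataplexy_hazard_multiplier,
    )


def _bout_seconds(rng: np.random.Generator, mean: float, shape: float, remaining: int) -> int:
    if math.isinf(mean):
        return remaining
    d = rng.gamma(shape, mean / shape)
    return max(1, int(round(d)))


def simulate_states(config: SimConfig, seed: int | None = None) -> StateTrack:
    """Generate a per-second vigilance-state sequence.

    Semi-Markov chain Wake -> NREM -> (REM with prob ``rem_entry_prob`` |
    Wake); REM -> Wake.  During wake bouts an exponential clock with rate
    ``cataplexy_hazard`` per hour competes with the bout end; when it fires,
    a cataplexy-like bout is inserted, normally preceded by at least
    ``min_wake_before_cataplexy_s`` of continuous wake.  A fraction
    ``decoy_fraction`` of these events is instead preceded by a short
    (10-39 s) wake run, producing theta-atonia episodes that genuine
    cataplexy criteria must reject.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = int(config.duration_s)
    out: list[str] = []
    state = WAKE

    def emit(label: str, secs: int) -> None:
        out.extend([label] * min(secs, n - len(out)))

    while len(out) < n:
        remaining = n - len(out)
        if state == WAKE:
            d = _bout_seconds(rng, config.mean_bout[WAKE], config.bout_shape[WAKE], remaining)
            wait = (
                rng.exponential(3600.0 / config.cataplexy_hazard)
                if config.cataplexy_hazard > 0
                else math.inf
            )
            if wait < d:
                if rng.random() < config.decoy_fraction:
                    run = int(rng.integers(10, int(config.min_wake_before_cataplexy_s)))
                else:
                    run = max(int(round(wait)), int(config.min_wake_before_cataplexy_s))
                emit(WAKE, max(run, 1))
                cd = max(
                    config.cataplexy_min_s,
                    rng.gamma(2.0, config.cataplexy_mean_s / 2.0),
                )
                emit(CATAPLEXY, int(round(cd)))
                state = WAKE
                continue
            emit(WAKE, d)
            state = NREM
        elif state == NREM:
            d = _bout_seconds(rng, config.mean_bout[NREM], config.bout_shape[NREM], remaining)
            emit(NREM, d)
            state = REM if rng.random() < config.rem_entry_prob else WAKE
        else:  # REM
            d = _bout_seconds(rng, config.mean_bout[REM], config.bout_shape[REM], remaining)
            emit(REM, d)
            state = WAKE
    return StateTrack(labels=np.asarray(out, dtype="<U9"), zt_origin=config.zt_origin)


def track_runs(labels: Sequence[str] | np.ndarray) -> list[tuple[int, int, str]]:
    """Run-length encode a label sequence as (onset_s, duration_s, label)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return [(int(s), int(e - s), str(labels[s])) for s, e in zip(starts, ends)]


def true_cataplexy_events(
    track: StateTrack,
    min_duration_s: float = 10.0,
    min_prior_wake_s: float = 40.0,
) -> list[tuple[int, int, int]]:
    """Ground-truth cataplexy episodes as (onset_s, duration_s, prior_wake_s).

    An episode qualifies when the Cataplexy-labelled run lasts at least
    ``min_duration_s`` and the immediately preceding contiguous Wake run is
    at least ``min_prior_wake_s``; shorter-prior-wake (decoy) theta-atonia
    runs are excluded, mirroring the detector's third criterion.
    """
    runs = track_runs(track.labels)
    events = []
    for i, (onset, dur, lab) in enumerate(runs):
        if lab != CATAPLEXY or dur < min_duration_s:
            continue
        prior = runs[i - 1][1] if i > 0 and runs[i - 1][2] == WAKE else 0
        if prior >= min_prior_wake_s:
            events.append((onset, dur, prior))
    return events


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-RMS noise restricted to [lo, hi] Hz (zero-phase Butterworth)."""
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.std(x)


def _per_sample_envelope(
    per_second: np.ndarray, fs: int, crossfade_s: float = 0.1
) -> np.ndarray:
    """Per-sample amplitude from per-second values, crossfaded <= 1 s.

    A short boxcar smoothing of the stepwise envelope keeps transitions
    continuous without smearing a state's first second, so episodes at the
    detection floor (10 s) keep their nominal duration.
    """
    env = np.repeat(per_second.astype(float), fs)
    k = max(1, int(round(crossfade_s * fs)))
    padded = np.pad(env, k, mode="edge")
    kernel = np.ones(k) / k
    return np.convolve(padded, kernel, mode="same")[k:-k]


def synthesize_signals(
    track: StateTrack, config: SimConfig, seed: int | None = None
) -> Recording:
    """Render EEG/EMG signals for a state track.

    EEG is the sum of three band-limited noise components scaled per second
    by the square root of the current state's band weight (so band *powers*
    match the weights); transitions are crossfaded over at most 1 s.  EMG is
    white Gaussian noise with state-conditioned RMS; wake RMS fluctuates
    second-to-second with coefficient of variation ``emg_wake_cv``.
    """
    if track.duration_s == 0:
        raise ConfigError("empty track")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    fs = int(config.sampling_rate)
    n_sec = track.duration_s
    n = n_sec * fs

    labels = track.labels
    weights = np.array([config.band_weights[st] for st in labels])  # (n_sec, 3)
    eeg = np.zeros(n)
    for b, (lo, hi) in enumerate(BANDS.values()):
        comp = _bandlimited_noise(rng, n, fs, lo, hi)
        amp = config.eeg_rms_uv * np.sqrt(weights[:, b])
        eeg += comp * _per_sample_envelope(amp, fs)

    lv = config.emg_level_uv
    emg_rms = np.empty(n_sec)
    wake_mask = labels == WAKE
    emg_rms[wake_mask] = lv["wake"] * np.clip(
        rng.normal(1.0, config.emg_wake_cv, wake_mask.sum()), 0.05, None
    )
    emg_rms[labels == NREM] = lv["nrem"]
    emg_rms[(labels == REM) | (labels == CATAPLEXY)] = lv["atonia"]
    emg = rng.standard_normal(n) * _per_sample_envelope(emg_rms, fs)

    return Recording(eeg=eeg, emg=emg, sampling_rate=float(fs), zt_origin=track.zt_origin)


def simulate_recording(
    config: SimConfig, seed: int | None = None
) -> tuple[StateTrack, Recording]:
    """Convenience: states then signals, with decorrelated sub-seeds."""
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed).spawn(2)
    track = simulate_states(config, seed=int(ss[0].generate_state(1)[0] % (2**31)))
    rec = synthesize_signals(track, config, seed=int(ss[1].generate_state(1)[0] % (2**31)))
    return track, rec
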