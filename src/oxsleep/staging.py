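"""Rule-based vigilance-state staging of EEG/EMG epochs.

Epochs are classified into wakefulness, NREM sleep and REM sleep:
wakefulness shows fast EEG activity with high, variable EMG; NREM shows
high-amplitude delta (1-4 Hz) EEG with low EMG tone; REM shows theta
(6-9 Hz)-dominant EEG with EMG atonia.  The qualitative criteria are made
operational through band-power ratios and EMG thresholds expressed as
fractions of a per-recording wake-reference EMG level (semiautomatic
scoring implies per-recording normalisation).  Both 20-s and 4-s epoch
lengths are supported; an epoch containing several states receives the
label of the predominant state (the state occupying the longest time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sim import CATAPLEXY, NREM, REM, WAKE, Recording, StateTrack
from .spectral import EpochFeatures, epoch_features


class StagingError(ValueError):
    pass


@dataclass(frozen=True)
class StagingThresholds:
    """Numeric staging conventions (the criteria themselves are qualitative).

    ``delta_dominance``/``theta_dominance`` are minimum band-power ratios
    for NREM/REM; ``emg_low``/``emg_atonia`` are fractions of the
    calibrated wake-reference EMG RMS; ``wake_emg_cv_min`` is retained for
    completeness (wakefulness is the fall-through class, so it is not
    consulted by the default decision rule).
    """

    delta_dominance: float = 1.5
    theta_dominance: float = 1.5
    emg_low: float = 0.5
    emg_atonia: float = 0.2
    wake_emg_cv_min: float = 0.0
    calibration_quantile: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.emg_atonia < self.emg_low < 1):
            raise StagingError("need 0 < emg_atonia < emg_low < 1")
        if self.delta_dominance < 1 or self.theta_dominance < 1:
            raise StagingError("dominance thresholds must be >= 1")
        if not 0 < self.calibration_quantile < 1:
            raise StagingError("calibration_quantile must be in (0, 1)")


@dataclass(frozen=True)
class Calibration:
    """Per-recording scale constants."""

    wake_emg_ref: float  # uV, high quantile of epoch EMG RMS
    power_scale: float  # uV^2, median total 1-30 Hz power


@dataclass(frozen=True)
class Hypnogram:
    """Fixed-length-epoch vigilance labels over {Wake, NREM, REM}."""

    epoch_len: float
    labels: np.ndarray  # dtype <U9
    zt_origin: float = 12.0

    def __post_init__(self) -> None:
        bad = set(np.unique(self.labels)) - {WAKE, NREM, REM}
        if bad:
            raise StagingError(f"labels outside the 3-state alphabet: {bad}")

    @property
    def n_epochs(self) -> int:
        return int(len(self.labels))

    @property
    def span_s(self) -> float:
        return self.n_epochs * self.epoch_len


def calibrate(
    features: list[EpochFeatures], thresholds: StagingThresholds | None = None
) -> Calibration:
    """Derive per-recording reference levels from the epoch features.

    The wake-reference EMG RMS is a high quantile (default 0.9) of epoch
    EMG RMS values — recordings of waking rodents spend enough time at high
    muscle tone for the upper tail to track the wake level.
    """
    thresholds = thresholds or StagingThresholds()
    if len(features) < 30:
        raise StagingError("need at least 30 epochs to calibrate")
    emg = np.array([f.emg_rms for f in features])
    total = np.array([f.total_power for f in features])
    return Calibration(
        wake_emg_ref=float(np.quantile(emg, thresholds.calibration_quantile)),
        power_scale=float(np.median(total)),
    )


def classify_epoch(
    features: EpochFeatures,
    thresholds: StagingThresholds,
    calibration: Calibration,
) -> str:
    """Classify one epoch; total and deterministic.

    REM is tested before NREM because atonia is the more specific
    condition; anything matching neither sleep criterion is wakefulness.
    """
    d, t = features.delta_power, features.theta_power
    emg = features.emg_rms
    ref = calibration.wake_emg_ref
    if t >= thresholds.theta_dominance * d and emg <= thresholds.emg_atonia * ref:
        return REM
    if d >= thresholds.delta_dominance * t and emg <= thresholds.emg_low * ref:
        return NREM
    return WAKE


def score_recording(
    recording: Recording,
    epoch_len: float = 20.0,
    thresholds: StagingThresholds | None = None,
) -> Hypnogram:
    """Feature extraction, calibration and per-epoch classification."""
    thresholds = thresholds or StagingThresholds()
    feats = epoch_features(recording, epoch_len)
    cal = calibrate(feats, thresholds)
    labels = np.asarray(
        [classify_epoch(f, thresholds, cal) for f in feats], dtype="<U9"
    )
    return Hypnogram(epoch_len=float(epoch_len), labels=labels, zt_origin=recording.zt_origin)


_PRIORITY = (WAKE, NREM, REM)


def predominant_label(fine_labels, previous: str | None = None) -> str:
    """Label of the state occupying the longest time within an epoch.

    Ties go to the previous epoch's label when it is among the tied
    states, otherwise to the fixed priority Wake > NREM > REM.
    """
    fine_labels = list(fine_labels)
    if not fine_labels:
        raise StagingError("empty epoch")
    counts: dict[str, int] = {}
    for lab in fine_labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    tied = [s for s, c in counts.items() if c == best]
    if len(tied) == 1:
        return tied[0]
    if previous in tied:
        return previous
    for s in _PRIORITY:
        if s in tied:
            return s
    return tied[0]


def hypnogram_from_track(track: StateTrack, epoch_len: float) -> Hypnogram:
    """Ground-truth hypnogram from per-second labels by the predominant rule.

    Cataplexy-like seconds map to REM for the 3-state alphabet: theta
    dominance plus atonia is spectrally REM-like, and separating the two is
    the cataplexy detector's job, not the stager's.
    """
    epoch_len = int(epoch_len)
    labels = np.where(track.labels == CATAPLEXY, REM, track.labels)
    n_epochs = len(labels) // epoch_len
    if n_epochs == 0:
        raise StagingError("track shorter than one epoch")
    out = []
    prev: str | None = None
    for k in range(n_epochs):
        lab = predominant_label(labels[k * epoch_len : (k + 1) * epoch_len], previous=prev)
        out.append(lab)
        prev = lab
    return Hypnogram(
        epoch_len=float(epoch_len), labels=np.asarray(out, dtype="<U9"), zt_origin=track.zt_origin
    )


def pool_to_blocks(hypnogram: Hypnogram, block_len: float) -> Hypnogram:
    """Majority-pool a fine hypnogram into coarser blocks (e.g. 4 s -> 20 s)."""
    k = int(round(block_len / hypnogram.epoch_len))
    if k < 1 or abs(k * hypnogram.epoch_len - block_len) > 1e-9:
        raise StagingError("block_len must be a multiple of epoch_len")
    n_blocks = hypnogram.n_epochs // k
    out = []
    prev: str | None = None
    for b in range(n_blocks):
        lab = predominant_label(hypnogram.labels[b * k : (b + 1) * k], previous=prev)
        out.append(lab)
        prev = lab
    return Hypnogram(
        epoch_len=float(block_len),
        labels=np.asarray(out, dtype="<U9"),
        zt_origin=hypnogram.zt_origin,
    )
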