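"""Cataplexy-like episode detection.

An episode qualifies when three criteria hold: (i) an abrupt episode of
nuchal atonia lasting at least 10 s, (ii) theta activity dominating the
EEG during the episode, and (iii) at least 40 s of wakefulness immediately
preceding the episode.  Detection runs at 1-s resolution — the 10-s
minimum duration is sub-epoch at 20-s scoring, and the criteria are stated
in seconds.  Criterion (iii) is what separates cataplexy from ordinary
(NREM-entered) REM sleep, which also shows theta and atonia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sim import WAKE, Recording
from .spectral import epoch_features
from .staging import Calibration, StagingThresholds, calibrate


class EventsError(ValueError):
    pass


@dataclass(frozen=True)
class CataplexyParams:
    """Detection thresholds; durations in seconds.

    ``merge_gap_s``: qualifying runs separated by strictly fewer than this
    many non-qualifying seconds are merged before the criteria are tested.
    ``wake_gap_tolerance_s``: maximum run of non-wake seconds tolerated
    inside the preceding wake run (robustness to single-second
    misclassification).
    """

    min_atonia_s: float = 10.0
    min_prior_wake_s: float = 40.0
    theta_dominance: float = 1.5
    atonia_fraction: float = 0.2
    merge_gap_s: float = 2.0
    wake_gap_tolerance_s: float = 1.0

    def __post_init__(self) -> None:
        if self.min_atonia_s <= 0 or self.min_prior_wake_s <= 0:
            raise EventsError("duration criteria must be positive")


@dataclass(frozen=True)
class CataplexyEvent:
    onset_s: int
    duration_s: int
    prior_wake_s: int


def detect_from_flags(
    wake: np.ndarray, qualifying: np.ndarray, params: CataplexyParams
) -> list[CataplexyEvent]:
    """Detect episodes from per-second wake and theta-atonia flags.

    Maximal qualifying runs (after gap merging) of length >= min_atonia_s
    whose immediately preceding wake run — measured backward from onset,
    tolerating non-wake gaps of at most ``wake_gap_tolerance_s`` consecutive
    seconds and reported as the full span from the earliest counted second
    to onset — is >= min_prior_wake_s, in onset order.
    """
    wake = np.asarray(wake, dtype=bool)
    qualifying = np.asarray(qualifying, dtype=bool)
    if wake.shape != qualifying.shape:
        raise EventsError("wake and qualifying flag tracks differ in length")
    n = wake.size
    if n == 0:
        return []

    # maximal runs of qualifying seconds
    padded = np.concatenate(([False], qualifying, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])

    # merge runs separated by < merge_gap_s non-qualifying seconds
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < params.merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])

    events = []
    for s, e in merged:
        if e - s < params.min_atonia_s:
            continue
        # backward scan for the preceding wake run
        i = s - 1
        gap = 0
        earliest = s
        while i >= 0:
            if wake[i]:
                earliest = i
                gap = 0
            else:
                gap += 1
                if gap > params.wake_gap_tolerance_s:
                    break
            i -= 1
        prior = s - earliest if earliest < s else 0
        if prior >= params.min_prior_wake_s:
            events.append(CataplexyEvent(onset_s=s, duration_s=e - s, prior_wake_s=prior))
    return events


def _feature_series(features) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed per-second (delta, theta, emg_rms) series.

    A 1-s periodogram gives each band only a handful of degrees of
    freedom, so raw per-second band powers flicker; a centred 5-s mean
    stabilises the dominance ratios.  EMG RMS instead gets a 5-s running
    median — edge-preserving, so an episode's first and last atonia
    seconds stay exactly in place, which matters for episodes at the
    10-s duration floor.
    """
    from scipy.ndimage import median_filter, uniform_filter1d

    delta = uniform_filter1d(
        np.asarray([f.delta_power for f in features], float), 5, mode="nearest"
    )
    theta = uniform_filter1d(
        np.asarray([f.theta_power for f in features], float), 5, mode="nearest"
    )
    emg = median_filter(np.asarray([f.emg_rms for f in features], float), size=5, mode="nearest")
    return delta, theta, emg


def _flags_from_series(
    delta: np.ndarray,
    theta: np.ndarray,
    emg: np.ndarray,
    thresholds: StagingThresholds,
    params: CataplexyParams,
    calibration: Calibration,
) -> tuple[np.ndarray, np.ndarray]:
    ref = calibration.wake_emg_ref
    rem_like = (theta >= thresholds.theta_dominance * delta) & (
        emg <= thresholds.emg_atonia * ref
    )
    nrem_like = (delta >= thresholds.delta_dominance * theta) & (
        emg <= thresholds.emg_low * ref
    )
    wake = ~rem_like & ~nrem_like
    qualifying = (theta >= params.theta_dominance * delta) & (
        emg <= params.atonia_fraction * ref
    )
    return wake, qualifying


def detect_cataplexy(
    second_labels,
    features,
    params: CataplexyParams | None = None,
    calibration: Calibration | None = None,
) -> list[CataplexyEvent]:
    """Detect episodes from a per-second label track and 1-s epoch features.

    ``second_labels`` is any sequence of per-second state labels (a
    ground-truth track or an inferred one); ``features`` are the matching
    1-s :class:`~oxsleep.spectral.EpochFeatures`.  The qualifying flag
    requires theta dominance over delta and EMG RMS at or below
    ``atonia_fraction`` of the calibrated wake-reference EMG.
    """
    params = params or CataplexyParams()
    thresholds = StagingThresholds()
    labels = np.asarray(getattr(second_labels, "labels", second_labels))
    if len(labels) != len(features):
        raise EventsError("label track and feature sequence differ in length")
    if calibration is None:
        calibration = calibrate(list(features))
    wake = labels == WAKE
    delta, theta, emg = _feature_series(features)
    _, qualifying = _flags_from_series(delta, theta, emg, thresholds, params, calibration)
    return detect_from_flags(wake, qualifying, params)


def second_flags(
    recording: Recording,
    thresholds: StagingThresholds | None = None,
    params: CataplexyParams | None = None,
    calibration: Calibration | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-second (wake, theta-atonia) flags from 1-s epoch features.

    Band powers are mean-smoothed and EMG RMS median-filtered over 5 s
    before thresholding.  The wake flag applies the staging criteria at 1-s
    resolution (wake = neither sleep criterion matches); the qualifying
    flag requires theta dominance over delta and EMG RMS at or below
    ``atonia_fraction`` of the calibrated wake-reference EMG.
    """
    thresholds = thresholds or StagingThresholds()
    params = params or CataplexyParams()
    feats = epoch_features(recording, 1)
    cal = calibration or calibrate(feats, thresholds)
    delta, theta, emg = _feature_series(feats)
    return _flags_from_series(delta, theta, emg, thresholds, params, cal)


def detect_cataplexy_in_recording(
    recording: Recording,
    thresholds: StagingThresholds | None = None,
    params: CataplexyParams | None = None,
    calibration: Calibration | None = None,
) -> list[CataplexyEvent]:
    """End-to-end detection on a recording (features -> flags -> episodes)."""
    params = params or CataplexyParams()
    wake, qualifying = second_flags(recording, thresholds, params, calibration)
    return detect_from_flags(wake, qualifying, params)


def count_and_latency(
    events: list[CataplexyEvent], window_s: float
) -> tuple[int, float]:
    """Number of episodes with onset inside the window, and latency to the
    first episode (right-censored at the window length when none occur)."""
    in_window = [e for e in events if e.onset_s < window_s]
    count = len(in_window)
    latency = float(in_window[0].onset_s) if in_window else float(window_s)
    return count, latency


def match_events(
    detected: list[CataplexyEvent],
    truth: list[tuple[int, int, int]],
) -> tuple[int, int, int]:
    """Overlap-match detections to ground-truth episodes.

    Returns (n_matched_truth, n_detected, n_truth); a truth episode counts
    as recalled if any detection overlaps it in time, and a detection as
    correct if it overlaps any truth episode.
    """
    def overlaps(a0: float, a1: float, b0: float, b1: float) -> bool:
        return a0 < b1 and b0 < a1

    matched_truth = sum(
        any(overlaps(t0, t0 + td, d.onset_s, d.onset_s + d.duration_s) for d in detected)
        for (t0, td, _) in truth
    )
    return matched_truth, len(detected), len(truth)
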