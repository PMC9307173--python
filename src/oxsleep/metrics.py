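"""Sleep-architecture summaries and the conditioned-place-preference score.

Total time per vigilance state is the summed epoch time in that state;
mean episode duration is total time divided by the number of episodes
(maximal runs of identical labels).  Transition counts are tallied for all
six ordered pairs among Wake/NREM/REM — direct Wake->REM transitions are
the narcolepsy signature and are reported alongside the rest.  Hourly
profiles use 3600-s bins aligned to the analysis-window start (the
administration time); an episode spanning an hour boundary is split at the
boundary, each fragment counting in its own bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .sim import NREM, REM, WAKE
from .spectral import EpochFeatures
from .staging import Hypnogram

STATE_ORDER = (WAKE, NREM, REM)
TRANSITION_PAIRS = (
    (WAKE, NREM),
    (NREM, WAKE),
    (NREM, REM),
    (REM, WAKE),
    (REM, NREM),
    (WAKE, REM),
)


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class Episode:
    state: str
    onset_s: float
    duration_s: float


@dataclass(frozen=True)
class ArchitectureSummary:
    total_s: Mapping[str, float]
    n_episodes: Mapping[str, int]
    mean_episode_duration_s: Mapping[str, float]
    transition_counts: Mapping[tuple[str, str], int]
    hourly_wake_s: tuple[float, ...]
    hourly_wake_episode_duration_s: tuple[float, ...]
    nrem_delta_power: float

    @property
    def wake_nrem_transitions(self) -> int:
        """Wake<->NREM transition count, the fragmentation index."""
        return self.transition_counts[(WAKE, NREM)] + self.transition_counts[(NREM, WAKE)]


def episodes(hypnogram: Hypnogram) -> list[Episode]:
    """Maximal same-label runs as half-open intervals in seconds.

    Runs truncated by the analysis-window edge count as episodes: the
    episode-duration formula divides totals by episode counts with no
    exclusion rule.
    """
    labels = hypnogram.labels
    if labels.size == 0:
        raise MetricsError("empty hypnogram")
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    L = hypnogram.epoch_len
    return [
        Episode(state=str(labels[s]), onset_s=s * L, duration_s=(e - s) * L)
        for s, e in zip(starts, ends)
    ]


def _clip(hypnogram: Hypnogram, window: tuple[float, float] | None) -> tuple[Hypnogram, int]:
    if window is None:
        return hypnogram, 0
    start, end = window
    L = hypnogram.epoch_len
    if start < 0 or end > hypnogram.span_s or start >= end:
        raise MetricsError("window outside hypnogram span")
    if (start / L) % 1 or (end / L) % 1:
        raise MetricsError("window must align to the epoch grid")
    i0, i1 = int(start / L), int(end / L)
    return (
        Hypnogram(epoch_len=L, labels=hypnogram.labels[i0:i1], zt_origin=hypnogram.zt_origin),
        i0,
    )


def summarize(
    hypnogram: Hypnogram,
    features: Sequence[EpochFeatures] | None = None,
    window: tuple[float, float] | None = None,
) -> ArchitectureSummary:
    """All architecture metrics on the (clipped) analysis window.

    ``features`` must be epoch-aligned with the full hypnogram; when given,
    NREM delta power is the mean delta power over NREM-labelled epochs in
    the window (unnormalised uV^2), otherwise NaN.
    """
    clipped, offset = _clip(hypnogram, window)
    eps = episodes(clipped)
    L = clipped.epoch_len

    total = {s: 0.0 for s in STATE_ORDER}
    count = {s: 0 for s in STATE_ORDER}
    for ep in eps:
        total[ep.state] += ep.duration_s
        count[ep.state] += 1
    mean_dur = {
        s: (total[s] / count[s]) if count[s] else 0.0 for s in STATE_ORDER
    }

    trans = {pair: 0 for pair in TRANSITION_PAIRS}
    for a, b in zip(clipped.labels[:-1], clipped.labels[1:]):
        if a != b:
            trans[(str(a), str(b))] += 1

    # hourly wake profiles, episodes split at hour boundaries
    n_hours = int(np.ceil(clipped.span_s / 3600.0))
    hourly_total = np.zeros(n_hours)
    hourly_count = np.zeros(n_hours, dtype=int)
    for ep in eps:
        if ep.state != WAKE:
            continue
        t0, t1 = ep.onset_s, ep.onset_s + ep.duration_s
        h = int(t0 // 3600)
        while t0 < t1:
            seg_end = min(t1, (h + 1) * 3600.0)
            hourly_total[h] += seg_end - t0
            hourly_count[h] += 1
            t0 = seg_end
            h += 1
    hourly_mean = tuple(
        float(hourly_total[h] / hourly_count[h]) if hourly_count[h] else 0.0
        for h in range(n_hours)
    )

    nrem_delta = float("nan")
    if features is not None:
        n = clipped.n_epochs
        feats = list(features)[offset : offset + n]
        if len(feats) != n:
            raise MetricsError("features not aligned with hypnogram epochs")
        vals = [
            f.delta_power for f, lab in zip(feats, clipped.labels) if lab == NREM
        ]
        if vals:
            nrem_delta = float(np.mean(vals))

    return ArchitectureSummary(
        total_s=total,
        n_episodes=count,
        mean_episode_duration_s=mean_dur,
        transition_counts=trans,
        hourly_wake_s=tuple(float(x) for x in hourly_total),
        hourly_wake_episode_duration_s=hourly_mean,
        nrem_delta_power=nrem_delta,
    )


@dataclass(frozen=True)
class CppResult:
    """Conditioned-place-preference outcome, all times in seconds."""

    pre_s: float
    post_s: float
    score_s: float


CPP_TEST_DURATION_S = 900.0


def cpp_score(pre_s: float, post_s: float) -> CppResult:
    """CPP score: post-conditioning minus pre-conditioning time on the
    drug-paired side.  Negative scores indicate aversion.  Both tests last
    900 s, bounding the inputs."""
    for name, v in (("pre_s", pre_s), ("post_s", post_s)):
        if not 0.0 <= v <= CPP_TEST_DURATION_S:
            raise MetricsError(f"{name} must lie in [0, {CPP_TEST_DURATION_S:.0f}] s")
    return CppResult(pre_s=float(pre_s), post_s=float(post_s), score_s=float(post_s - pre_s))


def summary_frame(summaries: Mapping[str, ArchitectureSummary]):
    """Group table (one row per recording) for CSV export / mean +/- SEM."""
    import pandas as pd

    rows = []
    for name, s in summaries.items():
        row: dict = {"recording": name}
        for st in STATE_ORDER:
            row[f"total_{st.lower()}_s"] = s.total_s[st]
            row[f"n_episodes_{st.lower()}"] = s.n_episodes[st]
            row[f"mean_episode_{st.lower()}_s"] = s.mean_episode_duration_s[st]
        for a, b in TRANSITION_PAIRS:
            row[f"transitions_{a[0]}{b[0]}".lower()] = s.transition_counts[(a, b)]
        row["wake_nrem_transitions"] = s.wake_nrem_transitions
        row["nrem_delta_power"] = s.nrem_delta_power
        rows.append(row)
    return pd.DataFrame(rows)
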