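"""Independent brute-force oracles used to cross-check the implementation.

These re-derive quantities from first principles with naive scans, sharing
no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def run_lengths(labels) -> list[tuple[int, int, str]]:
    """Naive per-second scan for maximal same-label runs: (onset, dur, label)."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i - start, str(labels[start])))
            start = i
    return runs


def state_bout_means(labels) -> dict[str, float]:
    """Mean bout duration per state from a naive run scan."""
    sums: dict[str, list[int]] = {}
    for _, dur, lab in run_lengths(labels):
        sums.setdefault(lab, []).append(dur)
    return {lab: float(np.mean(d)) for lab, d in sums.items()}


def direct_band_power(window: np.ndarray, fs: int, lo_hz: int, hi_hz: int) -> float:
    """One-sided discrete periodogram power summed over [lo_hz, hi_hz] bins,
    computed directly from the DFT definition on a mean-removed window."""
    x = np.asarray(window, float)
    x = x - x.mean()
    N = len(x)
    total = 0.0
    for f in range(lo_hz, hi_hz + 1):
        k = f * N // fs  # bin index at integer frequency
        c = np.sum(x * np.exp(-2j * np.pi * k * np.arange(N) / N))
        p = (abs(c) ** 2) / (N * N)
        if 0 < k < N // 2:
            p *= 2.0
        total += p
    return total


def brute_force_cataplexy(
    wake,
    qualifying,
    min_dur: int = 10,
    min_prior: int = 40,
    merge_gap: int = 2,
    gap_tol: int = 1,
) -> list[tuple[int, int, int]]:
    """Enumerate qualifying episodes by naive forward scanning.

    A candidate run extends while non-qualifying gaps stay shorter than
    ``merge_gap`` consecutive seconds; it must last >= ``min_dur`` and be
    preceded by a wake run (non-wake gaps of at most ``gap_tol`` consecutive
    seconds tolerated; reported as the span from earliest wake second to
    onset) of >= ``min_prior`` seconds.
    """
    wake = list(map(bool, wake))
    qualifying = list(map(bool, qualifying))
    n = len(wake)
    events = []
    s = 0
    while s < n:
        if not qualifying[s]:
            s += 1
            continue
        last_q = s
        gap = 0
        i = s
        while i < n:
            if qualifying[i]:
                last_q = i
                gap = 0
            else:
                gap += 1
                if gap >= merge_gap:
                    break
            i += 1
        e = last_q + 1
        if e - s >= min_dur:
            j = s - 1
            g = 0
            earliest = s
            while j >= 0:
                if wake[j]:
                    earliest = j
                    g = 0
                else:
                    g += 1
                    if g > gap_tol:
                        break
                j -= 1
            prior = s - earliest
            if prior >= min_prior:
                events.append((s, e - s, prior))
        s = e + 1
    return events
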