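"""Shared fixtures: synthetic recording batteries used across the suite.

The battery emulates the study conditions for the dark-phase experiments:
six narcoleptic (orexin-knockout-like) 3-h recordings per arm, fixed
seeds, with the drug arm applying a wake-bout x3 / cataplexy-hazard x0.2
effect.
"""

from __future__ import annotations

import numpy as np
import pytest

from oxsleep import (
    SimConfig,
    apply_drug_effect,
    hypnogram_from_track,
    score_recording,
    simulate_states,
    synthesize_signals,
)
from oxsleep.events import CataplexyParams, detect_cataplexy_in_recording
from oxsleep.sim import true_cataplexy_events
from oxsleep.spectral import epoch_features

BATTERY_SEEDS = (1, 2, 3, 4, 5, 6)
DRUG_WAKE_MULTIPLIER = 3.0
DRUG_HAZARD_MULTIPLIER = 0.2


def build_recording_set(config: SimConfig, seeds=BATTERY_SEEDS, score=True):
    """Simulate, synthesise and (optionally) score one arm of recordings."""
    out = []
    for seed in seeds:
        track = simulate_states(config, seed=seed)
        rec = synthesize_signals(track, config, seed=seed + 1000)
        item = {
            "seed": seed,
            "track": track,
            "recording": rec,
            "gt20": hypnogram_from_track(track, 20),
            "true_events": true_cataplexy_events(track),
        }
        if score:
            item["hyp20"] = score_recording(rec, 20)
            item["hyp4"] = score_recording(rec, 4)
            item["feats20"] = epoch_features(rec, 20)
            item["events"] = detect_cataplexy_in_recording(rec)
        out.append(item)
    return out


@pytest.fixture(scope="session")
def oxko_config() -> SimConfig:
    """Default narcoleptic dark-phase configuration, 3-h recordings."""
    return SimConfig(duration_s=10800.0)


@pytest.fixture(scope="session")
def battery(oxko_config):
    """Six vehicle-arm synthetic 3-h recordings, scored at 20 s and 4 s."""
    return build_recording_set(oxko_config)


@pytest.fixture(scope="session")
def drug_battery(oxko_config):
    """Seed-matched drug-arm recordings (wake bouts x3, hazard x0.2)."""
    cfg = apply_drug_effect(oxko_config, DRUG_WAKE_MULTIPLIER, DRUG_HAZARD_MULTIPLIER)
    return build_recording_set(cfg)


@pytest.fixture(scope="session")
def track_pairs(oxko_config):
    """Track-level vehicle/drug pairs (no signal synthesis), 6 seeds."""
    drug_cfg = apply_drug_effect(oxko_config, DRUG_WAKE_MULTIPLIER, DRUG_HAZARD_MULTIPLIER)
    pairs = []
    for seed in BATTERY_SEEDS:
        pairs.append(
            (
                simulate_states(oxko_config, seed=seed),
                simulate_states(drug_cfg, seed=seed),
            )
        )
    return pairs


def random_hypnogram(rng: np.random.Generator, n_epochs: int, epoch_len: float = 20.0):
    from oxsleep import Hypnogram
    from oxsleep.metrics import STATE_ORDER

    labels = rng.choice(np.array(STATE_ORDER, dtype="<U9"), size=n_epochs)
    return Hypnogram(epoch_len=epoch_len, labels=labels)
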