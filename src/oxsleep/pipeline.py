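"""End-to-end pipeline: recording -> features -> hypnogram -> events -> summary."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .events import CataplexyEvent, CataplexyParams, detect_cataplexy_in_recording
from .io import write_events_csv, write_hypnogram_csv
from .metrics import ArchitectureSummary, summarize, summary_frame
from .sim import Recording, SimConfig, simulate_recording
from .spectral import epoch_features, features_frame
from .staging import Hypnogram, StagingThresholds, score_recording


@dataclass(frozen=True)
class PipelineConfig:
    epoch_len_s: float = 20.0
    analysis_window_s: tuple[float, float] | None = (0.0, 10800.0)
    thresholds: StagingThresholds = field(default_factory=StagingThresholds)
    cataplexy: CataplexyParams = field(default_factory=CataplexyParams)
    sim: SimConfig | None = None
    seed: int = 0
    output_prefix: str | None = None

    def __post_init__(self) -> None:
        if self.epoch_len_s not in (20.0, 4.0, 20, 4):
            raise ValueError("epoch_len_s must be 20 or 4")
        if self.analysis_window_s is not None:
            a, b = self.analysis_window_s
            if not a < b:
                raise ValueError("analysis window start must precede end")


@dataclass(frozen=True)
class PipelineResult:
    hypnogram: Hypnogram
    events: list[CataplexyEvent]
    summary: ArchitectureSummary


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__") or hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, recording: Recording | None = None) -> PipelineResult:
    """Stage, detect and summarise one recording; persist products when
    ``output_prefix`` is set (hypnogram/events/features/summary CSVs plus a
    run manifest with config hash, seed and version)."""
    if recording is None:
        if config.sim is None:
            raise ValueError("pipeline: provide a recording or a sim config")
        _, recording = simulate_recording(config.sim, seed=config.seed)

    try:
        feats = epoch_features(recording, config.epoch_len_s)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'features' failed: {exc}") from exc
    try:
        hyp = score_recording(recording, config.epoch_len_s, config.thresholds)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'staging' failed: {exc}") from exc
    try:
        events = detect_cataplexy_in_recording(
            recording, config.thresholds, config.cataplexy
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'events' failed: {exc}") from exc

    window = config.analysis_window_s
    if window is not None:
        window = (window[0], min(window[1], hyp.span_s))
        # snap to the epoch grid
        L = hyp.epoch_len
        window = (window[0] // L * L, window[1] // L * L)
    try:
        summary = summarize(hyp, feats, window)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'metrics' failed: {exc}") from exc

    if config.output_prefix:
        prefix = Path(config.output_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_hypnogram_csv(f"{prefix}_hypnogram.csv", hyp)
        write_events_csv(f"{prefix}_events.csv", events)
        features_frame(feats).to_csv(f"{prefix}_features.csv", index=False)
        summary_frame({prefix.name: summary}).to_csv(f"{prefix}_summary.csv", index=False)
        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "oxsleep_version": __version__,
            "epoch_len_s": config.epoch_len_s,
            "n_epochs": hyp.n_epochs,
            "n_events": len(events),
        }
        with open(f"{prefix}_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    return PipelineResult(hypnogram=hyp, events=events, summary=summary)
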