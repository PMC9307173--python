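"""File I/O: EDF and CSV recordings, label tracks, hypnograms, events, configs.

EDF (European Data Format) is the de facto polysomnography container; the
writer here emits a plain EDF file with two signal channels labelled "EEG"
and "EMG" in microvolts, 1-s data records, 16-bit samples.  Reading goes
through MNE.  A documented CSV dialect (comment-line metadata header plus
``eeg_uv``/``emg_uv`` columns) serves as a text fallback for small files.
"""

from __future__ import annotations

import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .events import CataplexyEvent
from .sim import Recording, SimConfig, StateTrack, track_runs
from .staging import Hypnogram


class IOError_(ValueError):
    """Unreadable or malformed input file."""


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise IOError_(f"EDF header field too long: {s!r}")
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, recording: Recording) -> None:
    """Write a two-channel EDF file (EEG, EMG; uV; 1-s records, int16).

    A trailing fraction of a second is dropped (EDF records are whole
    seconds).  Physical scaling is symmetric about zero per channel, so
    quantisation error is bounded by physmax / 32767.
    """
    fs = int(recording.sampling_rate)
    n_rec = len(recording.eeg) // fs
    if n_rec == 0:
        raise IOError_("recording shorter than one EDF record (1 s)")
    channels = [("EEG", recording.eeg[: n_rec * fs]), ("EMG", recording.emg[: n_rec * fs])]

    start_h = recording.zt_origin % 24
    hh, mm = int(start_h), int((start_h % 1) * 60)
    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X X X X", 80),
            _edf_field("01.01.01", 8),
            _edf_field(f"{hh:02d}.{mm:02d}.00", 8),
            _edf_field(256 * (1 + len(channels)), 8),
            _edf_field("", 44),
            _edf_field(n_rec, 8),
            _edf_field("1", 8),
            _edf_field(len(channels), 4),
        ]
    )

    phys_max = []
    digitized = []
    for _, x in channels:
        m = float(np.max(np.abs(x))) if len(x) else 1.0
        m = max(m, 1e-6)
        phys_max.append(m)
        d = np.clip(np.round(x / m * 32767.0), -32768, 32767).astype("<i2")
        digitized.append(d.reshape(n_rec, fs))

    def sig_fields(width: int, values) -> bytes:
        return b"".join(_edf_field(v, width) for v in values)

    sig_header = b"".join(
        [
            sig_fields(16, [name for name, _ in channels]),
            sig_fields(80, ["" for _ in channels]),
            sig_fields(8, ["uV" for _ in channels]),
            sig_fields(8, [f"{-m:.6g}"[:8] for m in phys_max]),
            sig_fields(8, [f"{m:.6g}"[:8] for m in phys_max]),
            sig_fields(8, ["-32768" for _ in channels]),
            sig_fields(8, ["32767" for _ in channels]),
            sig_fields(80, ["" for _ in channels]),
            sig_fields(8, [fs for _ in channels]),
            sig_fields(32, ["" for _ in channels]),
        ]
    )

    records = np.concatenate(
        [np.stack([d[r] for d in digitized]).reshape(-1) for r in range(n_rec)]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(records.tobytes())


def _read_edf(path: Path, zt_origin: float | None) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = {n.upper(): n for n in raw.ch_names}
    eeg_name = next((names[k] for k in names if "EEG" in k), None)
    emg_name = next((names[k] for k in names if "EMG" in k), None)
    if eeg_name is None or emg_name is None:
        raise IOError_("EDF must contain channels identifiable as EEG and EMG")
    data = raw.get_data(picks=[eeg_name, emg_name]) * 1e6  # V -> uV
    if zt_origin is None:
        t = raw.info.get("meas_date")
        zt_origin = (t.hour + t.minute / 60.0) if t is not None else 0.0
    return Recording(
        eeg=data[0], emg=data[1], sampling_rate=float(raw.info["sfreq"]), zt_origin=zt_origin
    )


def write_recording_csv(path: str | Path, recording: Recording) -> None:
    """CSV dialect: '# key=value' metadata lines, then eeg_uv,emg_uv columns."""
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={recording.sampling_rate:g}\n")
        fh.write(f"# zt_origin_h={recording.zt_origin:g}\n")
        fh.write("eeg_uv,emg_uv\n")
        np.savetxt(fh, np.column_stack([recording.eeg, recording.emg]), fmt="%.6g", delimiter=",")


def _read_recording_csv(path: Path, zt_origin: float | None) -> Recording:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
    if "sampling_rate_hz" not in meta:
        raise IOError_("CSV recording missing '# sampling_rate_hz=' metadata line")
    df = pd.read_csv(path, comment="#")
    for col in ("eeg_uv", "emg_uv"):
        if col not in df.columns:
            raise IOError_(f"CSV recording missing channel column {col!r}")
    return Recording(
        eeg=df["eeg_uv"].to_numpy(float),
        emg=df["emg_uv"].to_numpy(float),
        sampling_rate=float(meta["sampling_rate_hz"]),
        zt_origin=zt_origin if zt_origin is not None else float(meta.get("zt_origin_h", 0.0)),
    )


def read_recording(path: str | Path, fmt: str | None = None, zt_origin: float | None = None) -> Recording:
    """Load a two-channel EEG/EMG recording from EDF or the CSV dialect."""
    path = Path(path)
    if not path.is_file() or path.stat().st_size == 0:
        raise IOError_(f"unreadable or empty file: {path}")
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    try:
        if fmt.lower() == "edf":
            return _read_edf(path, zt_origin)
        return _read_recording_csv(path, zt_origin)
    except IOError_:
        raise
    except Exception as exc:  # noqa: BLE001 - surface as a typed I/O error
        raise IOError_(f"failed to read {path}: {exc}") from exc


def write_statetrack_csv(path: str | Path, track: StateTrack) -> None:
    rows = track_runs(track.labels)
    pd.DataFrame(rows, columns=["onset_s", "duration_s", "state"]).to_csv(path, index=False)


def read_statetrack_csv(path: str | Path, zt_origin: float = 12.0) -> StateTrack:
    df = pd.read_csv(path)
    labels = np.concatenate(
        [np.repeat(r.state, int(r.duration_s)) for r in df.itertuples()]
    )
    return StateTrack(labels=labels.astype("<U9"), zt_origin=zt_origin)


def write_hypnogram_csv(path: str | Path, hyp: Hypnogram) -> None:
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(hyp.n_epochs),
            "onset_s": np.arange(hyp.n_epochs) * hyp.epoch_len,
            "epoch_len_s": hyp.epoch_len,
            "state": hyp.labels,
        }
    )
    df.to_csv(path, index=False)


def read_hypnogram_csv(path: str | Path, zt_origin: float = 12.0) -> Hypnogram:
    df = pd.read_csv(path)
    if df.empty:
        raise IOError_(f"empty hypnogram file: {path}")
    return Hypnogram(
        epoch_len=float(df["epoch_len_s"].iloc[0]),
        labels=df["state"].to_numpy(dtype="<U9"),
        zt_origin=zt_origin,
    )


def write_events_csv(path: str | Path, events: list[CataplexyEvent]) -> None:
    pd.DataFrame(
        [{"onset_s": e.onset_s, "duration_s": e.duration_s, "prior_wake_s": e.prior_wake_s} for e in events]
    ).to_csv(path, index=False)


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        elif isinstance(v, (list, tuple)):
            out[key] = ",".join(str(x) for x in v)
        else:
            out[key] = v
    return out


def write_sim_config(path: str | Path, config: SimConfig) -> None:
    """Flat key=value text serialisation (dotted keys for nested maps)."""
    flat = _flatten(asdict(config))
    with open(path, "w") as fh:
        for k, v in flat.items():
            fh.write(f"{k} = {v}\n")


def read_sim_config(path: str | Path) -> SimConfig:
    flat: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            flat[key.strip()] = val.strip()

    nested: dict = {}
    for k, v in flat.items():
        parts = k.split(".")
        d = nested
        for p in parts[:-1]:
            d = d.setdefault(p, {})
        d[parts[-1]] = v

    def conv(value):
        if isinstance(value, dict):
            return {k: conv(v) for k, v in value.items()}
        s = str(value)
        if "," in s:
            return tuple(float(x) for x in s.split(","))
        parsed = yaml.safe_load(s)
        if isinstance(parsed, str) and parsed.lower() in ("inf", "infinity"):
            return math.inf
        return parsed

    kwargs = {k: conv(v) for k, v in nested.items()}
    return SimConfig(**kwargs)
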