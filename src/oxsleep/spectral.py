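"""Per-epoch EEG spectral features and EMG amplitude features.

EEG power is computed by FFT from 1 to 30 Hz with a 1-Hz bin: within each
epoch the signal is cut into non-overlapping 1-s rectangular windows, each
window is mean-detrended, and the discrete periodograms are averaged, which
gives exactly 1-Hz frequency resolution.  Named bands are delta (1-4 Hz),
theta (6-9 Hz) and fast (10-30 Hz) activity; 5 Hz is deliberately in
neither delta nor theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sim import Recording

DELTA_BINS = (1, 4)
THETA_BINS = (6, 9)
FAST_BINS = (10, 30)
_BAND_SLICES = {"delta": DELTA_BINS, "theta": THETA_BINS, "fast": FAST_BINS}


class SpectralError(ValueError):
    pass


@dataclass(frozen=True)
class EpochFeatures:
    """Spectral and EMG features of one scoring epoch.

    ``power_bins[f-1]`` is EEG power (uV^2) in the 1-Hz bin at f Hz for
    f = 1..30; band powers are sums of their constituent bins.
    """

    epoch_index: int
    epoch_len: float
    power_bins: np.ndarray  # 30 values, 1..30 Hz
    delta_power: float
    theta_power: float
    fast_power: float
    emg_rms: float
    emg_var: float

    @property
    def total_power(self) -> float:
        return float(self.power_bins.sum())

    def band(self, name: str) -> float:
        lo, hi = _BAND_SLICES[name]
        return float(self.power_bins[lo - 1 : hi].sum())


def _epoch_power_matrix(eeg: np.ndarray, fs: int, epoch_len: int, n_epochs: int) -> np.ndarray:
    """Mean 1-s periodogram per epoch; returns (n_epochs, 30) powers 1..30 Hz."""
    n_windows = n_epochs * epoch_len
    wins = eeg[: n_windows * fs].reshape(n_windows, fs)
    wins = wins - wins.mean(axis=1, keepdims=True)
    # 1-s rectangular window -> exactly 1-Hz spaced FFT bins; one-sided power.
    spec = np.fft.rfft(wins, axis=1)
    power = (np.abs(spec) ** 2) / (fs * fs)
    power[:, 1:-1] *= 2.0
    per_window = power[:, 1:31]  # bins at 1..30 Hz
    return per_window.reshape(n_epochs, epoch_len, 30).mean(axis=1)


def epoch_features(recording: Recording, epoch_len: float) -> list[EpochFeatures]:
    """Tile a recording into half-open epochs and compute features per epoch.

    A trailing partial epoch is dropped.  EMG RMS and variance are taken
    over the raw epoch samples.
    """
    epoch_len = int(epoch_len)
    if epoch_len < 1:
        raise SpectralError("epoch_len must be a positive whole number of seconds")
    fs = int(recording.sampling_rate)
    n_epochs = len(recording.eeg) // (epoch_len * fs)
    if n_epochs == 0:
        raise SpectralError("recording shorter than one epoch")

    band_power = _epoch_power_matrix(recording.eeg, fs, epoch_len, n_epochs)
    emg = recording.emg[: n_epochs * epoch_len * fs].reshape(n_epochs, epoch_len * fs)
    emg_rms = np.sqrt(np.mean(emg**2, axis=1))
    emg_var = np.var(emg, axis=1)

    out = []
    for k in range(n_epochs):
        bins = band_power[k]
        out.append(
            EpochFeatures(
                epoch_index=k,
                epoch_len=float(epoch_len),
                power_bins=bins,
                delta_power=float(bins[DELTA_BINS[0] - 1 : DELTA_BINS[1]].sum()),
                theta_power=float(bins[THETA_BINS[0] - 1 : THETA_BINS[1]].sum()),
                fast_power=float(bins[FAST_BINS[0] - 1 : FAST_BINS[1]].sum()),
                emg_rms=float(emg_rms[k]),
                emg_var=float(emg_var[k]),
            )
        )
    return out


def band_ratio(features: EpochFeatures, numerator_band: str, denominator_band: str) -> float:
    """Ratio of two named band powers (delta, theta, fast)."""
    num = features.band(numerator_band)
    den = features.band(denominator_band)
    if den <= 0:
        raise SpectralError("denominator band power is zero; ratio undefined")
    return num / den


def features_frame(features: list[EpochFeatures]):
    """Features as a pandas DataFrame (one row per epoch), for CSV export."""
    import pandas as pd

    rows = []
    for f in features:
        row = {
            "epoch_index": f.epoch_index,
            "epoch_len_s": f.epoch_len,
            "delta_power": f.delta_power,
            "theta_power": f.theta_power,
            "fast_power": f.fast_power,
            "emg_rms": f.emg_rms,
            "emg_var": f.emg_var,
        }
        row.update({f"power_{hz}hz": f.power_bins[hz - 1] for hz in range(1, 31)})
        rows.append(row)
    return pd.DataFrame(rows)
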