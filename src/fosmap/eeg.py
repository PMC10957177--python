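"""Anesthesia-depth metrics from EEG/EMG.

The depth readout is the ratio of EEG delta-band power (0.5-4 Hz) to
theta-band power (6-10 Hz), computed per non-overlapping 5-s epoch from
a Hann-tapered periodogram zero-padded to a frequency resolution of at
most 0.18 Hz, plus the EMG power per epoch.  Post-administration epochs
are normalized to a pre-administration baseline window as a log2 ratio.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "DELTA_BAND",
    "THETA_BAND",
    "band_power",
    "delta_theta_ratio",
    "spectral_series",
    "baseline_normalize",
]

logger = logging.getLogger(__name__)

DELTA_BAND = (0.5, 4.0)
THETA_BAND = (6.0, 10.0)
EPOCH_SECONDS = 5.0


def _epochs(x: np.ndarray, fs: float, epoch: float) -> tuple[np.ndarray, np.ndarray]:
    length = int(round(fs * epoch))
    n_ep = len(x) // length
    if n_ep * length != len(x):
        logger.warning("dropping %d trailing sample(s) shorter than one epoch", len(x) - n_ep * length)
    starts = np.arange(n_ep) * epoch
    return x[: n_ep * length].reshape(n_ep, length), starts


def band_power(
    x,
    fs: float,
    band: tuple[float, float],
    epoch: float = EPOCH_SECONDS,
    resolution: float = 0.18,
) -> pd.Series:
    """Integrated power in ``band`` per epoch (index = epoch start, s).

    Each epoch gets a Hann-tapered periodogram zero-padded so the bin
    width is at most *resolution*; the band sums PSD bins whose centers
    lie in [low, high).
    """
    low, high = band
    if fs <= 2 * high:
        raise ValueError(f"sampling rate {fs} Hz too low for the {low}-{high} Hz band")
    x = np.asarray(x, dtype=float)
    segs, starts = _epochs(x, fs, epoch)
    if segs.shape[0] == 0:
        raise ValueError("signal shorter than one epoch")
    nfft = max(segs.shape[1], int(np.ceil(fs / resolution)))
    freqs, psd = signal.periodogram(segs, fs=fs, window="hann", nfft=nfft, detrend=False, axis=1)
    sel = (freqs >= low) & (freqs < high)
    df = freqs[1] - freqs[0]
    power = psd[:, sel].sum(axis=1) * df
    return pd.Series(power, index=pd.Index(starts, name="epoch_start"), name="power")


def delta_theta_ratio(
    eeg,
    fs: float,
    epoch: float = EPOCH_SECONDS,
    resolution: float = 0.18,
) -> pd.DataFrame:
    """Per-epoch delta (0.5-4 Hz) and theta (6-10 Hz) power and their
    ratio; the ratio is missing where theta power is 0."""
    delta = band_power(eeg, fs, DELTA_BAND, epoch=epoch, resolution=resolution)
    theta = band_power(eeg, fs, THETA_BAND, epoch=epoch, resolution=resolution)
    out = pd.DataFrame({"delta": delta, "theta": theta})
    out["delta_theta_ratio"] = out["delta"] / out["theta"].where(out["theta"] > 0)
    return out


def spectral_series(
    eeg,
    emg=None,
    fs: float = 200.0,
    epoch: float = EPOCH_SECONDS,
    resolution: float = 0.18,
) -> pd.DataFrame:
    """Full epoched summary: delta, theta, delta/theta ratio, and (if an
    EMG channel is given) mean-square EMG power per epoch."""
    out = delta_theta_ratio(eeg, fs, epoch=epoch, resolution=resolution)
    if emg is not None:
        segs, starts = _epochs(np.asarray(emg, dtype=float), fs, epoch)
        out = out.iloc[: len(starts)]
        out["emg_power"] = np.mean(segs**2, axis=1)[: len(out)]
    return out


def baseline_normalize(
    series: pd.Series,
    baseline_window: float = 300.0,
    t0: float = 0.0,
    mode: str = "log2",
) -> pd.Series:
    """Normalize an epoch-indexed power series to the pre-*t0* baseline.

    The baseline is the mean over epochs starting in
    [t0 - baseline_window, t0).  ``mode="log2"`` (default) returns
    log2(value / baseline mean); ``mode="fraction"`` returns
    value / baseline mean - 1.  A non-positive baseline mean is an
    error.
    """
    if mode not in ("log2", "fraction"):
        raise ValueError("mode must be 'log2' or 'fraction'")
    t = series.index.to_numpy(dtype=float)
    base = series[(t >= t0 - baseline_window) & (t < t0)]
    if base.empty:
        raise ValueError("no baseline epochs before t0")
    ref = float(base.mean())
    if ref <= 0:
        raise ValueError("baseline mean must be > 0")
    if mode == "log2":
        return np.log2(series / ref)
    return series / ref - 1.0
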