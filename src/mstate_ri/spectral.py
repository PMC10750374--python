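"""Welch spectral estimation and canonical band-power summaries.

Estimation is backed by ``scipy.signal.welch`` (Hamming window, one-sided
density, window-power normalized so white-noise density is unbiased).
When the input is epoched, segments never cross epoch boundaries: each
epoch contributes its own Welch segments and the periodograms of all
segments of all retained epochs are averaged.

Band powers are the dB of the mean in-band density per channel,
10*log10(V^2/Hz); whole-brain values average the per-channel dB values.
Band bins are half-open [low, high).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InvalidParameterError
from .io_preprocess import Epochs, Recording


@dataclass(frozen=True)
class WelchConfig:
    segment_length_samples: int = 1024
    overlap_samples: int = 512
    window: str = "hamming"
    fs_hz: float | None = None  # taken from the data when None

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_samples < self.segment_length_samples:
            raise InvalidParameterError("need 0 <= overlap < segment length")

    def n_segments(self, n_samples: int) -> int:
        """K = floor((N - M) / (M - D)) + 1."""
        m, d = self.segment_length_samples, self.overlap_samples
        if n_samples < m:
            return 0
        return (n_samples - m) // (m - d) + 1


@dataclass
class PsdEstimate:
    freqs_hz: np.ndarray
    power: np.ndarray  # channel x frequency, V^2/Hz
    n_segments: int

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(self.power < -1e-12):
            raise InvalidParameterError("PSD must be nonnegative")

    @property
    def df_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])

    def total_power(self) -> np.ndarray:
        """Per-channel integral of the density (trapezoid-free Riemann sum)."""
        return self.power.sum(axis=1) * self.df_hz

    def band_integral(self, low_hz: float, high_hz: float) -> np.ndarray:
        sel = (self.freqs_hz >= low_hz) & (self.freqs_hz < high_hz)
        return self.power[:, sel].sum(axis=1) * self.df_hz


#: delta..gamma2 scheme; the 45-55 Hz gap skips the mains region.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha1": (8.0, 10.0),
    "alpha2": (10.0, 13.0),
    "beta1": (13.0, 18.0),
    "beta2": (18.0, 21.0),
    "beta3": (21.0, 30.0),
    "gamma1": (30.0, 45.0),
    "gamma2": (55.0, 100.0),
}


@dataclass(frozen=True)
class BandScheme:
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise InvalidParameterError(f"band {name}: need low < high")

    @property
    def names(self) -> list[str]:
        return list(self.bands)


@dataclass
class BandPowerTable:
    """Per channel x band dB values plus the whole-brain summary."""

    channel_db: pd.DataFrame  # index channel, columns band names
    whole_brain_db: pd.Series  # per band, mean of channel dB


def welch_psd(data: Recording | Epochs, cfg: WelchConfig | None = None) -> PsdEstimate:
    """One-sided Welch density per channel; epochs averaged segment-wise."""
    cfg = cfg or WelchConfig()
    m, d = cfg.segment_length_samples, cfg.overlap_samples
    if isinstance(data, Recording):
        blocks = [data.data]
        fs = cfg.fs_hz or data.fs_hz
    else:
        blocks = list(data.retained)
        fs = cfg.fs_hz or data.fs_hz
        if not blocks:
            raise InvalidParameterError("no retained epochs")
    total_k = sum(cfg.n_segments(b.shape[1]) for b in blocks)
    if total_k == 0:
        raise InvalidParameterError(
            f"segment length {m} exceeds available data")
    acc = None
    freqs = None
    for block in blocks:
        k = cfg.n_segments(block.shape[1])
        if k == 0:
            continue
        freqs, pxx = signal.welch(block, fs=fs, window=cfg.window,
                                  nperseg=m, noverlap=d, detrend=False,
                                  scaling="density", axis=-1)
        contrib = pxx * k
        acc = contrib if acc is None else acc + contrib
    return PsdEstimate(freqs, acc / total_k, total_k)


def band_power(psd: PsdEstimate, scheme: BandScheme | None = None) -> BandPowerTable:
    """Mean in-band density per channel, in dB; bins are [low, high)."""
    scheme = scheme or BandScheme()
    fmax = psd.freqs_hz[-1]
    cols = {}
    for name, (lo, hi) in scheme.bands.items():
        if lo < psd.freqs_hz[0] - psd.df_hz or hi > fmax + psd.df_hz:
            raise InvalidParameterError(
                f"band {name} ({lo}-{hi} Hz) outside PSD grid (0-{fmax} Hz)")
        sel = (psd.freqs_hz >= lo) & (psd.freqs_hz < hi)
        if not sel.any():
            raise InvalidParameterError(f"band {name} contains no PSD bin")
        mean_density = psd.power[:, sel].mean(axis=1)
        with np.errstate(divide="ignore"):
            cols[name] = 10.0 * np.log10(mean_density)
    channel_db = pd.DataFrame(cols)
    return BandPowerTable(channel_db, channel_db.mean(axis=0))


def band_table_per_subject(recordings: dict[tuple[str, str, str], Recording | Epochs],
                           cfg: WelchConfig | None = None,
                           scheme: BandScheme | None = None) -> pd.DataFrame:
    """Long-form (subject, group, condition, band, db) table.

    ``recordings`` maps (subject_id, group, condition) to preprocessed
    data. Rows with non-finite dB (all-zero input) are excluded with a
    warning column in the log; ordering is deterministic.
    """
    import logging

    scheme = scheme or BandScheme()
    rows = []
    for (subject, group, condition) in sorted(recordings):
        data = recordings[(subject, group, condition)]
        table = band_power(welch_psd(data, cfg), scheme)
        for band in scheme.names:
            db = float(table.whole_brain_db[band])
            if not np.isfinite(db):
                logging.getLogger(__name__).warning(
                    "excluding %s/%s/%s band %s: undefined dB",
                    subject, group, condition, band)
                continue
            rows.append((subject, group, condition, band, db))
    return pd.DataFrame(rows, columns=["subject", "group", "condition",
                                       "band", "db"])
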