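"""Recording I/O and the deterministic preprocessing chain.

Chain (in pipeline order): resample to 512 Hz, zero-phase FIR band-pass
0.5-100 Hz with 50/100 Hz notches, average reference, 2-s epochs with a
+/-100 uV amplitude rejection rule. A separate 2-20 Hz band-pass feeds
the microstate stage. Everything here is deterministic.

Recordings travel as TSV matrices (channels x samples, one row per
channel, first column the channel label) with a ``# fs_hz=<rate>``
header line. This build has no EDF backend; see ``read_recording``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .errors import (
    DimensionError,
    EmptyResultError,
    FormatError,
    InvalidParameterError,
)
from .montage import Montage

logger = logging.getLogger(__name__)


@dataclass
class Recording:
    """Channel x sample potential matrix in microvolts."""

    data: np.ndarray
    fs_hz: float
    montage: Montage
    annotations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DimensionError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise DimensionError(
                f"data has {self.data.shape[0]} channels, montage has "
                f"{self.montage.n_channels}")
        if not np.all(np.isfinite(self.data)):
            raise InvalidParameterError("data must be finite")
        if not self.fs_hz > 0:
            raise InvalidParameterError("fs_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def annotated(self, note: str) -> "Recording":
        return replace(self, annotations=[*self.annotations, note])


@dataclass
class Epochs:
    """Fixed-length consecutive epochs with a rejection mask.

    ``rejection_mask[i]`` is True when epoch ``i`` was rejected;
    ``rejection_reasons[i]`` holds the reason code (empty if retained).
    """

    data: np.ndarray  # epoch x channel x sample, all epochs (incl. rejected)
    fs_hz: float
    epoch_length_s: float
    rejection_mask: np.ndarray
    rejection_reasons: list[str]
    montage: Montage | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.rejection_mask = np.asarray(self.rejection_mask, dtype=bool)
        if self.data.ndim != 3:
            raise DimensionError("epochs data must be 3-D")
        if self.rejection_mask.shape != (self.data.shape[0],):
            raise DimensionError("rejection mask length mismatch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_retained(self) -> int:
        return int((~self.rejection_mask).sum())

    @property
    def retained(self) -> np.ndarray:
        return self.data[~self.rejection_mask]


# ---------------------------------------------------------------------------
# I/O

def write_recording(path: str | Path, rec: Recording) -> Path:
    """Write a recording as a labeled TSV matrix with a fs header line."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        raise FormatError(
            "this build has no EDF backend (text formats only); use .tsv")
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={rec.fs_hz!r}\n")
        for name, row in zip(rec.montage.channel_names, rec.data):
            fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    return path


def read_recording(path: str | Path, montage: Montage) -> Recording:
    """Read a TSV recording, dropping channels unknown to ``montage``.

    Dropped channels are logged, mirroring removal of irrelevant
    electrodes; the output channel order follows the file, not the
    montage.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        raise FormatError(
            "this build has no EDF backend (text formats only); use .tsv")
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fs_hz = None
    names: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "fs_hz=" in line:
                    fs_hz = float(line.split("fs_hz=", 1)[1].strip())
                continue
            parts = line.split("\t")
            names.append(parts[0])
            rows.append(np.array(parts[1:], dtype=float))
    if fs_hz is None or not rows:
        raise IOError(f"unreadable or empty recording file: {path}")
    keep = [i for i, n in enumerate(names) if n in montage.channel_names]
    dropped = [n for n in names if n not in montage.channel_names]
    if not keep:
        raise FormatError(f"no channel of {path} matches the montage")
    if dropped:
        logger.warning("dropping %d channel(s) not in montage: %s",
                       len(dropped), ", ".join(dropped))
    sub = montage.subset([names[i] for i in keep])
    rec = Recording(np.vstack([rows[i] for i in keep]), fs_hz, sub)
    if dropped:
        rec = rec.annotated(f"dropped channels: {','.join(dropped)}")
    return rec


# ---------------------------------------------------------------------------
# Preprocessing operations

def resample(rec: Recording, target_fs_hz: float) -> Recording:
    """Polyphase resampling with built-in anti-alias filtering."""
    if not target_fs_hz > 0:
        raise InvalidParameterError("target_fs_hz must be positive")
    if target_fs_hz == rec.fs_hz:
        return rec
    from fractions import Fraction

    frac = Fraction(target_fs_hz / rec.fs_hz).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator,
                                axis=1)
    out = replace(rec, data=data, fs_hz=target_fs_hz)
    return out.annotated(f"resampled {rec.fs_hz} -> {target_fs_hz} Hz")


def _fir_bandpass(low_hz: float, high_hz: float, fs_hz: float) -> np.ndarray:
    # windowed-sinc, Hamming; order = 3.3 * fs / transition width
    trans = max(min(low_hz * 0.5, 2.0), 0.5)
    numtaps = int(np.ceil(3.3 * fs_hz / trans)) | 1
    return signal.firwin(numtaps, [low_hz, high_hz], pass_zero=False,
                         fs=fs_hz, window="hamming")


def _fir_notch(notch_hz: float, fs_hz: float, half_width_hz: float = 2.0) -> np.ndarray:
    trans = 1.0
    numtaps = int(np.ceil(3.3 * fs_hz / trans)) | 1
    lo = max(notch_hz - half_width_hz, 0.1)
    hi = min(notch_hz + half_width_hz, fs_hz / 2 * 0.999)
    return signal.firwin(numtaps, [lo, hi], pass_zero=True, fs=fs_hz,
                         window="hamming")


def _zero_phase(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric odd-length FIR with zero phase (centered FFT conv).

    Edges are odd-reflection padded to suppress filter ringing at the
    recording boundaries.
    """
    from scipy import fft as sfft

    n = data.shape[-1]
    pad = min(len(taps), n - 1)
    left = 2.0 * data[..., :1] - data[..., 1:pad + 1][..., ::-1]
    right = 2.0 * data[..., -1:] - data[..., -pad - 1:-1][..., ::-1]
    ext = np.concatenate([left, data, right], axis=-1)
    n_ext = ext.shape[-1]
    nfft = sfft.next_fast_len(n_ext + len(taps) - 1)
    spec = sfft.rfft(ext, nfft, axis=-1) * sfft.rfft(taps, nfft)
    full = sfft.irfft(spec, nfft, axis=-1)
    centered = full[..., (len(taps) - 1) // 2:]  # zero phase: undo group delay
    return centered[..., pad:pad + n]


def filter_band(rec: Recording, low_hz: float, high_hz: float,
                notch_hz: list[float] | None = None) -> Recording:
    """Zero-phase FIR band-pass with optional band-stop notches.

    The per-channel mean is removed first (the high-pass edge discards
    DC anyway; doing it exactly avoids residual offset leakage).
    """
    nyq = rec.fs_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise InvalidParameterError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({nyq})")
    for f0 in notch_hz or []:
        if not 0 < f0 < nyq:
            raise InvalidParameterError(f"notch {f0} Hz outside (0, Nyquist)")
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    data = _zero_phase(data, _fir_bandpass(low_hz, high_hz, rec.fs_hz))
    for f0 in notch_hz or []:
        data = _zero_phase(data, _fir_notch(f0, rec.fs_hz))
    out = replace(rec, data=data)
    notches = f", notches {notch_hz}" if notch_hz else ""
    return out.annotated(f"band-pass {low_hz}-{high_hz} Hz{notches}")


def rereference_average(rec: Recording) -> Recording:
    """Subtract the instantaneous across-channel mean from every sample."""
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data).annotated("average reference")


def epoch_and_reject(rec: Recording, epoch_length_s: float = 2.0,
                     threshold_uv: float = 100.0) -> Epochs:
    """Cut consecutive epochs; reject any epoch with |v| > threshold.

    A trailing partial epoch is discarded.
    """
    if not threshold_uv > 0:
        raise InvalidParameterError("threshold_uv must be positive")
    ns = int(round(epoch_length_s * rec.fs_hz))
    n_epochs = rec.n_samples // ns
    if n_epochs < 1:
        raise EmptyResultError(
            f"recording ({rec.duration_s:.3f} s) shorter than one epoch "
            f"({epoch_length_s} s)")
    data = rec.data[:, : n_epochs * ns]
    epochs = np.transpose(data.reshape(rec.n_channels, n_epochs, ns), (1, 0, 2))
    peak = np.abs(epochs).max(axis=(1, 2))
    mask = peak > threshold_uv
    reasons = [f"amplitude {p:.1f} uV > {threshold_uv:.1f} uV" if m else ""
               for p, m in zip(peak, mask)]
    logger.info("epoching: %d epochs, %d rejected (threshold %.1f uV)",
                n_epochs, int(mask.sum()), threshold_uv)
    return Epochs(epochs, rec.fs_hz, epoch_length_s, mask, reasons,
                  montage=rec.montage)


def preprocess(rec: Recording, target_fs_hz: float = 512.0,
               band: tuple[float, float] = (0.5, 100.0),
               notches: tuple[float, ...] = (50.0, 100.0)) -> Recording:
    """Standard chain: resample, band-pass + notches, average reference."""
    rec = resample(rec, target_fs_hz)
    notch_ok = [f for f in notches if f < target_fs_hz / 2]
    high = min(band[1], target_fs_hz / 2 * 0.98)
    rec = filter_band(rec, band[0], high, notch_ok)
    return rereference_average(rec)
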