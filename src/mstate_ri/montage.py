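"""Electrode montages on the unit sphere.

The standard montage uses 10-10 extension labels laid out on the usual
9 x 9 anterior-posterior / left-right grid and projected onto the unit
sphere with Cz at the pole (azimuthal equidistant scheme, outer ring at
90 degrees polar angle). Positions are montage metadata: no analysis
operation consumes them, but invariants (unique labels, unit norm) are
enforced so downstream I/O can rely on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

# row letter -> anterior(+)/posterior(-) grid index
_ROWS = [
    ("Fp", 4.0),
    ("AF", 3.0),
    ("F", 2.0),
    ("FC", 1.0),
    ("C", 0.0),
    ("CP", -1.0),
    ("P", -2.0),
    ("PO", -3.0),
    ("O", -4.0),
]

# columns present per row in the 60-channel cap (left..right);
# 'z' is midline, odd numbers left, even numbers right
_ROW_COLUMNS = {
    "Fp": ["1", "z", "2"],
    "AF": ["7", "3", "4", "8"],  # AFz omitted to land on 60 channels
    "F": ["7", "5", "3", "1", "z", "2", "4", "6", "8"],
    "FC": ["FT7", "5", "3", "1", "z", "2", "4", "6", "FT8"],
    "C": ["T7", "5", "3", "1", "z", "2", "4", "6", "T8"],
    "CP": ["TP7", "5", "3", "1", "z", "2", "4", "6", "TP8"],
    "P": ["7", "5", "3", "1", "z", "2", "4", "6", "8"],
    "PO": ["7", "3", "z", "4", "8"],
    "O": ["1", "z", "2"],
}

_COL_X = {"z": 0.0, "1": -1.0, "2": 1.0, "3": -2.0, "4": 2.0,
          "5": -3.0, "6": 3.0, "7": -4.0, "8": 4.0}


def _grid_to_sphere(x: float, y: float) -> np.ndarray:
    """Map grid coordinates (4 grid units = 90 deg polar) to a unit vector."""
    r = float(np.hypot(x, y))
    theta = min(r, 4.0) / 4.0 * (np.pi / 2.0)
    phi = np.arctan2(x, y) if r > 0 else 0.0
    return np.array([np.sin(theta) * np.sin(phi),
                     np.sin(theta) * np.cos(phi),
                     np.cos(theta)])


def _standard_positions() -> tuple[list[str], np.ndarray]:
    names: list[str] = []
    pos: list[np.ndarray] = []
    for row, y in _ROWS:
        for col in _ROW_COLUMNS[row]:
            if len(col) > 1:
                # temporal chain (T7/T8, FT7/8, TP7/8) sits on the outer ring
                name = col
                x = -4.0 if col.endswith("7") else 4.0
            else:
                name = f"{row}{col}"
                x = _COL_X[col]
            names.append(name)
            pos.append(_grid_to_sphere(x, y))
    return names, np.asarray(pos)


@dataclass(frozen=True)
class Montage:
    """Named electrode set with unit-sphere positions."""

    channel_names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(names) < 2:
            raise InvalidParameterError("montage needs at least 2 channels")
        if len(set(names)) != len(names):
            raise InvalidParameterError("montage channel names must be unique")
        if pos.shape != (len(names), 3):
            raise InvalidParameterError(
                f"positions must be ({len(names)}, 3), got {pos.shape}")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise InvalidParameterError("positions must have unit norm")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def subset(self, names: list[str]) -> "Montage":
        idx = [self.channel_names.index(n) for n in names]
        return Montage(tuple(names), self.positions[idx])


def standard_montage(n_channels: int = 60) -> Montage:
    """Idealized 10-10 montage; ``n_channels`` must be <= 60.

    Smaller counts take an evenly spaced subset, preserving scalp spread.
    """
    names, pos = _standard_positions()
    if n_channels > len(names):
        raise InvalidParameterError(
            f"standard montage has {len(names)} channels, requested {n_channels}")
    if n_channels < 2:
        raise InvalidParameterError("n_channels must be >= 2")
    if n_channels == len(names):
        idx = np.arange(len(names))
    else:
        idx = np.unique(np.round(np.linspace(0, len(names) - 1, n_channels)).astype(int))
        # rounding collisions are impossible for n <= 60 over 60 slots, but be safe
        while len(idx) < n_channels:
            missing = np.setdiff1d(np.arange(len(names)), idx)
            idx = np.sort(np.r_[idx, missing[: n_channels - len(idx)]])
    return Montage(tuple(names[i] for i in idx), pos[idx])
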