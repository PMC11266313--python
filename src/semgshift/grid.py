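"""Electrode-grid geometry and channel indexing.

All spatial layout logic lives here: the rectangular HD-sEMG grid (10 mm
inter-electrode pitch), the bijective map between flat channel indices and
(row, col) positions, and the four shift directions used to build interleaved
train/test channel splits.

Channels are numbered 0-based in row-major order against the physical grid
(row 0 at the top). This ordering is a package convention, not a property of
any particular acquisition device; adapters for real recordings can remap via
``channel_order``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridError", "ElectrodeGrid", "ShiftDirection", "make_grid"]


class GridError(ValueError):
    """Invalid grid geometry or an operation incompatible with it."""


class ShiftDirection(str, enum.Enum):
    """One of the four simulated 10 mm electrode-shift directions.

    ``INWARDS``/``ONWARDS`` split the grid by column parity (a horizontal
    shift of one pitch); ``UPWARDS``/``DOWNWARDS`` split by row parity (a
    vertical shift). Each direction trains on one parity class and tests on
    the other; the paired direction swaps the roles, so the two members of a
    pair are exact complements of each other.
    """

    INWARDS = "inwards"
    ONWARDS = "onwards"
    UPWARDS = "upwards"
    DOWNWARDS = "downwards"

    @property
    def axis(self) -> str:
        """Split axis: ``"col"`` for horizontal shifts, ``"row"`` for vertical."""
        return "col" if self in (ShiftDirection.INWARDS, ShiftDirection.ONWARDS) else "row"

    @property
    def train_parity(self) -> int:
        """Parity (0 = even, 1 = odd) of the training electrodes on the split axis."""
        return 0 if self in (ShiftDirection.INWARDS, ShiftDirection.UPWARDS) else 1

    @property
    def complement(self) -> "ShiftDirection":
        pairs = {
            ShiftDirection.INWARDS: ShiftDirection.ONWARDS,
            ShiftDirection.ONWARDS: ShiftDirection.INWARDS,
            ShiftDirection.UPWARDS: ShiftDirection.DOWNWARDS,
            ShiftDirection.DOWNWARDS: ShiftDirection.UPWARDS,
        }
        return pairs[self]


@dataclass(frozen=True)
class ElectrodeGrid:
    """Rectangular HD-sEMG electrode grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid extent. The able-bodied configuration is 8 x 24 (192 channels);
        the amputee configuration is 6 x 24 (144 channels).
    pitch_mm
        Center-to-center electrode spacing in millimetres (default 10).
    channel_order
        Permutation mapping grid position ``row * n_cols + col`` (row-major)
        to the recorded channel index. Identity by default.
    """

    n_rows: int
    n_cols: int
    pitch_mm: float = 10.0
    channel_order: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise GridError(
                f"grid must be at least 2x2 so both parities exist on each axis, "
                f"got {self.n_rows}x{self.n_cols}"
            )
        if self.pitch_mm <= 0:
            raise GridError(f"pitch_mm must be positive, got {self.pitch_mm}")
        if self.channel_order is not None:
            order = np.asarray(self.channel_order, dtype=np.intp)
            if sorted(order.tolist()) != list(range(self.n_channels)):
                raise GridError("channel_order must be a permutation of all channels")
            object.__setattr__(self, "channel_order", order)

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def channel_to_rc(self, channel: int) -> tuple[int, int]:
        """Map a flat channel index to its 0-based (row, col) grid position."""
        if not 0 <= channel < self.n_channels:
            raise IndexError(
                f"channel {channel} out of range for {self.n_rows}x{self.n_cols} grid"
            )
        if self.channel_order is not None:
            pos = int(np.flatnonzero(self.channel_order == channel)[0])
        else:
            pos = channel
        return divmod(pos, self.n_cols)

    def rc_to_channel(self, row: int, col: int) -> int:
        """Map a 0-based (row, col) position to its flat channel index."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"position ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        pos = row * self.n_cols + col
        if self.channel_order is not None:
            return int(self.channel_order[pos])
        return pos

    def channels_with_parity(self, axis: str, parity: int) -> np.ndarray:
        """Channels whose row (``axis="row"``) or column index has the given parity.

        Returned in row-major grid order so the subset reshapes into a
        contiguous half-grid.
        """
        rows, cols = np.divmod(np.arange(self.n_channels), self.n_cols)
        coord = rows if axis == "row" else cols
        positions = np.flatnonzero(coord % 2 == parity)
        if self.channel_order is not None:
            return self.channel_order[positions]
        return positions

    def to_dict(self) -> dict:
        return {"n_rows": self.n_rows, "n_cols": self.n_cols, "pitch_mm": self.pitch_mm}

    @classmethod
    def from_dict(cls, d: dict) -> "ElectrodeGrid":
        return cls(n_rows=int(d["n_rows"]), n_cols=int(d["n_cols"]), pitch_mm=float(d["pitch_mm"]))


def make_grid(n_rows: int, n_cols: int, pitch_mm: float = 10.0) -> ElectrodeGrid:
    """Build an :class:`ElectrodeGrid` with row-major channel ordering.

    >>> make_grid(8, 24).n_channels
    192
    """
    return ElectrodeGrid(n_rows=n_rows, n_cols=n_cols, pitch_mm=pitch_mm)
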