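"""The in-memory container for a single bead's stretch-relief time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace"]


@dataclass
class Trace:
    """One bead's magnetic-tweezers recording.

    Attributes
    ----------
    time : array of float
        Seconds, strictly increasing.
    force : array of float
        Applied force in pN, non-negative.
    extension : array of float
        Bead extension in nm.
    magnet_pos : array of float or None
        Magnet position in mm (optional).
    bead_id : str
        Identifier of the bead / trace.
    """

    time: np.ndarray
    force: np.ndarray
    extension: np.ndarray
    magnet_pos: np.ndarray | None = None
    bead_id: str = "bead0"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.magnet_pos is not None:
            self.magnet_pos = np.asarray(self.magnet_pos, dtype=float)
        n = len(self.time)
        arrays = [self.force, self.extension] + (
            [self.magnet_pos] if self.magnet_pos is not None else []
        )
        if any(len(a) != n for a in arrays):
            raise ValueError("trace arrays must have equal length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.force < 0):
            raise ValueError("forces must be non-negative")

    def __len__(self) -> int:
        return len(self.time)

    def slice(self, start: int, stop: int) -> "Trace":
        """Sub-trace over the half-open index range [start, stop)."""
        return Trace(
            time=self.time[start:stop],
            force=self.force[start:stop],
            extension=self.extension[start:stop],
            magnet_pos=None if self.magnet_pos is None else self.magnet_pos[start:stop],
            bead_id=self.bead_id,
        )
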