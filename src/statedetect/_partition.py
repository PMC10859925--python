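"""Segment partitions: time-continuous states over a retained-epoch sequence.

Epochs are 0-based; segments are half-open ``[start, end)`` intervals in the
retained-epoch index space, so consecutive segments tile ``[0, n_epochs)``
exactly and adjacency is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SegmentPartition"]


@dataclass(frozen=True)
class SegmentPartition:
    """A partition of ``[0, n_epochs)`` into time-continuous states.

    Parameters
    ----------
    boundaries : array-like of int
        Strictly increasing epoch indices, including 0 and ``n_epochs``.
        Segment *i* is ``[boundaries[i], boundaries[i+1])``.
    """

    boundaries: np.ndarray = field()

    def __init__(self, boundaries) -> None:
        b = np.asarray(boundaries, dtype=np.int64)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("boundaries must be a 1-D sequence with >= 2 entries")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing (empty segment)")
        if b[0] != 0:
            raise ValueError("first boundary must be 0")
        object.__setattr__(self, "boundaries", b)

    @classmethod
    def from_interior(cls, interior, n_epochs: int) -> "SegmentPartition":
        """Build a partition from interior boundaries over ``n_epochs`` epochs."""
        interior = np.asarray(interior, dtype=np.int64)
        return cls(np.concatenate(([0], np.sort(interior), [n_epochs])))

    @property
    def n_epochs(self) -> int:
        return int(self.boundaries[-1])

    @property
    def n_states(self) -> int:
        return len(self.boundaries) - 1

    @property
    def interior(self) -> np.ndarray:
        """Interior boundaries (change points), excluding 0 and ``n_epochs``."""
        return self.boundaries[1:-1]

    @property
    def segments(self) -> list[tuple[int, int]]:
        b = self.boundaries
        return [(int(b[i]), int(b[i + 1])) for i in range(len(b) - 1)]

    @property
    def durations(self) -> np.ndarray:
        """Segment lengths in epochs."""
        return np.diff(self.boundaries)

    def labels(self) -> np.ndarray:
        """Per-epoch state label (0-based, in temporal order)."""
        out = np.empty(self.n_epochs, dtype=np.int64)
        for i, (lo, hi) in enumerate(self.segments):
            out[lo:hi] = i
        return out

    def state_indices(self, state: int) -> np.ndarray:
        lo, hi = self.segments[state]
        return np.arange(lo, hi)

    def __len__(self) -> int:  # number of states
        return self.n_states

    def __eq__(self, other) -> bool:
        return isinstance(other, SegmentPartition) and np.array_equal(
            self.boundaries, other.boundaries
        )

    def __hash__(self) -> int:
        return hash(self.boundaries.tobytes())
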