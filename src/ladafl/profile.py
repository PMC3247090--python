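"""Ordered log2-ratio profiles.

A CGH profile holds the marker-ordered log2 test/reference intensity
ratios for a single chromosome.  Marker order is the analysis order;
all public indices (breakpoints, segment bounds) are 1-based and
inclusive, matching the convention of array-CGH segment tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class CGHProfile:
    """Log2 ratios ``y_i`` for one chromosome, in marker order.

    Parameters
    ----------
    values
        Sequence of finite log2 ratios, length >= 2.
    positions
        Optional integer genomic coordinates, strictly increasing,
        same length as ``values``.
    chrom
        Optional chromosome label carried through to output writers.
    """

    values: np.ndarray
    positions: np.ndarray | None = None
    chrom: str | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("profile values must be one-dimensional")
        if vals.size < 2:
            raise ValueError(f"profile needs at least 2 markers, got {vals.size}")
        if not np.all(np.isfinite(vals)):
            bad = int(np.flatnonzero(~np.isfinite(vals))[0]) + 1
            raise ValueError(f"non-finite log2 ratio at marker {bad}")
        object.__setattr__(self, "values", vals)
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=np.int64)
            if pos.shape != vals.shape:
                raise ValueError("positions and values length mismatch")
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing")
            object.__setattr__(self, "positions", pos)

    @property
    def n(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.n
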