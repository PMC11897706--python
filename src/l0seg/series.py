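"""In-memory series containers for single- and dual-track signals.

A :class:`WeightedSeries` carries one observation per position (read counts,
binned coverage, or any real-valued signal) together with non-negative
weights.  A :class:`DualCountSeries` carries the (methylated, total) read-count
pairs produced by bisulfite sequencing.  Both are plain validated containers;
the loss families in :mod:`l0seg.families` bind to them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WeightedSeries", "DualCountSeries"]


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains NaN or infinite entries")
    return arr


@dataclass
class WeightedSeries:
    """Ordered observations ``values`` with non-negative ``weights``.

    Weights default to 1.  A zero weight keeps the position in the index
    space but removes its contribution to every loss.
    """

    values: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = _as_float_vector(self.values, "values")
        if self.weights is None:
            self.weights = np.ones_like(self.values)
        else:
            self.weights = _as_float_vector(self.weights, "weights")
        if self.weights.shape != self.values.shape:
            raise ValueError("values and weights must have equal length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class DualCountSeries:
    """Paired (methylated, total) counts per CpG with optional weights."""

    meth: np.ndarray
    total: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.meth = _as_float_vector(self.meth, "meth")
        self.total = _as_float_vector(self.total, "total")
        if self.meth.shape != self.total.shape:
            raise ValueError("meth and total must have equal length")
        if self.weights is None:
            self.weights = np.ones_like(self.meth)
        else:
            self.weights = _as_float_vector(self.weights, "weights")
            if self.weights.shape != self.meth.shape:
                raise ValueError("weights must match series length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if np.any(self.meth < 0) or np.any(self.total < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.meth > self.total):
            raise ValueError("meth count exceeds total count")

    def __len__(self) -> int:
        return self.meth.size

    @property
    def beta(self) -> np.ndarray:
        """Methylation fraction per CpG (NaN where total is zero)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.total > 0, self.meth / np.maximum(self.total, 1e-300), np.nan)
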