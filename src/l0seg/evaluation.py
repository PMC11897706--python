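"""Quantitative evaluation of compressed track representations.

These statistics quantify how much of a signal's salient structure survives
compression to a piecewise-constant representation:

* compression ratio — input positions per output segment;
* median fold change under peak regions — signal retention inside
  peaks relative to the background after compression;
* maximum Jaccard index per peak — how well segment boundaries recover peak
  boundaries;
* per-class enrichment ratio — mean signal inside labeled region classes
  (e.g. chromatin-state annotations) over the background;
* median TES-to-breakpoint distance — whether breakpoints land near
  transcription end sites.

"Background" means every analyzed position not covered by any peak/class
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks_io import IntervalSet

__all__ = [
    "EvalReport",
    "compression_ratio",
    "peak_fold_change",
    "max_jaccard",
    "region_enrichment",
    "tes_breakpoint_distance",
    "runs_to_intervals",
    "peaks_to_segments",
]


def compression_ratio(n_points: int, n_segments: int) -> float:
    """Average number of input positions represented by one segment."""
    if n_segments < 1:
        raise ValueError("n_segments must be at least 1")
    return n_points / n_segments


def _interval_mask(n: int, start: int, step: int, starts, ends) -> np.ndarray:
    """Boolean mask over ``n`` positions covering the given bp intervals."""
    mask = np.zeros(n, dtype=bool)
    for s, e in zip(np.asarray(starts), np.asarray(ends)):
        lo = max(0, (int(s) - start) // step)
        hi = min(n, -(-(int(e) - start) // step))
        if hi > lo:
            mask[lo:hi] = True
    return mask


def peak_fold_change(values: np.ndarray, peaks: IntervalSet, start: int = 0,
                     step: int = 1) -> float:
    """Median, over peaks, of mean signal inside the peak over mean background.

    ``values`` is a per-position (or per-bin) signal beginning at basepair
    ``start`` with ``step`` basepairs per position; background is every
    position outside all peaks.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    all_mask = _interval_mask(n, start, step, peaks.start, peaks.end)
    if all_mask.all():
        raise ValueError("peaks cover every position; background is empty")
    bg = float(values[~all_mask].mean())
    if bg == 0.0:
        raise ValueError("background mean is zero")
    folds = []
    for s, e in zip(peaks.start, peaks.end):
        m = _interval_mask(n, start, step, [s], [e])
        if not m.any():
            continue
        folds.append(float(values[m].mean()) / bg)
    if not folds:
        raise ValueError("no peak overlaps the signal extent")
    return float(np.median(folds))


def runs_to_intervals(values: np.ndarray, start: int = 0, step: int = 1
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Maximal runs of constant value as bp intervals (starts, ends)."""
    values = np.asarray(values)
    change = np.flatnonzero(np.diff(values) != 0)
    starts = np.concatenate(([0], change + 1)) * step + start
    ends = np.concatenate((change + 1, [values.size])) * step + start
    return starts, ends


def max_jaccard(segment_starts, segment_ends, peaks: IntervalSet
                ) -> dict[str, object]:
    """Per-peak maximum Jaccard index against candidate segments.

    For each peak the best |intersection| / |union| over all segments is
    taken (0 for a peak no segment overlaps).  Returns the distribution with
    its median and 90% quantile.
    """
    seg_s = np.asarray(segment_starts, dtype=float)
    seg_e = np.asarray(segment_ends, dtype=float)
    best = np.zeros(len(peaks))
    for k, (ps, pe) in enumerate(zip(peaks.start, peaks.end)):
        inter = np.minimum(seg_e, pe) - np.maximum(seg_s, ps)
        union = np.maximum(seg_e, pe) - np.minimum(seg_s, ps)
        j = np.where(inter > 0, inter / union, 0.0)
        best[k] = j.max() if j.size else 0.0
    return {
        "per_peak": best,
        "median": float(np.median(best)),
        "q90": float(np.quantile(best, 0.9)),
    }


def region_enrichment(values: np.ndarray, classes: IntervalSet, start: int = 0,
                      step: int = 1) -> dict[str, float]:
    """Mean signal within each labeled class over the shared background.

    Background is every position outside *all* class intervals; raises if the
    classes tile the whole extent (no background left).
    """
    if classes.name is None:
        raise ValueError("classes need a name (label) column")
    values = np.asarray(values, dtype=float)
    n = values.size
    all_mask = _interval_mask(n, start, step, classes.start, classes.end)
    if all_mask.all():
        raise ValueError("classes cover every position; background is empty")
    bg = float(values[~all_mask].mean())
    if bg == 0.0:
        raise ValueError("background mean is zero")
    out: dict[str, float] = {}
    for label in pd.unique(pd.Series(classes.name)):
        m = classes.name == label
        mask = _interval_mask(n, start, step, classes.start[m], classes.end[m])
        if not mask.any():
            continue
        out[str(label)] = float(values[mask].mean()) / bg
    return out


def tes_breakpoint_distance(breakpoints_bp, tes_bp) -> float:
    """Median, over TESs, of the distance to the closest breakpoint."""
    bps = np.sort(np.asarray(breakpoints_bp, dtype=float))
    tes = np.asarray(tes_bp, dtype=float)
    if bps.size == 0 or tes.size == 0:
        raise ValueError("need at least one breakpoint and one TES")
    idx = np.searchsorted(bps, tes)
    left = np.abs(tes - bps[np.clip(idx - 1, 0, bps.size - 1)])
    right = np.abs(bps[np.clip(idx, 0, bps.size - 1)] - tes)
    return float(np.median(np.minimum(left, right)))


def peaks_to_segments(peaks: IntervalSet, region_start: int, region_end: int
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Treat peaks plus the gaps between them as a segmentation of a region.

    Allows interval-based peak calls to be scored with the same
    boundary-recovery metrics as model-based segmentations.
    """
    order = np.argsort(peaks.start)
    starts, ends = [], []
    cursor = region_start
    for s, e in zip(peaks.start[order], peaks.end[order]):
        s = max(int(s), region_start)
        e = min(int(e), region_end)
        if e <= s:
            continue
        if s > cursor:
            starts.append(cursor)
            ends.append(s)
        starts.append(s)
        ends.append(e)
        cursor = max(cursor, e)
    if cursor < region_end:
        starts.append(cursor)
        ends.append(region_end)
    return np.asarray(starts), np.asarray(ends)


@dataclass
class EvalReport:
    """Container for the evaluation statistics, writable as TSV."""

    compression_ratio: float | None = None
    peak_fold_change: float | None = None
    jaccard_median: float | None = None
    jaccard_q90: float | None = None
    enrichment: dict[str, float] = field(default_factory=dict)
    tes_median_distance: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in ("compression_ratio", "peak_fold_change", "jaccard_median",
                    "jaccard_q90", "tes_median_distance"):
            v = getattr(self, key)
            if v is not None:
                rows.append((key, v))
        for label, v in self.enrichment.items():
            rows.append((f"enrichment[{label}]", v))
        return pd.DataFrame(rows, columns=["metric", "value"])

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
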