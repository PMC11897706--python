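"""Exact L0- and L1-penalized segmentation solvers.

The L0 solver minimizes

    sum_i e(theta_i, y_i)  +  lam * #{i : theta_i != theta_{i+1}}

exactly, by a forward pass that maintains the optimal objective as a
piecewise function of the current segment's natural parameter (an
:class:`~l0seg.envelope.Envelope`), followed by a backward pass that assigns
minimizers: the last position takes the argmin of the final envelope, and the
value is copied backwards until a stored restart region is hit, at which
point a changepoint is emitted and the value restarts at the argmin of that
position's envelope.

The L1 (fused-lasso) solver replaces the L0 transition with derivative
clipping at slopes ``-lam``/``+lam`` — the inf-convolution of the envelope
with ``lam*|.|`` — and the backward pass clamps each position's parameter to
its stored clip interval.  Both penalties act on differences of the *natural*
parameter (mean, log-rate, log-odds), which keeps the recursions exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envelope import Envelope
from .families import make_family
from .series import DualCountSeries, WeightedSeries

__all__ = [
    "Segmentation",
    "segment_stats",
    "l0_segment",
    "l1_segment",
    "reconstruct",
    "as_series",
]


@dataclass
class Segmentation:
    """A piecewise-constant fit of a length-``n`` series.

    ``breakpoints[k] = i`` means the fitted value changes between positions
    ``i`` and ``i+1`` (0-based).  ``segment_values`` are on the mean scale
    (mean / rate / methylation fraction); ``segment_params`` are the same
    segments in the family's natural parameter.
    """

    n: int
    breakpoints: np.ndarray
    segment_params: np.ndarray
    segment_values: np.ndarray
    objective: float
    family: str
    penalty: str
    lam: float
    mean_envelope_pieces: float = float("nan")

    @property
    def n_segments(self) -> int:
        return len(self.segment_values)

    @property
    def starts(self) -> np.ndarray:
        """Segment start indices (0-based, inclusive)."""
        return np.concatenate(([0], np.asarray(self.breakpoints, dtype=int) + 1))

    @property
    def ends(self) -> np.ndarray:
        """Segment end indices (0-based, exclusive)."""
        return np.concatenate((np.asarray(self.breakpoints, dtype=int) + 1, [self.n]))

    def reconstruct(self) -> np.ndarray:
        """Per-position fitted values on the mean scale."""
        lengths = self.ends - self.starts
        return np.repeat(self.segment_values, lengths)


def as_series(data, weights=None, family: str = "gaussian"):
    """Coerce raw input into the series container the family expects."""
    if isinstance(data, (WeightedSeries, DualCountSeries)):
        return data
    arr = np.asarray(data, dtype=float)
    if family == "binomial":
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("binomial input must be an (n, 2) array of (meth, total)")
        return DualCountSeries(arr[:, 0], arr[:, 1], weights)
    return WeightedSeries(arr.ravel(), weights)


def segment_stats(series, family: str, i: int, j: int):
    """Optimal constant fit of positions ``[i, j)`` under a loss family.

    Returns ``(theta_star, value, cost)``: the minimizing natural parameter,
    the same optimum on the mean scale, and the minimal summed loss (with the
    family's data-only constants dropped).
    """
    series = as_series(series, family=family)
    fam = make_family(family, series)
    if not (0 <= i < j <= fam.n):
        raise IndexError(f"invalid segment range [{i}, {j}) for length {fam.n}")
    return fam.seg(i, j)


def _solve_l0(fam, lam: float):
    n = fam.n
    env = Envelope(fam)
    records = []
    pieces_total = 0
    for i in range(n):
        env.add_datum(i)
        pieces_total += len(env.pieces)
        if i < n - 1:
            delta, theta_hat = env.minimum()
            restarts = env.l0_step(delta + lam)
            records.append((restarts, theta_hat))
    objective, theta = env.minimum()

    thetas = np.empty(n)
    thetas[n - 1] = theta
    breakpoints = []
    dom_lo, dom_hi = fam.dom_lo, fam.dom_hi
    for i in range(n - 2, -1, -1):
        restarts, theta_hat = records[i]
        th = thetas[i + 1]
        restart = False
        for lo, hi in restarts:
            # restart where the constant branch is strictly active; intervals
            # are open at interior crossings (ties prefer continue) but
            # closed at the domain boundaries, where no crossing exists
            if lo < th < hi or (th == lo == dom_lo) or (th == hi == dom_hi):
                restart = True
                break
        if restart:
            breakpoints.append(i)
            thetas[i] = theta_hat
        else:
            thetas[i] = th
    breakpoints.reverse()
    return np.asarray(breakpoints, dtype=int), thetas, objective, pieces_total / n


def _solve_l1(fam, lam: float):
    n = fam.n
    env = Envelope(fam)
    bounds = []
    pieces_total = 0
    for i in range(n):
        env.add_datum(i)
        pieces_total += len(env.pieces)
        if i < n - 1:
            bounds.append(env.l1_clip(lam))
    _, theta = env.minimum()

    thetas = np.empty(n)
    thetas[n - 1] = theta
    for i in range(n - 2, -1, -1):
        lo, hi = bounds[i]
        thetas[i] = min(max(thetas[i + 1], lo), hi)

    # objective from the definition (losses plus lam * total variation)
    objective = 0.0
    for i in range(n):
        a, b, c = fam.coeffs(i)
        objective += fam.value(a, b, c, thetas[i])
    objective += lam * float(np.sum(np.abs(np.diff(thetas))))
    return thetas, objective, pieces_total / n


_BREAK_TOL = 1e-8


def l0_segment(series, family: str = "gaussian", lam: float = 1.0, weights=None) -> Segmentation:
    """Globally optimal L0-penalized segmentation of a series."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    series = as_series(series, weights, family)
    fam = make_family(family, series)
    breakpoints, _, objective, mean_pieces = _solve_l0(fam, lam)
    starts = np.concatenate(([0], breakpoints + 1))
    ends = np.concatenate((breakpoints + 1, [fam.n]))
    params = np.empty(len(starts))
    values = np.empty(len(starts))
    for k, (s, e) in enumerate(zip(starts, ends)):
        params[k], values[k], _ = fam.seg(int(s), int(e))
    return Segmentation(
        n=fam.n,
        breakpoints=breakpoints,
        segment_params=params,
        segment_values=values,
        objective=float(objective),
        family=family,
        penalty="l0",
        lam=float(lam),
        mean_envelope_pieces=mean_pieces,
    )


def l1_segment(series, family: str = "gaussian", lam: float = 1.0, weights=None) -> Segmentation:
    """Exact fused-lasso (L1) segmentation in the natural parameter."""
    if lam < 0:
        raise ValueError("lam must be non-negative")
    series = as_series(series, weights, family)
    fam = make_family(family, series)
    thetas, objective, mean_pieces = _solve_l1(fam, lam)
    jumps = np.flatnonzero(np.abs(np.diff(thetas)) > _BREAK_TOL)
    starts = np.concatenate(([0], jumps + 1))
    params = np.array([thetas[s] for s in starts])
    values = np.array([fam.theta_to_value(t) for t in params])
    return Segmentation(
        n=fam.n,
        breakpoints=jumps.astype(int),
        segment_params=params,
        segment_values=values,
        objective=float(objective),
        family=family,
        penalty="l1",
        lam=float(lam),
        mean_envelope_pieces=mean_pieces,
    )


def segment(series, family="gaussian", penalty="l0", lam=1.0, weights=None) -> Segmentation:
    """Dispatch to :func:`l0_segment` or :func:`l1_segment` by penalty name."""
    if penalty == "l0":
        return l0_segment(series, family, lam, weights)
    if penalty == "l1":
        return l1_segment(series, family, lam, weights)
    raise ValueError(f"unknown penalty {penalty!r}; choose 'l0' or 'l1'")


def reconstruct(n: int, seg: Segmentation) -> np.ndarray:
    """Length-``n`` vector of per-position fitted (mean-scale) values."""
    if n != seg.n:
        raise ValueError(f"segmentation covers {seg.n} positions, not {n}")
    return seg.reconstruct()
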