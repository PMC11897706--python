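"""Penalty selection by cross-validation and by segment-count targeting.

Two CV modes are provided:

* **binned** ("offset") CV for ChIP-like tracks.  Immunoprecipitated
  fragments are much longer than the factor's occupancy site, so adjacent
  positions share reads and a held-out *point* is trivially predicted by its
  neighbors — naive CV then prefers absurdly fine segmentations.  Binned CV
  instead holds out contiguous windows about one fragment length wide
  (300 bp by default) and predicts each held-out window by the average of
  the fitted value at the left-most position of the adjacent left window and
  the fitted value at the right-most position of the adjacent right window.

* **pointwise** CV for methylation and other conditionally independent data:
  every ``n_folds``-th position is held out and predicted by the average of
  the fitted values at its two immediate training neighbors.

Both modes fit on the training positions concatenated in order (removed test
windows close the gap) and score held-out positions with the family's
negative log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dp import as_series, segment
from .families import make_family
from .series import DualCountSeries, WeightedSeries

__all__ = [
    "CVConfig",
    "CVResult",
    "binned_cv_split",
    "binned_cv_predict",
    "select_lambda",
    "lambda_for_target_segments",
    "default_lambda_grid",
]


@dataclass
class CVConfig:
    """Cross-validation settings.

    ``window_bp`` is expressed in basepairs and converted to positions with
    ``bin_bp`` (300 bp windows over 20 bp bins -> 15 positions per window).
    For ``mode="pointwise"`` the window is a single position regardless of
    ``window_bp``.
    """

    window_bp: int = 300
    bin_bp: int = 20
    n_folds: int = 5
    lambda_grid: np.ndarray | None = None
    n_lambdas: int = 20
    mode: str = "binned"
    seed: int = 0

    def __post_init__(self):
        if self.window_bp < 1 or self.bin_bp < 1:
            raise ValueError("window_bp and bin_bp must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.mode not in ("binned", "pointwise"):
            raise ValueError("mode must be 'binned' or 'pointwise'")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if np.any(grid <= 0) or np.any(np.diff(grid) < 0):
                raise ValueError("lambda_grid must be positive and ascending")
            self.lambda_grid = grid

    @property
    def window_positions(self) -> int:
        if self.mode == "pointwise":
            return 1
        return max(1, round(self.window_bp / self.bin_bp))


@dataclass
class CVResult:
    lambdas: np.ndarray
    mean_losses: np.ndarray
    fold_losses: np.ndarray  # (n_folds, n_lambdas)
    lambda_: float
    mode: str

    def __repr__(self) -> str:  # compact, the arrays can be long
        return (
            f"CVResult(lambda_={self.lambda_:.6g}, mode={self.mode!r}, "
            f"n_lambdas={len(self.lambdas)})"
        )


def binned_cv_split(n: int, window: int, n_folds: int, fold: int):
    """Train indices and test windows for one fold of binned CV.

    The sequence is tiled by consecutive windows of ``window`` positions (the
    last window may be partial); every ``n_folds``-th window starting at
    window ``fold`` is held out.  Returns ``(train_idx, test_windows)`` where
    ``test_windows`` is a list of ``(window_index, positions_array)``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window >= n:
        raise ValueError("window must be smaller than the series")
    if not 0 <= fold < n_folds:
        raise ValueError("fold index out of range")
    n_windows = -(-n // window)
    test_windows = []
    test_mask = np.zeros(n, dtype=bool)
    for j in range(fold, n_windows, n_folds):
        pos = np.arange(j * window, min((j + 1) * window, n))
        test_windows.append((j, pos))
        test_mask[pos] = True
    train_idx = np.flatnonzero(~test_mask)
    return train_idx, test_windows


def binned_cv_predict(fitted: np.ndarray, train_idx: np.ndarray, window_index: int,
                      window: int, n: int) -> float:
    """Constant prediction for one held-out window.

    ``fitted`` holds mean-scale fitted values for the training positions (in
    training order); the prediction is the average of the fitted value at the
    left-most position of the adjacent left window and the fitted value at
    the right-most position of the adjacent right window, falling back to the
    single available neighbor at sequence edges.
    """
    value_at = {int(p): fitted[k] for k, p in enumerate(train_idx)}
    neighbors = []
    left_pos = (window_index - 1) * window
    if window_index - 1 >= 0 and left_pos in value_at:
        neighbors.append(value_at[left_pos])
    right_pos = min((window_index + 2) * window, n) - 1
    if (window_index + 1) * window < n and right_pos in value_at:
        neighbors.append(value_at[right_pos])
    if not neighbors:
        raise ValueError("held-out window has no fitted neighbors")
    return float(np.mean(neighbors))


def default_lambda_grid(series, family: str, penalty: str, n_lambdas: int = 20,
                        span: float = 1e6) -> np.ndarray:
    """Log-spaced grid ending at the penalty that fuses everything.

    The upper end is found by doubling until the fit collapses to a single
    segment; the grid spans ``span`` downwards from there.
    """
    lam_hi = 1.0
    for _ in range(80):
        if segment(series, family, penalty, lam_hi).n_segments == 1:
            break
        lam_hi *= 2.0
    return np.geomspace(lam_hi / span, lam_hi, n_lambdas)


def _subset_series(series, idx: np.ndarray):
    if isinstance(series, DualCountSeries):
        return DualCountSeries(series.meth[idx], series.total[idx], series.weights[idx])
    return WeightedSeries(series.values[idx], series.weights[idx])


def select_lambda(series, family: str = "poisson", penalty: str = "l0",
                  config: CVConfig | None = None) -> CVResult:
    """Choose the penalty by held-out negative log-likelihood.

    For each fold the training positions are concatenated in order and
    segmented at each candidate penalty; held-out positions are predicted by
    the neighbor-average rule of the configured mode and scored with the
    family's negative log-likelihood.  The winning penalty minimizes the mean
    held-out loss, ties broken toward the larger (sparser) value.
    """
    if config is None:
        config = CVConfig()
    series = as_series(series, family=family)
    fam_full = make_family(family, series)
    n = fam_full.n
    window = config.window_positions
    if n <= 2 * window:
        raise ValueError("series too short for the requested CV window")
    if config.lambda_grid is not None:
        lambdas = config.lambda_grid
    else:
        lambdas = default_lambda_grid(series, family, penalty, config.n_lambdas)

    fold_losses = np.zeros((config.n_folds, len(lambdas)))
    for k in range(config.n_folds):
        train_idx, test_windows = binned_cv_split(n, window, config.n_folds, k)
        train_series = _subset_series(series, train_idx)
        for li, lam in enumerate(lambdas):
            fit = segment(train_series, family, penalty, lam)
            fitted = fit.reconstruct()
            loss = 0.0
            for j, pos in test_windows:
                pred = binned_cv_predict(fitted, train_idx, j, window, n)
                loss += fam_full.nll(pos, np.full(pos.size, pred))
            fold_losses[k, li] = loss
    mean_losses = fold_losses.sum(axis=0) / n
    if not np.any(np.isfinite(mean_losses)):
        raise ValueError("all candidate penalties gave non-finite held-out loss")
    best = np.min(mean_losses)
    best_idx = int(np.max(np.flatnonzero(mean_losses == best)))
    return CVResult(
        lambdas=np.asarray(lambdas, dtype=float),
        mean_losses=mean_losses,
        fold_losses=fold_losses,
        lambda_=float(lambdas[best_idx]),
        mode=config.mode,
    )


def lambda_for_target_segments(series, family: str = "poisson", penalty: str = "l0",
                               k: int = 10, max_doublings: int = 80) -> float:
    """Penalty whose fit has a segment count closest to ``k``.

    Segment count is non-increasing in the penalty, so a bracket is found by
    doubling and then bisected.  Ties in closeness prefer the larger penalty
    (fewer segments).
    """
    series = as_series(series, family=family)
    n = len(series)
    if not 1 <= k <= n:
        raise ValueError(f"target segment count must be in [1, {n}]")

    def count(lam: float) -> int:
        return segment(series, family, penalty, lam).n_segments

    best_lam, best_gap, best_count = None, None, None

    def consider(lam: float, cnt: int) -> None:
        nonlocal best_lam, best_gap, best_count
        gap = abs(cnt - k)
        if (
            best_gap is None
            or gap < best_gap
            or (gap == best_gap and cnt < best_count)
        ):
            best_lam, best_gap, best_count = lam, gap, cnt

    lo, hi = 0.0, 1.0
    c_hi = count(hi)
    consider(hi, c_hi)
    d = 0
    while c_hi > k and d < max_doublings:
        lo = hi
        hi *= 2.0
        c_hi = count(hi)
        consider(hi, c_hi)
        d += 1
    if c_hi > k:
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        c_mid = count(mid)
        consider(mid, c_mid)
        if c_mid == k:
            return mid
        if c_mid > k:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-12 * (1.0 + hi):
            break
    return best_lam
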