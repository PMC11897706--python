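"""Loss families in their natural parameters.

Every per-position loss used by the segmenter can be written, as a function of
the segment's natural parameter ``theta``, in the form

    a * g1(theta) + b * theta + c

with ``a >= 0`` and a family-specific convex basis function ``g1``:

* Gaussian  -- ``g1 = theta**2``, theta is the segment mean,
               ``e = w/2 * (y - theta)**2``;
* Poisson   -- ``g1 = exp(theta)``, theta is the log rate,
               ``e = w * (exp(theta) - y*theta)`` (the ``log y!`` constant is
               dropped);
* binomial  -- ``g1 = log(1 + exp(theta))``, theta is the log-odds of
               methylation, ``e = w * (y2*log(1+exp(theta)) - y1*theta)``
               (the binomial coefficient constant is dropped).

Sums of per-position losses stay in the same 3-coefficient class, which is
what lets the dynamic program store its running objective as a piecewise
function of ``theta``.  Dropped constants mean objectives are comparable only
within a family.

Poisson and binomial natural parameters are clamped to ``[-30, 30]``
(log / log-odds scale): empty-count segments otherwise have their optimum at
minus infinity, and the clamp keeps arithmetic finite at a negligible cost in
loss.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .series import DualCountSeries, WeightedSeries

__all__ = [
    "GaussianLoss",
    "PoissonLoss",
    "BinomialLoss",
    "make_family",
    "FAMILIES",
    "CLAMP",
]

#: natural-parameter clamp for the count families (log / log-odds scale)
CLAMP = 30.0

_REL_TOL = 1e-12


def _softplus(t: float) -> float:
    # log(1 + exp(t)), stable at both tails
    if t > 35.0:
        return t + math.exp(-t)
    if t < -35.0:
        return math.exp(t)
    return math.log1p(math.exp(t))


def _sigmoid(t: float) -> float:
    if t >= 0:
        z = math.exp(-t)
        return 1.0 / (1.0 + z)
    z = math.exp(t)
    return z / (1.0 + z)


def _newton_root(value, deriv, target: float, lo: float, hi: float) -> float:
    """Root of ``value(x) == target`` on a monotone bracket ``[lo, hi]``.

    Safeguarded Newton iteration with bisection fallback; the bracket is
    maintained throughout, so convexity of the piece guarantees convergence.
    """
    flo = value(lo) - target
    fhi = value(hi) - target
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    a, b = lo, hi
    sign_lo = flo > 0.0
    x = 0.5 * (lo + hi)
    for _ in range(100):
        fx = value(x) - target
        if fx == 0.0:
            return x
        if (fx > 0.0) == sign_lo:
            a = x
        else:
            b = x
        d = deriv(x)
        xn = x - fx / d if d != 0.0 else None
        if xn is None or not (a < xn < b):
            xn = 0.5 * (a + b)
        if abs(xn - x) <= _REL_TOL * (1.0 + abs(x)):
            return xn
        x = xn
    return x


class GaussianLoss:
    """Weighted squared error, ``e = w/2 * (y - theta)**2``."""

    name = "gaussian"
    dom_lo = -1e15
    dom_hi = 1e15

    def __init__(self, series: WeightedSeries):
        if not isinstance(series, WeightedSeries):
            raise TypeError("gaussian loss requires a WeightedSeries")
        y, w = series.values, series.weights
        if y.size == 0:
            raise ValueError("cannot segment an empty series")
        self.n = y.size
        self._y = y
        self._w = w
        self._W = np.concatenate(([0.0], np.cumsum(w)))
        self._S = np.concatenate(([0.0], np.cumsum(w * y)))
        self._Q = np.concatenate(([0.0], np.cumsum(w * y * y)))

    def coeffs(self, i: int) -> tuple[float, float, float]:
        wi = self._w[i]
        yi = self._y[i]
        return 0.5 * wi, -wi * yi, 0.5 * wi * yi * yi

    @staticmethod
    def value(a: float, b: float, c: float, t: float) -> float:
        return (a * t + b) * t + c

    @staticmethod
    def dvalue(a: float, b: float, t: float) -> float:
        return 2.0 * a * t + b

    @staticmethod
    def argmin_piece(a: float, b: float) -> Optional[float]:
        if a > 0.0:
            return -b / (2.0 * a)
        return None

    @staticmethod
    def solve_deriv(a: float, b: float, s: float) -> Optional[float]:
        if a > 0.0:
            return (s - b) / (2.0 * a)
        return None

    def solve_value(self, a, b, c, target, lo, hi):
        """Root of the piece equal to ``target`` on the monotone bracket."""
        if a == 0.0:
            if b == 0.0:
                return lo
            return (target - c) / b
        disc = b * b - 4.0 * a * (c - target)
        if disc < 0.0:
            disc = 0.0
        sq = math.sqrt(disc)
        # the bracket is monotone, so it lies on one side of the vertex:
        # right side -> increasing -> larger root; left side -> smaller root
        vertex = -b / (2.0 * a)
        if lo >= vertex:
            r = (-b + sq) / (2.0 * a)
        else:
            r = (-b - sq) / (2.0 * a)
        return min(max(r, lo), hi)

    @staticmethod
    def theta_to_value(t: float) -> float:
        return t

    @staticmethod
    def value_to_theta(v: float) -> float:
        return v

    def seg(self, i: int, j: int) -> tuple[float, float, float]:
        """(theta*, mean-scale value, minimal cost) over positions [i, j)."""
        W = self._W[j] - self._W[i]
        S = self._S[j] - self._S[i]
        Q = self._Q[j] - self._Q[i]
        if W <= 0.0:
            return 0.0, 0.0, 0.0
        th = S / W
        cost = 0.5 * Q - 0.5 * S * S / W
        return th, th, max(cost, 0.0) if cost > -1e-9 else cost

    def nll(self, idx: np.ndarray, pred: np.ndarray) -> float:
        y = self._y[idx]
        w = self._w[idx]
        return float(np.sum(0.5 * w * (y - pred) ** 2))


class PoissonLoss:
    """Poisson deviance in the log-rate, ``e = w*(exp(theta) - y*theta)``."""

    name = "poisson"
    dom_lo = -CLAMP
    dom_hi = CLAMP

    def __init__(self, series: WeightedSeries):
        if not isinstance(series, WeightedSeries):
            raise TypeError("poisson loss requires a WeightedSeries")
        y, w = series.values, series.weights
        if y.size == 0:
            raise ValueError("cannot segment an empty series")
        if np.any(y < 0):
            raise ValueError("poisson loss requires non-negative values")
        self.n = y.size
        self._y = y
        self._w = w
        self._A = np.concatenate(([0.0], np.cumsum(w)))
        self._B = np.concatenate(([0.0], np.cumsum(w * y)))

    def coeffs(self, i: int) -> tuple[float, float, float]:
        wi = self._w[i]
        return wi, -wi * self._y[i], 0.0

    @staticmethod
    def value(a: float, b: float, c: float, t: float) -> float:
        return a * math.exp(t) + b * t + c

    @staticmethod
    def dvalue(a: float, b: float, t: float) -> float:
        return a * math.exp(t) + b

    @staticmethod
    def argmin_piece(a: float, b: float) -> Optional[float]:
        if a > 0.0 and b < 0.0:
            return math.log(-b / a)
        return None

    @staticmethod
    def solve_deriv(a: float, b: float, s: float) -> Optional[float]:
        if a <= 0.0:
            return None
        x = (s - b) / a
        if x <= 0.0:
            return None
        return math.log(x)

    def solve_value(self, a, b, c, target, lo, hi):
        return _newton_root(
            lambda t: self.value(a, b, c, t),
            lambda t: self.dvalue(a, b, t),
            target,
            lo,
            hi,
        )

    @staticmethod
    def theta_to_value(t: float) -> float:
        return math.exp(t)

    @staticmethod
    def value_to_theta(v: float) -> float:
        return math.log(v) if v > 0 else -CLAMP

    def seg(self, i: int, j: int) -> tuple[float, float, float]:
        A = self._A[j] - self._A[i]
        B = self._B[j] - self._B[i]
        if A <= 0.0:
            return 0.0, 0.0, 0.0
        rate = B / A
        if B > 0.0:
            th = min(max(math.log(rate), -CLAMP), CLAMP)
        else:
            th = -CLAMP
        cost = A * math.exp(th) - B * th
        return th, rate, cost

    def nll(self, idx: np.ndarray, pred: np.ndarray) -> float:
        y = self._y[idx]
        w = self._w[idx]
        rate = np.maximum(np.asarray(pred, dtype=float), math.exp(-CLAMP))
        return float(np.sum(w * (rate - y * np.log(rate))))


class BinomialLoss:
    """Binomial log-odds loss, ``e = w*(y2*log(1+exp(theta)) - y1*theta)``."""

    name = "binomial"
    dom_lo = -CLAMP
    dom_hi = CLAMP

    def __init__(self, series: DualCountSeries):
        if not isinstance(series, DualCountSeries):
            raise TypeError("binomial loss requires a DualCountSeries")
        if len(series) == 0:
            raise ValueError("cannot segment an empty series")
        self.n = len(series)
        self._y1 = series.meth
        self._y2 = series.total
        self._w = series.weights
        self._A = np.concatenate(([0.0], np.cumsum(self._w * self._y2)))
        self._B = np.concatenate(([0.0], np.cumsum(self._w * self._y1)))

    def coeffs(self, i: int) -> tuple[float, float, float]:
        wi = self._w[i]
        return wi * self._y2[i], -wi * self._y1[i], 0.0

    @staticmethod
    def value(a: float, b: float, c: float, t: float) -> float:
        return a * _softplus(t) + b * t + c

    @staticmethod
    def dvalue(a: float, b: float, t: float) -> float:
        return a * _sigmoid(t) + b

    @staticmethod
    def argmin_piece(a: float, b: float) -> Optional[float]:
        if a <= 0.0:
            return None
        p = -b / a
        if 0.0 < p < 1.0:
            return math.log(p / (1.0 - p))
        return None

    @staticmethod
    def solve_deriv(a: float, b: float, s: float) -> Optional[float]:
        if a <= 0.0:
            return None
        p = (s - b) / a
        if not 0.0 < p < 1.0:
            return None
        return math.log(p / (1.0 - p))

    def solve_value(self, a, b, c, target, lo, hi):
        return _newton_root(
            lambda t: self.value(a, b, c, t),
            lambda t: self.dvalue(a, b, t),
            target,
            lo,
            hi,
        )

    @staticmethod
    def theta_to_value(t: float) -> float:
        return _sigmoid(t)

    @staticmethod
    def value_to_theta(v: float) -> float:
        v = min(max(v, _sigmoid(-CLAMP)), _sigmoid(CLAMP))
        return math.log(v / (1.0 - v))

    def seg(self, i: int, j: int) -> tuple[float, float, float]:
        A = self._A[j] - self._A[i]
        B = self._B[j] - self._B[i]
        if A <= 0.0:
            return 0.0, 0.0, 0.0
        frac = B / A
        if 0.0 < frac < 1.0:
            th = min(max(math.log(frac / (1.0 - frac)), -CLAMP), CLAMP)
        elif frac <= 0.0:
            th = -CLAMP
        else:
            th = CLAMP
        cost = A * _softplus(th) - B * th
        return th, frac, cost

    def nll(self, idx: np.ndarray, pred: np.ndarray) -> float:
        y1 = self._y1[idx]
        y2 = self._y2[idx]
        w = self._w[idx]
        p = np.clip(np.asarray(pred, dtype=float), _sigmoid(-CLAMP), _sigmoid(CLAMP))
        th = np.log(p / (1.0 - p))
        return float(np.sum(w * (y2 * np.logaddexp(0.0, th) - y1 * th)))


FAMILIES = {
    "gaussian": GaussianLoss,
    "poisson": PoissonLoss,
    "binomial": BinomialLoss,
}


def make_family(name: str, series):
    """Bind a loss family to a series by family name."""
    try:
        cls = FAMILIES[name]
    except KeyError:
        raise ValueError(f"unknown family {name!r}; choose from {sorted(FAMILIES)}") from None
    return cls(series)
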