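"""Piecewise representation of the running DP objective.

The forward pass of the segmenter maintains the optimal objective as a
function of the *current segment's* natural parameter theta.  Because every
loss family writes its per-position loss as ``a*g1(theta) + b*theta + c``
(see :mod:`l0seg.families`), this function is stored exactly as an ordered
list of pieces ``(lo, hi, a, b, c)`` tiling the parameter domain.

Three updates are needed:

* ``add_datum`` -- add one position's loss: coefficient-wise addition, piece
  intervals unchanged;
* ``l0_step`` -- pointwise minimum with the constant ``min(env) + lam``,
  which is the L0 transition (either continue the current segment, or pay
  ``lam`` and restart); the theta-regions where the constant branch is
  strictly better are recorded for the backward pass;
* ``l1_clip`` -- inf-convolution with ``lam*|.|``: clip the (convex)
  envelope's derivative at ``-lam`` and ``+lam``, replacing the tails with
  lines, which is the fused-lasso transition.
"""

from __future__ import annotations

from typing import List, Tuple

__all__ = ["Envelope"]

Piece = Tuple[float, float, float, float, float]  # (lo, hi, a, b, c)


class Envelope:
    """Piecewise ``a*g1(theta)+b*theta+c`` function over the family domain."""

    __slots__ = ("family", "pieces")

    def __init__(self, family, pieces: List[Piece] | None = None):
        self.family = family
        if pieces is None:
            pieces = [(family.dom_lo, family.dom_hi, 0.0, 0.0, 0.0)]
        self.pieces = pieces

    # ------------------------------------------------------------------ eval

    def __call__(self, theta: float) -> float:
        fam = self.family
        for lo, hi, a, b, c in self.pieces:
            if lo <= theta <= hi:
                return fam.value(a, b, c, theta)
        raise ValueError(f"theta={theta} outside envelope domain")

    def n_pieces(self) -> int:
        return len(self.pieces)

    # ------------------------------------------------------------- updates

    def add_datum(self, i: int) -> None:
        """Add position ``i``'s loss to every piece (in place)."""
        da, db, dc = self.family.coeffs(i)
        if da == 0.0 and db == 0.0 and dc == 0.0:
            return
        self.pieces = [
            (lo, hi, a + da, b + db, c + dc) for (lo, hi, a, b, c) in self.pieces
        ]

    def add_coeffs(self, da: float, db: float, dc: float) -> None:
        self.pieces = [
            (lo, hi, a + da, b + db, c + dc) for (lo, hi, a, b, c) in self.pieces
        ]

    def minimum(self) -> Tuple[float, float]:
        """Global minimum value and minimizer over the domain."""
        fam = self.family
        value = fam.value
        argmin_piece = fam.argmin_piece
        best = float("inf")
        best_t = self.pieces[0][0]
        for lo, hi, a, b, c in self.pieces:
            tm = argmin_piece(a, b)
            if tm is not None and lo < tm < hi:
                v = value(a, b, c, tm)
                t = tm
            else:
                vlo = value(a, b, c, lo)
                vhi = value(a, b, c, hi)
                if vlo <= vhi:
                    v, t = vlo, lo
                else:
                    v, t = vhi, hi
            if v < best:
                best, best_t = v, t
        return best, best_t

    def l0_step(self, threshold: float) -> List[Tuple[float, float]]:
        """Replace the envelope by ``min(env, threshold)`` in place.

        Returns the list of (open) theta-intervals where the constant branch
        is *strictly* below the envelope — the restart regions used by the
        backward pass.  Exact ties prefer the continue branch (fewer
        changepoints).
        """
        fam = self.family
        value = fam.value
        argmin_piece = fam.argmin_piece
        t = threshold
        out: List[Piece] = []
        restarts: List[Tuple[float, float]] = []

        def push_const(lo: float, hi: float, restart: bool = True) -> None:
            if out and out[-1][2] == 0.0 and out[-1][3] == 0.0 and out[-1][4] == t and out[-1][1] == lo:
                plo, phi, a, b, c = out[-1]
                out[-1] = (plo, hi, a, b, c)
            else:
                out.append((lo, hi, 0.0, 0.0, t))
            if restart:
                if restarts and restarts[-1][1] == lo:
                    restarts[-1] = (restarts[-1][0], hi)
                else:
                    restarts.append((lo, hi))

        for lo, hi, a, b, c in self.pieces:
            tm = argmin_piece(a, b)
            interior = tm is not None and lo < tm < hi
            vlo = value(a, b, c, lo)
            vhi = value(a, b, c, hi)
            vm = value(a, b, c, tm) if interior else min(vlo, vhi)
            if vm > t:
                # whole piece strictly above: constant, full restart region
                push_const(lo, hi)
                continue
            if vm == t:
                # grazing contact: constant branch ties at the minimizer;
                # prefer continue there, restart strictly elsewhere
                tmin = tm if interior else (lo if vlo <= vhi else hi)
                push_const(lo, hi, restart=False)
                if lo < tmin:
                    if restarts and restarts[-1][1] == lo:
                        restarts[-1] = (restarts[-1][0], tmin)
                    else:
                        restarts.append((lo, tmin))
                if tmin < hi:
                    restarts.append((tmin, hi))
                continue
            if vlo <= t and vhi <= t:
                out.append((lo, hi, a, b, c))
                continue
            # vm < t with at least one endpoint above: one or two crossings
            m = tm if interior else (lo if vlo < vhi else hi)
            left = lo
            if vlo > t:
                r1 = fam.solve_value(a, b, c, t, lo, m)
                push_const(lo, r1)
                left = r1
            right = hi
            if vhi > t:
                r2 = fam.solve_value(a, b, c, t, m, hi)
                right = r2
            if left < right:
                out.append((left, right, a, b, c))
            if right < hi:
                push_const(right, hi)
        self.pieces = out
        return restarts

    def l1_clip(self, lam: float) -> Tuple[float, float]:
        """Clip the convex envelope's derivative at ``-lam`` / ``+lam``.

        Replaces the tails with lines of slope ``-lam`` (left) and ``+lam``
        (right); returns the clip interval ``(theta_lo, theta_hi)`` used by
        the backward clamping pass.
        """
        fam = self.family
        dvalue = fam.dvalue
        value = fam.value
        pieces = self.pieces
        dom_lo = pieces[0][0]
        dom_hi = pieces[-1][1]

        if lam == 0.0:
            delta, that = self.minimum()
            self.pieces = [(dom_lo, dom_hi, 0.0, 0.0, delta)]
            return that, that

        # left clip point: first theta where derivative reaches -lam
        theta_lo = dom_lo
        if dvalue(pieces[0][2], pieces[0][3], dom_lo) < -lam:
            for lo, hi, a, b, c in pieces:
                if dvalue(a, b, hi) >= -lam:
                    r = fam.solve_deriv(a, b, -lam)
                    theta_lo = min(max(r if r is not None else hi, lo), hi)
                    break
            else:  # pragma: no cover - derivative must cross by convexity
                theta_lo = dom_hi

        # right clip point: last theta where derivative is at most +lam
        theta_hi = dom_hi
        if dvalue(pieces[-1][2], pieces[-1][3], dom_hi) > lam:
            for lo, hi, a, b, c in reversed(pieces):
                if dvalue(a, b, lo) <= lam:
                    r = fam.solve_deriv(a, b, lam)
                    theta_hi = min(max(r if r is not None else lo, lo), hi)
                    break
            else:  # pragma: no cover
                theta_hi = dom_lo

        if theta_hi < theta_lo:  # numerically degenerate; collapse
            theta_hi = theta_lo

        out: List[Piece] = []
        if theta_lo > dom_lo:
            # tangent line of slope -lam through (theta_lo, f(theta_lo))
            fl = self._eval_raw(theta_lo)
            out.append((dom_lo, theta_lo, 0.0, -lam, fl + lam * theta_lo))
        for lo, hi, a, b, c in pieces:
            nlo = max(lo, theta_lo)
            nhi = min(hi, theta_hi)
            if nlo < nhi:
                out.append((nlo, nhi, a, b, c))
        if theta_hi > dom_hi:  # pragma: no cover
            theta_hi = dom_hi
        if theta_hi < dom_hi:
            fr = self._eval_raw(theta_hi)
            out.append((theta_hi, dom_hi, 0.0, lam, fr - lam * theta_hi))
        if not out:  # zero-width interior (theta_lo == theta_hi)
            fl = self._eval_raw(theta_lo)
            out = [
                (dom_lo, theta_lo, 0.0, -lam, fl + lam * theta_lo),
                (theta_lo, dom_hi, 0.0, lam, fl - lam * theta_lo),
            ]
        self.pieces = out
        return theta_lo, theta_hi

    def _eval_raw(self, theta: float) -> float:
        fam = self.family
        for lo, hi, a, b, c in self.pieces:
            if lo <= theta <= hi:
                return fam.value(a, b, c, theta)
        # clamp to nearest piece end (roundoff)
        if theta < self.pieces[0][0]:
            lo, hi, a, b, c = self.pieces[0]
            return fam.value(a, b, c, lo)
        lo, hi, a, b, c = self.pieces[-1]
        return fam.value(a, b, c, hi)
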