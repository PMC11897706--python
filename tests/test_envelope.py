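"""Envelope updates checked against dense-grid oracles."""

import numpy as np
import pytest

from l0seg.dp import as_series
from l0seg.envelope import Envelope
from l0seg.families import make_family


def grid_for(fam, lo=-10, hi=10, n=1001):
    glo = max(fam.dom_lo, lo)
    ghi = min(fam.dom_hi, hi)
    return np.linspace(glo, ghi, n)


def env_on_grid(env, grid):
    return np.array([env(t) for t in grid])


def build_env(family, data, weights, lam=2.0):
    """Run a few forward steps to get a non-trivial multi-piece envelope."""
    series = as_series(data, weights, family)
    fam = make_family(family, series)
    env = Envelope(fam)
    for i in range(fam.n):
        env.add_datum(i)
        if i < fam.n - 1:
            delta, _ = env.minimum()
            env.l0_step(delta + lam)
    return fam, env


class TestAddDatum:
    def test_single_gaussian_datum_is_half_quadratic(self):
        fam, env = build_env("gaussian", np.array([5.0]), None)
        # 1/2 theta^2 - 5 theta + 12.5
        (lo, hi, a, b, c) = env.pieces[0]
        assert (a, b, c) == (0.5, -5.0, 12.5)

    @pytest.mark.parametrize("family", ["gaussian", "poisson", "binomial"])
    def test_addition_is_pointwise(self, family, rng):
        if family == "binomial":
            data = np.c_[rng.integers(0, 5, 6), rng.integers(5, 12, 6)].astype(float)
        else:
            data = rng.uniform(0, 10, 6)
        fam, env = build_env(family, data, None)
        grid = grid_for(fam)
        before = env_on_grid(env, grid)
        a, b, c = 1.3, -2.0, 0.7
        env.add_coeffs(a, b, c)
        after = env_on_grid(env, grid)
        datum = np.array([fam.value(a, b, c, t) for t in grid])
        assert np.max(np.abs(after - (before + datum))) < 1e-10 * (1 + np.abs(before).max())

    def test_piece_intervals_unchanged_by_addition(self, rng):
        fam, env = build_env("poisson", rng.poisson(5, 8).astype(float), None)
        intervals = [(p[0], p[1]) for p in env.pieces]
        env.add_datum(3)
        assert [(p[0], p[1]) for p in env.pieces] == intervals


class TestL0Step:
    def test_quadratic_crossings_at_0_and_4(self):
        # env = (1/2)(theta-2)^2, lam = 2: crossings where it equals 2
        series = as_series(np.array([2.0]), None, "gaussian")
        fam = make_family("gaussian", series)
        env = Envelope(fam)
        env.add_datum(0)
        restarts = env.l0_step(2.0)
        boundaries = sorted({p[0] for p in env.pieces} | {p[1] for p in env.pieces})
        inner = [b for b in boundaries if abs(b) < 100]
        assert inner == pytest.approx([0.0, 4.0], abs=1e-9)
        assert len(restarts) == 2  # constant active on both tails

    def test_lambda_zero_collapses_to_constant(self):
        fam, env = build_env("gaussian", np.array([1.0, 4.0]), None, lam=5.0)
        delta, _ = env.minimum()
        env.l0_step(delta + 0.0)
        grid = grid_for(fam)
        assert np.max(np.abs(env_on_grid(env, grid) - delta)) < 1e-9

    @pytest.mark.parametrize("family", ["gaussian", "poisson", "binomial"])
    def test_matches_pointwise_min_on_grid(self, family, rng):
        for trial in range(5):
            n = 7
            if family == "binomial":
                tot = rng.integers(1, 20, n).astype(float)
                meth = np.array([rng.integers(0, t + 1) for t in tot], dtype=float)
                data = np.c_[meth, tot]
            elif family == "poisson":
                data = rng.poisson(6, n).astype(float)
            else:
                data = rng.normal(0, 3, n)
            fam, env = build_env(family, data, None, lam=1.0)
            grid = grid_for(fam)
            before = env_on_grid(env, grid)
            delta, _ = env.minimum()
            t = delta + 0.8
            env.l0_step(t)
            after = env_on_grid(env, grid)
            scale = 1 + np.abs(before).max()
            assert np.max(np.abs(after - np.minimum(before, t))) < 1e-8 * scale

    def test_minimum_matches_grid(self, rng):
        fam, env = build_env("binomial",
                             np.c_[[2.0, 9.0, 1.0], [10.0, 10.0, 10.0]], None)
        grid = grid_for(fam, n=200001)
        delta, that = env.minimum()
        vals = env_on_grid(env, grid)
        assert delta == pytest.approx(vals.min(), abs=1e-7)
        assert env(that) == pytest.approx(delta, abs=1e-12)

    def test_pieces_tile_domain(self, rng):
        fam, env = build_env("poisson", rng.poisson(4, 10).astype(float), None)
        assert env.pieces[0][0] == fam.dom_lo
        assert env.pieces[-1][1] == fam.dom_hi
        for p, q in zip(env.pieces, env.pieces[1:]):
            assert p[1] == q[0]


class TestL1Clip:
    def test_clip_is_identity_inside_and_linear_outside(self):
        series = as_series(np.array([5.0]), None, "gaussian")
        fam = make_family("gaussian", series)
        env = Envelope(fam)
        env.add_datum(0)
        lo, hi = env.l1_clip(2.0)
        # derivative of (1/2)(t-5)^2 equals -2 at t=3 and +2 at t=7
        assert (lo, hi) == pytest.approx((3.0, 7.0))
        assert env(5.0) == pytest.approx(0.0)
        assert env(0.0) == pytest.approx(env(3.0) + 2.0 * 3.0)  # slope -2 tail

    @pytest.mark.parametrize("family", ["gaussian", "poisson", "binomial"])
    def test_clip_matches_infconv_on_grid(self, family, rng):
        """Clipped envelope equals min_u env(u) + lam|theta-u| pointwise."""
        n = 5
        if family == "binomial":
            tot = rng.integers(2, 15, n).astype(float)
            meth = np.array([rng.integers(0, t + 1) for t in tot], dtype=float)
            data = np.c_[meth, tot]
        elif family == "poisson":
            data = rng.poisson(5, n).astype(float)
        else:
            data = rng.normal(0, 2, n)
        series = as_series(data, None, family)
        fam = make_family(family, series)
        env = Envelope(fam)
        for i in range(n):
            env.add_datum(i)
        grid = grid_for(fam, -8, 8, 401)
        ugrid = grid_for(fam, -8, 8, 40001)  # fine minimization grid
        uvals = env_on_grid(env, ugrid)
        lam = 1.7
        env.l1_clip(lam)
        after = env_on_grid(env, grid)
        infconv = np.array(
            [np.min(uvals + lam * np.abs(t - ugrid)) for t in grid]
        )
        scale = 1 + np.abs(infconv).max()
        assert np.max(np.abs(after - infconv)) < 1e-5 * scale
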