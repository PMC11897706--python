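import numpy as np
import pytest

from l0seg.dp import as_series


def random_instance(rng, family, n):
    """Random small series for a family, weights in [0.2, 2]."""
    if family == "binomial":
        tot = rng.integers(1, 30, n).astype(float)
        meth = np.array([rng.integers(0, t + 1) for t in tot], dtype=float)
        data = np.c_[meth, tot]
    elif family == "poisson":
        data = rng.poisson(rng.uniform(0, 20), n).astype(float)
    else:
        data = rng.normal(0, 3, n)
    w = rng.uniform(0.2, 2.0, n)
    return as_series(data, w, family)


def brute_force_l0(fam, lam):
    """Exhaustive minimum over all 2^(n-1) changepoint sets."""
    import itertools

    n = fam.n
    best = np.inf
    for mask in itertools.product([0, 1], repeat=n - 1):
        bps = [i for i, m in enumerate(mask) if m]
        starts = [0] + [b + 1 for b in bps]
        ends = [b + 1 for b in bps] + [n]
        cost = sum(fam.seg(s, e)[2] for s, e in zip(starts, ends)) + lam * len(bps)
        best = min(best, cost)
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
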