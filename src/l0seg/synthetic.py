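"""Seeded generators for the signal classes the segmenter targets.

Every generator is a pure function of its parameters and seed, returns the
ground truth needed for recovery tests, and emulates one data regime:

* :func:`sim_piecewise` — piecewise-constant signals sampled from the loss
  family's own distribution (the idealized segmentation setting);
* :func:`sim_chip_like` — point sources spread by the sequencing fragment
  length into locally dependent coverage, the regime that motivates binned
  cross-validation;
* :func:`sim_pol2_like` — polymerase-style tracks: a sharp TSS peak, a
  gene-body plateau ending at the TES, and background;
* :func:`sim_low_coverage_insert` — methylation with a short low-coverage
  insert whose beta looks dramatically different but carries almost no reads;
* :func:`sim_cpg_outliers` — constant methylation with two isolated
  single-CpG outliers at ample coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import DualCountSeries, WeightedSeries

__all__ = [
    "SimSpec",
    "sim_piecewise",
    "sim_chip_like",
    "sim_pol2_like",
    "sim_low_coverage_insert",
    "sim_cpg_outliers",
    "true_breakpoints",
]


@dataclass
class SimSpec:
    """Piecewise-constant scenario: per-segment lengths and true parameters.

    ``params`` are means (gaussian), rates (poisson) or methylation fractions
    (binomial); ``coverage`` is the per-CpG total-count model for binomial
    draws (a scalar Poisson mean or an explicit per-position vector).
    """

    lengths: np.ndarray
    params: np.ndarray
    sd: float = 1.0
    coverage: float | np.ndarray = 30.0
    fragment_length: int = 15
    seed: int = 0

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=int)
        self.params = np.asarray(self.params, dtype=float)
        if self.lengths.shape != self.params.shape:
            raise ValueError("lengths and params must match")
        if np.any(self.lengths < 1):
            raise ValueError("segment lengths must be >= 1")

    @property
    def n(self) -> int:
        return int(self.lengths.sum())


def true_breakpoints(lengths) -> np.ndarray:
    """0-based positions i where the truth changes between i and i+1."""
    return np.cumsum(np.asarray(lengths, dtype=int))[:-1] - 1


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sim_piecewise(spec: SimSpec, family: str = "gaussian"):
    """Sample a piecewise-constant series from the family's distribution.

    Returns ``(series, truth)`` where ``truth`` is a dict with the true
    per-position parameter and breakpoint positions.
    """
    rng = _rng(spec.seed)
    signal = np.repeat(spec.params, spec.lengths)
    truth = {"signal": signal, "breakpoints": true_breakpoints(spec.lengths)}
    if family == "gaussian":
        y = rng.normal(signal, spec.sd) if spec.sd > 0 else signal.copy()
        return WeightedSeries(y), truth
    if family == "poisson":
        if np.any(spec.params < 0):
            raise ValueError("poisson rates must be non-negative")
        return WeightedSeries(rng.poisson(signal).astype(float)), truth
    if family == "binomial":
        if np.any((spec.params < 0) | (spec.params > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        cov = np.broadcast_to(np.asarray(spec.coverage, dtype=float), signal.shape)
        total = rng.poisson(cov).astype(float)
        meth = rng.binomial(total.astype(int), signal).astype(float)
        return DualCountSeries(meth, total), truth
    raise ValueError(f"unknown family {family!r}")


def sim_chip_like(n: int = 3000, peak_positions=(500, 1500, 2500),
                  peak_reads: float = 300.0, background: float = 0.5,
                  fragment_length: int = 15, seed=0):
    """ChIP-like coverage: point sources smeared by the fragment length.

    Each point source's expected reads are spread uniformly over a box of
    ``fragment_length`` positions (total expectation conserved) and added to
    a uniform background; counts are Poisson draws from the resulting rate.
    The smearing induces the smooth local structure that defeats pointwise
    cross-validation.  Returns ``(series, truth)`` with the true rate vector.
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    rng = _rng(seed)
    spikes = np.zeros(n)
    for p in peak_positions:
        spikes[int(p)] += peak_reads
    kernel = np.ones(fragment_length) / fragment_length
    rate = background + np.convolve(spikes, kernel, mode="same")
    y = rng.poisson(rate).astype(float)
    return WeightedSeries(y), {"rate": rate}


def sim_pol2_like(n: int = 1200, tss: int = 200, tes: int = 900,
                  tss_rate: float = 40.0, body_rate: float = 8.0,
                  background: float = 0.5, tss_width: int = 5, seed=0):
    """Polymerase-style track: TSS spike, gene-body plateau ending at the TES.

    The rate is ``background`` outside the gene, ``tss_rate`` on
    ``[tss, tss+tss_width)`` and ``body_rate`` on ``[tss+tss_width, tes)``;
    the true TES changepoint sits between positions ``tes-1`` and ``tes``.
    Returns ``(series, truth)`` with the rate vector and the TES position.
    """
    if not 0 < tss < tss + tss_width < tes <= n:
        raise ValueError("require 0 < tss < tss+tss_width < tes <= n")
    rng = _rng(seed)
    rate = np.full(n, background)
    rate[tss:tss + tss_width] = tss_rate
    rate[tss + tss_width:tes] = body_rate
    y = rng.poisson(rate).astype(float)
    return WeightedSeries(y), {"rate": rate, "tes": tes}


def sim_low_coverage_insert(block_len: int = 100, betas=(0.8, 0.2, 0.8),
                            coverage: float = 30.0, insert_len: int = 5,
                            insert_beta: float = 0.2, insert_coverage: float = 1.0,
                            insert_at: int = 40, seed=0):
    """Methylation region with a low-coverage insert of deviant beta.

    Three ``block_len``-CpG blocks at ``betas`` and ``coverage`` reads per
    CpG, with an ``insert_len``-CpG insert inside the first block whose beta
    differs dramatically but whose coverage (default 1 read) makes the
    estimate unreliable.  A coverage-aware loss should absorb the insert into
    its block; segmenting the beta values directly need not.

    Returns ``(series, truth)`` with the block breakpoints (the truth a
    coverage-aware segmentation should recover) and the insert's index range.
    """
    rng = _rng(seed)
    lengths = np.array([block_len] * 3)
    n = int(lengths.sum()) + insert_len
    beta = np.empty(n)
    cov = np.full(n, float(coverage))
    beta[:insert_at] = betas[0]
    beta[insert_at:insert_at + insert_len] = insert_beta
    cov[insert_at:insert_at + insert_len] = insert_coverage
    beta[insert_at + insert_len:block_len + insert_len] = betas[0]
    beta[block_len + insert_len:2 * block_len + insert_len] = betas[1]
    beta[2 * block_len + insert_len:] = betas[2]
    total = np.maximum(rng.poisson(cov), 1).astype(float)
    meth = rng.binomial(total.astype(int), beta).astype(float)
    series = DualCountSeries(meth, total)
    truth = {
        "breakpoints": np.array([block_len + insert_len - 1,
                                 2 * block_len + insert_len - 1]),
        "insert": (insert_at, insert_at + insert_len),
        "beta": beta,
    }
    return series, truth


def sim_cpg_outliers(n: int = 200, beta: float = 0.9, coverage: float = 30.0,
                     outlier_positions=(60, 140), outlier_beta: float = 0.1,
                     seed=0):
    """Constant methylation with two isolated single-CpG outliers.

    All CpGs share ``beta`` at ample coverage except the two outlier
    positions, which flip to ``outlier_beta``.  An L0 penalty can isolate
    each outlier as its own single-CpG segment; an L1 penalty, paying per
    unit of jump size, cannot afford to.
    """
    rng = _rng(seed)
    b = np.full(n, beta)
    for p in outlier_positions:
        b[int(p)] = outlier_beta
    total = np.maximum(rng.poisson(float(coverage), n), 1).astype(float)
    meth = rng.binomial(total.astype(int), b).astype(float)
    return DualCountSeries(meth, total), {
        "outliers": np.asarray(outlier_positions, dtype=int),
        "beta": b,
    }
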