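# Methods

## Model

A track is an ordered series of observations `y_1..y_N` with non-negative
weights `w_i` (all 1 unless stated).  The segmenter approximates the series
by a piecewise-constant parameter vector `β` minimizing

    Σ_i e(β_i, y_i) + λ Σ_i Ω(β_i − β_{i+1}),

with Ω the L0 norm (count of changepoints) or the L1 norm (fused lasso).
Three loss families cover the common sequencing data types:

* **Gaussian** `e = w/2 (y − β)²` for normalized or real-valued signal;
* **Poisson** `e = w (e^θ − y θ)` in the log-rate `θ` for read counts;
* **binomial** `e = w (y₂ log(1+e^θ) − y₁ θ)` in the log-odds `θ` for
  methylated/total count pairs `(y₁, y₂)`.

Additive terms that do not depend on the parameter (`log y!`, binomial
coefficients) are dropped: they never move the argmin, so objectives are
comparable only within a family.  The assumption throughout is conditional
independence of observations given a locally constant parameter; for
ChIP-like data this fails at fragment scale, which is handled at the
penalty-selection stage (below), not in the loss.

## Exact L0 solver

The key structural fact is that every per-position loss is `a·g1(θ) + b·θ + c`
with `g1` convex (`θ²`, `e^θ`, `log(1+e^θ)`), and this 3-coefficient class is
closed under addition.  The forward recursion

    f_1(θ) = e(θ, y_1)
    f_{i+1}(θ) = min( f_i(θ), min_θ f_i + λ ) + e(θ, y_{i+1})

is therefore computed exactly on a piecewise representation (the
*envelope*): adding a datum shifts each piece's coefficients; the L0 step
takes the pointwise minimum with the constant `min f_i + λ`, splitting
pieces at crossings.  The regions where the constant branch is strictly
active are recorded per position; the backward pass assigns
`θ_N = argmin f_N` and copies the value backwards, emitting a changepoint
and restarting at the stored argmin whenever the value falls in a recorded
restart region.  This yields a global optimum of the non-convex L0 problem;
the test suite verifies it against exhaustive search over all `2^(N−1)`
changepoint sets on hundreds of random instances per family.

Worst-case complexity is `O(N²)` (the envelope could in principle keep every
piece), but on signals with genuine segment structure the mean number of
pieces per position stays small — about 8 on length-10⁵ simulations for all
three families, measured by the acceptance script — so observed runtime is
linear in `N`.

The L1 path replaces the L0 step by the inf-convolution of the envelope with
`λ|·|`: the (convex) envelope's derivative is clipped at `∓λ`, the tails
replaced by lines, and the clip interval stored; the backward pass clamps
each position's parameter into its interval.  For the Gaussian family this
is the classical fused lasso and is checked against an independent
box-constrained dual least-squares solution.

### Numerical choices

* **Clamping.**  Poisson/binomial optima for empty-count segments lie at
  `θ = −∞` (or `+∞` for fully methylated segments); the natural parameter is
  confined to `[−30, 30]` (log / log-odds scale).  At coverage 30 the loss
  error of the clamp is below 10⁻¹¹; reported mean-scale values use the
  exact weighted mean/rate/fraction, not the clamped parameter.
* **Crossing roots.**  Gaussian crossings are quadratic roots chosen by
  bracket side (the bracket is always monotone, lying on one side of the
  vertex).  Poisson/binomial crossings use safeguarded Newton iteration with
  a maintained bisection bracket, relative tolerance 10⁻¹², at most two
  roots per convex piece.
* **Tie-breaking.**  When the continue and restart branches are exactly
  equal, continue wins (fewer changepoints): restart regions are open at
  interior crossings but closed at the domain boundaries, where the constant
  branch is strictly active and no crossing exists.  (The boundary case is
  not hypothetical: any segment with fraction 0 or 1 puts the running argmin
  exactly at ±30.)
* **Penalty scale for L1.**  Differences are penalized in the natural
  parameter (mean / log-rate / log-odds).  This keeps the clipping recursion
  exact in all families; note that for count families a penalty on the mean
  scale would weight the same jump differently at different baselines.
* **Weights.**  `w_i = 0` removes a position's loss but keeps it in the
  index space, so it adopts the surrounding segment's value.
* **Degenerate inputs.**  Empty series are rejected; NaN/Inf anywhere is
  rejected; λ = 0 returns the per-point fit; λ large returns one segment at
  the global weighted estimate.

## Penalty selection

`select_lambda` minimizes held-out negative log-likelihood over a log-spaced
grid (20 values by default, spanning a factor of 10⁶ below the smallest
single-segment penalty, found by doubling).  Ties prefer the larger λ.

* **Binned ("offset") CV** for ChIP-like tracks: immunoprecipitated
  fragments are far longer than the bound site, so adjacent positions share
  reads and a held-out *point* is trivially predictable from its neighbors,
  driving naive CV toward absurdly fine fits.  Instead the series is tiled
  into windows of `window_bp` (default 300 bp, about one fragment length;
  converted to positions via the track's bin width, 300/20 → 15 positions),
  every `n_folds`-th window is held out, the training remainder is
  concatenated (the gap closes) and segmented, and each held-out window is
  predicted by the average of the fitted value at the left-most position of
  the adjacent left window and at the right-most position of the adjacent
  right window (one-sided at sequence edges).  With length 6 and window 2,
  fold 1 trains on {X1,X2,X5,X6}, tests on {X3,X4} and predicts
  (fitted(X1)+fitted(X6))/2.
* **Pointwise CV** for methylation and other conditionally independent
  data: windows of a single position; the held-out value is predicted by the
  average of its two immediate training neighbors, which equals the segment
  value whenever both neighbors share a segment.

Fold count is 5 equally offset window sets (design choice; any value ≥ 2
keeps neighbor windows in the training set).  The held-out metric is the
family NLL, consistent with the fitting objective.

`lambda_for_target_segments` finds the penalty whose segment count is
closest to a requested `k` (ties → fewer segments) by doubling to bracket
and bisection, exploiting that the count is non-increasing in λ.  It is used
to compare penalties/losses at matched model size.

## Track I/O conventions

All coordinates are 0-based half-open.  BigWig (or BedGraph) values are
summed into fixed 20 bp bins by default — count semantics for the Poisson
loss; an averaging option exists for pre-normalized signal.  Missing BigWig
intervals read as 0 with weight 1 (absence of reads is an observation of
zero).  A partial last bin keeps its sum and gets weight equal to its width
fraction.  Bismark 6-column files are accepted in both common dialects
(1-based `.cov` with start == end, and 0-based half-open), auto-detected
from the coordinates; paired fraction+coverage BigWigs are converted via
`meth = round(fraction × coverage)`.  Segmentations never cross chromosome
boundaries; CpG-rank segments are written back spanning the genomic extent
of their CpGs.

## Evaluation statistics

Compression ratio is input positions per segment.  Peak fold change is the
median over peaks of (mean reconstructed signal inside the peak) / (mean
reconstructed signal over the background), background being every analyzed
position outside all peak/class intervals; both numerator and denominator
use the reconstruction so the statistic measures what survives compression.
Maximum Jaccard per peak is taken over maximal constant runs of the
reconstruction.  The TES statistic is the median over transcription end
sites of the distance to the nearest breakpoint; a converter treats interval
peak calls plus their gaps as a segmentation so they can be scored the same
way.

## Synthetic data

The generators are pure functions of (parameters, seed) and define the
regimes the tests probe:

* `sim_piecewise` — draws from the family's own distribution around a
  piecewise-constant truth (segment lengths, means/rates/fractions, Gaussian
  sd, Poisson-distributed CpG coverage with mean 30 by default).
* `sim_chip_like` — point sources (300 expected reads) spread uniformly
  over a fragment-length box (15 positions ≈ 300 bp at 20 bp bins) on a 0.5
  background, then Poisson-sampled.  This reproduces the smooth local
  structure that defeats pointwise CV; it does *not* simulate correlated
  noise from shared fragments, library amplification, or mappability
  artifacts, so CV conclusions transfer to real ChIP only qualitatively.
* `sim_pol2_like` — background 0.5, a 5-position TSS spike at rate 40, a
  gene-body plateau at rate 8 ending at the TES, on 1200 positions.  The
  body/background contrast (16×) is generous relative to weak genes, so the
  TES-localisation rates measured here are an upper bound on real data.
* `sim_low_coverage_insert` — three 100-CpG blocks at β = (0.8, 0.2, 0.8)
  and coverage 30, with a 5-CpG insert at β = 0.2, coverage 1, inside the
  first block: the insert's β estimate is dramatic but supported by ~5
  reads.  Chosen to match the qualitative description of the scenario
  ("dramatically different β", "coverage is low"); the published figure's
  exact draws and parameters are not available.
* `sim_cpg_outliers` — 200 CpGs at β = 0.9, coverage 30, with single-CpG
  outliers at positions 60 and 140 flipped to β = 0.1.

On the insert scenario, the binomial dual-track L0 fit at a segment count
matched to the β-only Gaussian fit keeps exactly the three blocks and never
isolates the insert.  The β-only fit *at three segments* also picks the
block boundaries — with these parameters the insert's squared-error gain
(≈ 5 points × 0.6² jumps) cannot compete with a 100-CpG block boundary —
so the pathology of β-only segmentation is demonstrated at the next finer
scale: at five segments the Gaussian fit spends its extra breakpoints
isolating the unreliable insert, which the coverage-aware loss never does.

## Scale of the shipped experiments

The test suite and acceptance script run entirely on synthetic data at desk
scale, chosen to exercise every code path while keeping a full run in
minutes: oracle comparisons at N ≤ 12 (exhaustive enumeration is 2^(N−1)),
recovery at 2 000 positions, TES localisation on 50 tracks of 1 200
positions, envelope economy at 100 000 positions.  Genome-scale inputs
stream through the same per-chromosome pipeline.

## Known limitations

* No negative-binomial loss: overdispersed counts are fit as Poisson, which
  over-segments truly overdispersed tracks unless λ compensates.
* The L1 penalty acts on the natural parameter; published fused-lasso
  analyses on the mean scale will differ for count families.
* Binned CV assumes the fragment length is roughly known; a window far from
  the true fragment scale degrades toward pointwise behavior (too small) or
  over-smoothing (too large).
* Multi-track/multivariate segmentation and peak-shape-constrained models
  are out of scope.
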