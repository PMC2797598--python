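# Methods

## The steady-state dosage model

Consider a population of cells in balanced exponential growth with mass
doubling time `T` (minutes).  Replication initiates at `oriC` and proceeds
bidirectionally; each fork moves at a position-dependent velocity `v(x)`
(`x` = distance along its replichore).  The time for a fork to reach `x`
is

    t(x) = ∫₀ˣ ds / v(s).

In steady state the population's relative gene dosage is time-invariant:
a locus replicated `t(x)` minutes after the origin "lags" the origin by
exactly that much of the exponential expansion, so its mean relative copy
number is `2^(−t(x)/T)` and its log2 dosage is

    g(x) = −t(x)/T        (intercept fixed by g(oriC) = 0).

Where `v` is constant, `g` is linear with slope magnitude `a = 1/(vT)`
per Mbp (`v` in Mbp/min), which inverts to

    v = 1/(aT)            (reported in kb/min as 1000/(aT)).

The package verifies this closed form against an explicit multifork
population simulation (`sample_async_profile(mode="cell_sampling")`): each
cell carries initiation events at past times `(φ+j)·T`, `j = 0, 1, 2, …`,
with cell-cycle phase `φ` drawn from the exponential-growth age density
`(2 ln2)·2^(−φ)` on `[0,1)`; every initiation whose age exceeds `t(x)` has
doubled locus `x`.  Averaging per-cell copy numbers and normalizing to the
origin reproduces `2^(−t(x)/T)` exactly in expectation (the integral over
the phase density telescopes), and the sampler is used as a Monte-Carlo
cross-check of the closed form, not as the estimator.

The division (D) period is deliberately omitted: the steady-state marginal
dosage `∝ 2^(−t(x)/T)` is independent of division bookkeeping, which only
redistributes copies among cells.

## Slope fitting and velocities

`fit_segments` converts probes to replichore coordinates (after applying
the genome map's inversions/deletions) and fits straight lines between
user-supplied breakpoints, either independently per segment (ordinary
least squares; slope SE is the standard OLS slope error) or as a connected
piecewise-linear function (hinge/broken-stick basis, forcing segments to
meet at breakpoints).  Independent fits are the default because tabulated
per-segment standard errors correspond to unconstrained per-row fits;
both modes agree exactly on noiseless data.  Slopes are reported as
positive decline magnitudes per Mbp — the tabulation convention — while
plotting uses signed genome coordinates (+ right arm, − left arm).

Velocity standard errors use the delta method, `SE(v) = v·SE(a)/a`.
Percent speed change between two segments is `100·(1 − a_ref/a_test)`
(velocity ∝ 1/slope, so the doubling time cancels).  Because it is
ambiguous whether a "head-on vs co-directional" comparison should use the
same-arm co-directional segment (28.5% with the tabulated Min slopes) or
the intact left arm (36.8%), the function takes both fits explicitly and
both comparisons are exercised in the tests.

`stall_segments` flags segments whose slope exceeds `fold_threshold`
(default 2.0) times the median slope of the other segments on the same
replichore — an operational definition of "strongly impeded or stalled"
forks such as head-on rRNA clusters in rich medium.

### Changepoint detection

Slope changepoints are found on one replichore at a time.  Because the
dosage track is continuous (a velocity change alters the slope, not the
level), a changepoint is a *knot* of a connected broken-stick function.
An optimal-partitioning search over independent per-segment fits was
implemented first and measured: intercept jumps make the breakpoint
location weakly identified (~100 kb errors where the connected model
achieves ~20 kb), so the shipped algorithm is:

1. **Forward hinge selection.** Starting from a single line, repeatedly
   add the knot whose hinge term `(x−b)₊` most reduces the residual sum
   of squares (computed for all candidate positions at once by projecting
   candidate hinges against the current fit), re-optimizing each existing
   knot after every addition.  Stop when the best remaining gain is below
   the penalty.
2. **Joint refinement.** Re-optimize all knot positions together by
   derivative-free least squares (Nelder–Mead over knot positions with
   profiled linear coefficients) — forward placement biases closely
   spaced knots (e.g. the two ends of a short stalled segment) and joint
   refinement removes that bias.
3. **Backward pruning.** Drop any knot whose hinge no longer earns the
   penalty, then re-refine.

The penalty defaults to a BIC-style `3·σ̂²·ln n` (a knot spends roughly
three parameters: position, slope change, and the maximization over
candidate positions), with `σ̂` estimated robustly as
`1.4826·median|Δy|/√2`.  Candidates keep `min_segment_probes` (default
50) probes on each side of every knot.  Localization is information-
limited: for a slope change of 0.25/Mbp at noise sd 0.05 and 1 kb probe
spacing, the exact broken-stick MLE itself has a knot-error sd of ~22 kb,
and the implementation attains that limit; larger slope changes (e.g. a
1.51/Mbp stall flanked by 0.65/Mbp) localize within ±20 kb.

## Synchronized-release profiles

After synchronization, a fraction `f` of cells initiates at release; the
dosage relative to pre-initiation DNA is `1+f` behind the fork front and
1 beyond it, i.e. a two-plateau step of height `log2(1+f)` per replichore.
The front position is the time integral of a `VelocitySchedule`
(piecewise-constant in time *and* space), which also models protocols
where the velocity field changes mid-run (e.g. rifampicin added 4 min
after release removing transcriptional obstruction).

Estimators (`sync_analysis`) smooth first (rolling mean over 200 probes by
default, matching the usual presentation of such tracks; the mean is
plotted at the midpoint of the window's first and last positions):

- **Initiation fraction**: `f = 2^(plateau − baseline) − 1`, clipped to
  `[0,1]`, with plateau/baseline the medians over an origin-proximal and a
  distal region (defaults: first and last 10% of the arm's probes —
  configurable, since stalls can distort interior shape).  Invariant to
  the profile's arbitrary intercept.
- **Fork position**: the first crossing of `(baseline+plateau)/2` moving
  outward from `oriC`, linearly interpolated between flanking probes.
  The midpoint is taken in log2 space (the space the tracks are plotted
  in; a linear-space option would differ by < half a probe spacing at
  these plateau heights).  The first-crossing rule resolves non-monotone
  noise wiggles; on a noiseless step the rolling mean is symmetric around
  the step so the estimator is exactly unbiased, and the worst-case bias
  is half the smoothing window's bp span.
- A transition is declared absent when `plateau − baseline ≤ 3×` the
  distal region's smoothed noise (so `f = 0` profiles raise an error
  instead of returning a noise crossing); a plateau significantly *below*
  the baseline raises an "inverted profile" error.

## Fluctuation assays and the P0 method

The simulator grows each culture from `N0` to `Nt` by discrete doublings
(the last generation may be partial when `Nt/N0` is not a power of two).
In generation `k`, the `N_k − N_{k−1}` newly born cells each mutate with
probability `μ` (Poisson approximation); a mutation founds a clone that
expands with the culture to final size `≈ Nt/N_k`.  Mutation opportunities
sum to exactly `Nt − N0`, so the zero-mutant probability is
`P0 = exp(−μ(Nt−N0))` — the analytic oracle the tests check against —
while early ("jackpot") mutations reproduce the heavy right skew that
makes the mean count uninformative.  Plating efficiency is fixed at 1
(whole cultures plated).

The estimator uses only the zero fraction: `P̂0 = n_zero/n`,
`m = −ln P̂0`, `rate = m/Nt` (the `Nt−N0` denominator is available as an
option; the difference is negligible at `Nt ≫ N0`).  The confidence
interval is a Wilson binomial interval on `P0` pushed through the
monotone map `−ln(·)/Nt`.  Boundary cases: no zero-mutant cultures →
the method is inapplicable (error); all cultures zero → rate 0 with a
one-sided upper bound.  Rate ratios between two assays get percentile-
bootstrap CIs (binomial resampling of the zero counts, clamped one
culture inside the boundary); measured coverage for a 3-fold difference
at 50 cultures is ~92% at nominal 95%.

## Growth and fitness

- Doubling times: OLS of `ln(OD600)` on time over a user-selected window;
  `T = ln2/slope`, SE by the delta method.  Exact on noiseless
  exponentials.
- Multiplicative null model for combining two growth perturbations:
  growth-rate ratios multiply, `T_AB = T_A·T_B/T_ctrl` — symmetric in A
  and B and equal to `T_B` when A is neutral.
- Competition fitness: `W = ln(test fold-expansion)/ln(reference
  fold-expansion)` (ratio of realized Malthusian parameters — the
  declared convention, since competition protocols differ), divided by a
  neutral-marker control `W` (default 1).  Invariant to rescaling all
  counts.  The simulator expands the reference by a set number of
  doublings, the test strain by `W×` that, and applies mean-one lognormal
  count noise with a given CV.

## Synthetic-data defaults (the stated world)

- Genome: 4,214,810 bp, `oriC` at 0°, `terC` at 172°; inversion strains
  as half-open bp intervals (HT: 0°–94°; rrn cluster: bp 159,778–176,408).
- Asynchronous profiles: probe noise Gaussian on log2 ratios (aCGH-like),
  default sd 0.05, 1 kb probe spacing; Min-medium velocities from the
  tabulated slopes at `T = 44` min, CAA at `T = 55` min.
- Synchronized profiles: `f = 0.5`, sampled 30 min after release, noise
  sd 0.1, smoothing window 200 probes; transcription inhibition modeled
  as a velocity-schedule change 4 min after release.
- Fluctuation assays: 50 parallel cultures, `Nt ≈ 2×10⁸`; competitions:
  10 reference doublings, 2% count noise.

What the generators do **not** emulate: probe-specific biases and spatial
noise correlation, incomplete run-out of the synchronized reference DNA
(which elevates baselines in real data), copy-number artifacts from
residual prophages, cell-to-cell initiation-timing variance in
synchronized populations (the step is sharp), and post-plating phenotypic
lag in fluctuation assays.  A green parameter-recovery test therefore
establishes estimator correctness *under the model*, not robustness to
these real-data artifacts.

## Numerical choices and degenerate inputs

- Coordinates are 0-based bp with half-open intervals; degrees are
  display-only.  Inversion `[s,e)` maps `x → s+e−1−x` (an involution);
  deletion shifts `x ≥ e` down by `e−s` and positions inside a deletion
  raise an error.  Rearrangement list order is authoritative.
- Rolling averages emit full windows only (`n−w+1` probes).
- Profile intersection uses exact positions; optional alignment is linear
  interpolation with no extrapolation.
- Segments require ≥ 10 probes and non-zero spatial extent; non-declining
  segments have undefined velocity (error, not NaN).
- All samplers are deterministic given `(parameters, seed)` via
  `numpy.random.default_rng`.

## Known limitations

- The changepoint search is greedy-then-refined, not globally optimal;
  with many closely spaced true knots it can merge neighbors.
- The P0 method discards non-zero count information by design (no
  Ma–Sandri–Sarkar/MLE estimator is provided).
- The synchronized-profile model assumes at most one initiation per cell
  during the sampling window (no re-initiation plateau above `1+f`).
- `velocity` is a population-average phenomenology: no single-molecule
  fork dynamics or replication–transcription collision mechanics.
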