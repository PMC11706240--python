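# Methods

## The paradigm and its analysis rules

The timed-beep paradigm measures 16-way object categorization accuracy at
controlled reaction times.  A session is one untimed training block of 50
trials followed by five timed blocks of 210 trials; each timed block plays
a beep at a fixed latency (500, 900, 1,100, 1,300, 1,500 ms by default) at
which the observer must click their response, with a 200 ms grace period
after the beep.  Blocks are seen in ascending or descending latency order
with equal probability.

The analysis applies, in order:

1. **Observer exclusion.** An observer is discarded when at least 50% of
   their timed responses fall outside ±100 ms of the beep; a missing
   response counts as outside, and the boundary is inclusive (exactly half
   outside excludes).  We interpret the ±100 ms window purely as an
   observer-level quality criterion: trials of *kept* observers are all
   analyzed, including late-but-present responses, because the imputation
   rule below is framed per trial, not per window.  A strict
   within-window-only analysis can be obtained by pre-filtering trials
   before aggregation.
2. **Warm-up discard.** The first 10 trials of each timed block are
   dropped (observers use them to adapt to the block's beep timing),
   leaving 200 analyzed trials per block.
3. **Imputation.** Missing responses are replaced by a uniformly drawn
   category (seeded), which biases measured accuracy toward chance by
   exactly `m·(1/16 − a)` at miss rate `m` and true accuracy `a`; a `drop`
   mode removes them instead.  Imputation runs after the warm-up discard,
   so warm-up trials never receive imputed responses.
4. **Aggregation.** Per condition and beep latency: accuracy is the
   fraction correct and the standard error the binomial `√(a(1−a)/n)`.
5. **Normalization.** Curves are divided by the untimed accuracy (fraction
   correct on training trials).  The default baseline is the
   experiment-level mean over kept observers, so group curves share one
   unit; a per-observer baseline is available for individual-level fits.
6. **Timestep mapping.** A model observer's ordinal timesteps are placed
   on the reaction-time axis.  Index mode (default) assigns timestep *i*
   the *i*-th beep latency, which is exact when the number of timesteps
   equals the number of timed blocks.  Affine mode fits `t = a·i + b`
   (a > 0) by least squares against a reference human curve interpolated
   at the mapped times, giving the model both a speed and a fixed delay —
   absorbing retinal and motor latencies that are independent of task
   difficulty.  In the pipeline one (a, b) pair is fitted per model,
   jointly across all perturbation conditions (a single network has a
   single clock), and the mapped curves are then re-gridded onto the
   design latencies by linear interpolation so model and human families
   share a time axis.  A flat reference leaves (a, b) unidentified; the
   pipeline falls back to index mapping with a warning.
7. **Chance anchor.** For display, a point at time 0 with accuracy
   1/16 = 6.25% (divided by the baseline when normalized) can be prepended;
   every metric excludes it.

## Psychometric model

Accuracy as a function of allowed time is modeled by the cumulative
Weibull

    a(t) = γ + (1 − γ − λ)(1 − exp(−(t/τ)^β))

with guess rate γ (pinned at chance, 1/16, by default), lapse rate
λ ∈ [0, 0.5), time scale τ (ms), and shape β.  Fitting is bounded
least squares on the accuracy points (anchor excluded): λ ∈ [0, 0.5],
τ ∈ [min t/10, 100·max t], β ∈ [0.05, 50], restarted from a fixed 3×3 grid
of (τ, β) initializations (τ at 0.5/1/2 × the median sampled time;
β at 0.5/2/8), smallest residual wins, residual ties go to the smaller β.
The objective is unweighted because the design gives every point the same
trial count; inverse-variance weighting is available via the `weights`
argument (binomial maximum likelihood was also evaluated during
development and gave no material accuracy gain in the identifiable regime
described below).  A flat curve (range < 1e−6) is flagged degenerate — τ
and β are not identifiable from it — and propagates as NaN rather than a
number.

**Identifiability.** With five latencies spanning 500–1,500 ms and 200
trials per point, τ and β are only well determined when the curve both
rises and saturates inside the sampled window.  A Cramér–Rao analysis at
the design latencies shows that the best possible median relative error of
β exceeds 10% for any estimator once τ approaches the top of the window
(e.g. τ ≈ 1,150 ms), while for τ ∈ [600, 900], β ∈ [2.5, 3.5],
λ ∈ [0.05, 0.25] the least-squares fit achieves median errors of 2–4% (τ)
and 7–9% (β).  The parameter-recovery tests therefore sample that
identifiable regime; recovery claims do not extend to curves whose scale
parameter lies at or beyond the last sampled latency.

## Comparison metrics

- **Curve-fit error.** `e_RMSE(c₁, c₂) = (1/N_p) Σ_p √((1/N_t) Σ_t (c₁[p,t] − c₂[p,t])²)`
  over an `N_p × N_t` family of accuracy curves spanning perturbation
  levels (level 0, the unperturbed condition, must be present) and times.
  The square root applies to the inner time average only — RMSE across
  time, then averaged across perturbation curves — so the statistic is an
  average of per-condition RMSEs, each a true metric; symmetry,
  nonnegativity, identity and the triangle inequality follow level-wise.
- **Category-wise correlation.** Per-category SAT curves on both sides are
  flattened in a fixed order (categories alphabetically, then time
  ascending) and compared by Spearman rank correlation with average-rank
  ties.  Category curves pool all conditions of an experiment: with 200
  analyzed trials per block split over 16 categories, restricting to a
  single condition would leave cells empty.  Negative correlations are
  preserved; zero-variance vectors yield NaN (degenerate), never a
  substituted value.
- **Steepness.** The fitted Weibull is evaluated on a grid of 101 points
  uniform in log₁₀(t) over the curve's time range, and the mean plane-curve
  curvature `|y″|/(1 + y′²)^{3/2}` of log₁₀(accuracy) vs log₁₀(t) is taken
  at interior grid points by central differences.  The log–log axes follow
  the convention in which SAT steepness is reported; the statistic is then
  invariant to rescaling the time unit (τ and the range together).  Grid
  size, axes and range are configurable; defaults are stated here because
  different choices give numerically different steepness values.
- **Timestep–FLOP correlation.** Pearson correlation of the timestep index
  1..T with user-supplied per-output FLOP counts, validating that an
  architecture's ordinal time analog tracks real computational cost.
- **Benchmark assembly.** Every model is compared with every human
  observer; the `human` baseline row compares the average human curve
  with each individual, giving the error floor set by inter-observer
  variability.  Summaries report median, quartiles, and points beyond
  1.5×IQR; degenerate (NaN) values are excluded and counted.  Steepness is
  reported per entity and perturbation level from the (normalized) family
  rows; the average-human steepness is a fit to the averaged curve, with
  per-observer fits available by calling `curve_steepness` on individual
  curves.

## Synthetic observers

The generator reproduces the statistical structure the analysis consumes,
not the stimuli.  A synthetic human draws each timed trial independently:
a miss with a latency-dependent probability (default 15% at 500 ms falling
to 2% at 1,500 ms — the shortest latency leaves too little time to
respond; the true rates are a free parameter of the generator), otherwise
correct with the Weibull probability adjusted by the condition's
(asymptote scale, τ multiplier) pair and a per-category τ multiplier, with
errors uniform over the 15 wrong categories.  Response times are the beep
latency plus truncated-normal jitter (σ = 60 ms) confined to
[0, latency + grace].  Category counts per block are as equal as possible
(floor allocation, random remainder).  All draws flow from one integer
seed per observer; identical specs yield byte-identical trial tables.

Default human Weibull parameters are τ = 1,150 ms, β = 3.5, λ = 0.22,
chosen so the unperturbed curve is near chance (≈0.10) at 500 ms, reaches
≈0.72 at 1,500 ms, and saturates at 0.78 untimed — the accuracy range the
paradigm is designed to span.  The population sampler jitters τ and β
lognormally (10%) and λ uniformly (±0.05) across observers and draws
lognormal (15%) per-category difficulty multipliers.

Synthetic model observers are defined by a per-timestep accuracy table per
condition, built from named profiles: `gradual_wide` rises smoothly over a
wide range (cascaded-network-like), `steep_saturating` jumps to its
ceiling after the first timestep (early-exit-like), `shallow_low_range`
creeps over a narrow low band.  By default the accuracy range shrinks with
perturbation rank (scales 1.0, 0.5, 0.35, 0.25), mirroring how mild
degradation sharply depresses peak network accuracy while humans degrade
more gracefully.

**What the generator does not emulate:** real images and their
item-level difficulty correlations between humans and networks, sequential
effects (fatigue, learning, block-order effects beyond the order flag),
non-stationary miss behavior, response-time dependence on difficulty, and
any architecture-specific network behavior.  Tests passing on synthetic
data therefore validate the analysis machinery and its statistical
calibration, not claims about real observers or trained networks.

## Problem sizes and numerical choices

The test suite and the acceptance script run populations of 2–6 synthetic
observers (1,100 trials each) and model observers with 100–200 images per
condition — sizes at which every statistical contract is tested against
exact binomial confidence bounds or 3-SE Monte-Carlo bands while the whole
suite completes in well under a minute.  Metric oracle checks (double-loop
RMSE, rank-then-Pearson) use 200 random instances at 1e−12 tolerance.
Degenerate inputs are handled uniformly: flagged (NaN + degenerate flag),
logged, excluded from summaries with their count reported, never coerced.

## Known limitations

- The ±100 ms window is used only for observer exclusion; whether late
  responses of kept observers should additionally be dropped is left as a
  pre-filtering choice rather than a pipeline stage.
- Weibull parameter recovery degrades near the edge of the sampled time
  window (see Identifiability); reported β values for nearly flat or
  saturating curves should be read alongside the degenerate flags.
- The affine timestep mapping assumes the reference curve is monotone
  enough for interpolation-based fitting; strongly non-monotone references
  can yield local minima, and only one (speed, delay) pair is fitted per
  model.
- Normalized accuracies above 1 are possible (an observer better than the
  group baseline); the Weibull's upper asymptote is capped at 1, so fits
  to such curves saturate the lapse bound.
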