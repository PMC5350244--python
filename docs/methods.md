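# Methods

## Model and rationale

The package targets recordings of rhythmically bursting neurons observed
through noisy optical reporters (voltage-sensitive or calcium dyes).  The
activity profile assumed per burst cycle is: a ramp-up of the membrane
potential into a depolarisation plateau on which spikes ride, a ramp-down,
and a silent phase.  Spike times are unreliable in such data, so the unit of
timing analysis is the cycle's set of *salient points*: ramp-up midpoint,
plateau begin, plateau end, ramp-down midpoint.

All estimators are linear least-squares slopes over sliding windows of
`2τ+1` samples.  The centred slope has the closed form
`m_t = 3/(τ(τ+1)(2τ+1)) · Σ (u−t)·x_u`, i.e. a first-order Savitzky–Golay
derivative filter; the forward/backward slopes over `t…t+2τ` / `t−2τ…t` are
the centred slope evaluated at `t+τ` / `t−τ` (the slope of a least-squares
line is invariant to how the window is indexed, and intercepts are never
used).

## Noise propagation

For additive i.i.d. Gaussian noise of SD σ the slope noise is exactly
Gaussian, zero-mean, with SD `σ·√(3/(τ(τ+1)(2τ+1)))`, by
`Σ_{u=−τ}^{τ} u² = τ(τ+1)(2τ+1)/3`.  A variant of this formula circulates
with `2τ+2` in the final factor of the denominator; the sum identity above
gives `2τ+1`, the package implements `2τ+1`, and `simulate_slope_noise`
(10⁵ Monte-Carlo windows, agreement within 3 %, mean within 3 standard
errors of zero) confirms it.  The comparator statistic, a plain
`2τ+1`-point local average, has noise SD `σ/√(2τ+1)`; the ratio
`√(3/(τ(τ+1)))` is below 1 for every `τ ≥ 2` and above 1 only at `τ = 1`,
so slope-based features are the more noise-robust choice for any
non-trivial window.

## Detection pipeline and parameters

* `smoothing.window` (samples, default **10**, centred): pre-smoothing by a
  sliding mean.  Centred alignment avoids the ~window/2 systematic lag that
  trailing alignment would add to every feature time; trailing is available
  for comparison.  Edge windows truncate to available samples.
* `tau` (samples, no default — analyst-chosen): half-window of the slope
  fits.  Guidance: half the ramp duration or slightly less.  Larger τ
  suppresses noise (SD ∝ τ^{−3/2}) but blurs timing.
* Acceptability bands: a detected slope extremum is *valid* only if its
  slope value lies in the band for its kind.  `default_bands` derives them
  from the observed slope distribution — max band `[fraction·max m_t, ∞)`,
  min band mirrored, with `fraction` defaulting to **0.5** — which is
  appropriate when ramps dominate the slope distribution (plateau-dominant
  regime).  When spikes are taller than the plateau the analyst must supply
  a narrow band bracketing the ramp-slope magnitude (e.g. taken from a
  quiet stretch or a spike-free calibration); the tests derive it from the
  spike-free slope distribution of the same template.
* `epsilon` (default **0.1**): the near-zero band for plateau bounds is
  `[−ε·m_max, ε·m_max]`, `m_max` being the largest absolute slope among
  accepted extrema.
* Whole-recording detection (`detect_cycles`) finds maximal runs of in-band
  centred slope, takes each run's extremum as a candidate, collapses
  consecutive same-kind candidates to the steepest (threshold runs can be
  split by noise; keeping the steepest is deterministic and unbiased toward
  either fragment), then pairs alternating max→min candidates.  Unpaired
  leading/trailing candidates (cycles straddling the trace edges) are
  discarded, not extrapolated.  Single-interval operations
  (`max_slope_point`, `min_slope_point`) remain for analyst-chosen windows.
* Plateau bounds are searched strictly inside `(t*, t**)`; if no forward
  (resp. backward) slope enters the zero band there, or the bounds cross,
  the cycle is flagged `plateau_undetermined` — its slope extrema still
  feed the delay analysis.  Ties in arg-extrema break to the earliest
  index.  All detection is deterministic.

## Synchronisation assay

Same-kind valid points of a neuron pair are matched greedily by nearest
neighbour within ±`max_lag` (default: half the median inter-point period of
the first neuron), each point used at most once; the rule is symmetric in
spirit, deterministic, and robust to single missed cycles.  Delay SDs use
the n−1 denominator.  Conditions are compared with a two-sided
variance-ratio F-test, `F = s²_treatment/s²_control` with
`(n_t−1, n_c−1)` degrees of freedom; two-sided because both loosening and
tightening of phase locking occur.  Significance is per-comparison at
α = 0.05 with no multiple-testing correction by default (a Bonferroni flag
exists).  `count_significant` partitions comparisons into
larger/lower/not-significant; `count_significant_pvalues` counts strictly
`p < α` for published tables that report p-values only.

Event-triggered averaging aligns windows spanning a fixed number of
consecutive rhythm cycles (default 3) at analyst-marked trigger events and
truncates all windows to the shortest rather than resampling — interpolation
on noisy data would manufacture correlated noise.

## Synthetic data

The generator emulates the target recordings, not their biophysics: each
cycle is a piecewise-linear trapezoid (exact integer corner and midpoint
ground truth — precisely what the detector is validated against), with
optional brief triangular spikes at Poisson times on the plateau.  Defaults:
1.5 ms sampling (666 frames/s), 900 ms cycle period, 120/360/120 ms
ramp-up/plateau/ramp-down, three neurons, 60 cycles (recordings of this kind
typically contain 50–80), per-cycle Gaussian start-time jitter of SD 4.5 ms,
additive noise SD 5 % of plateau height (optical noise levels vary; the
tests span 1–10 %).  Two amplitude regimes: plateau-dominant
(plateau ≫ spikes; spikes 0.15, rate 0.03/ms) and spike-dominant
(spikes ≫ plateau; plateau 0.2, spikes 1.0 tall and 1.5 ms brief, as somatic
action potentials are).  Multi-neuron datasets are phase-offset, jittered
copies of one template; `make_condition_pair` scales the jitter SD by a
de-synchronisation factor with fresh per-condition seeds derived from the
base seed.  What the generator does **not** emulate: bleaching and drift,
correlated (shared-light-path) noise, cycle-period wander, waveform
variability between cycles, and synaptic coupling between the simulated
neurons.  Passing tests therefore show correctness of the estimators and
statistics under the stated noise model, not end-to-end performance on any
particular biological preparation.

## Numerical choices

* Missing slope values at trace edges are NaN, never zero-filled; padding
  would fabricate extrema.
* All internal times are 0-based sample indices; milliseconds only at
  reporting (`sampling_interval`, default 1.5 ms).
* Jittered cycle starts are rounded to integer samples; this adds a
  quantisation variance of ~1/12 sample² per neuron to true delays, well
  inside the stated tolerances at the default sampling rate.
* Monte-Carlo problem sizes: the variance-comparison replicate studies use a
  compact 450 ms-period template (60-sample ramps, τ = 30, 60 cycles,
  2 % noise) so that a 1500-replicate study completes in well under a
  minute; the conclusions are invariant to the template scale because the
  F-statistic depends only on delay variances.
* The reference p-value table bundled with the package carries 44 published
  F-test comparisons (11 PY pairs × 4 feature kinds); counting strictly
  `p < 0.05` yields 22 significant comparisons.

## Known limitations

* On long perfectly linear ramps the noise-free slope profile is nearly flat
  around its peak, so under noise the arg-max timing can wander several
  samples even when the slope value is estimated accurately; this inflates
  delay SDs equally in both conditions and hence dilutes (never inflates)
  variance-ratio effects.
* The F-test assumes approximately normal, independent delays; per-cycle
  jitter satisfies this in simulation, but slowly drifting rhythms in real
  data would violate independence.
* No sub-sample interpolation of feature times, no resampling of
  non-uniform time bases, and no spike detection: these are outside the
  method's scope by design.
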