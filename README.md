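# slopesync

Robust extraction of burst-timing features from noisy optical-imaging traces
of rhythmic neurons, and quantification of how the temporal relationship
between neurons changes (synchronisation / de-synchronisation) across
experimental conditions.

## Who this is for

Voltage-sensitive-dye (VSD) and calcium imaging make it possible to record
many synaptically connected neurons at single-neuron resolution — e.g. the
pyloric constrictor (PY) neurons of the crustacean stomatogastric ganglion —
but the traces are too noisy for spike-level analysis.  `slopesync`
implements a slope-based alternative: instead of spikes it tracks four
*salient points* of each burst cycle, which can be estimated robustly from
noisy data, and uses their pairwise timing statistics to assay phase locking.

## The method

For a smoothed trace `x_t` (default: 10-sample sliding-window mean), the
local slope over a window of `2τ+1` samples centred on `t` is the
least-squares line slope, available in closed form:

```
m_t = 3 / (τ(τ+1)(2τ+1)) · Σ_{u=t−τ}^{t+τ} (u−t)·x_u
```

Per burst cycle the package detects

* the **maximum slope point** `t*` (midpoint of the ramp-up into the burst),
* the **minimum slope point** `t**` (midpoint of the ramp-down),
* the **plateau begin/end**: the first time after `t*` whose *forward* slope
  (least-squares slope over `t … t+2τ`) enters a near-zero band
  `[−z*, z*]`, and the last time before `t**` whose *backward* slope does.

Slope extrema whose value falls outside an analyst-set acceptability band are
flagged *spurious* (silent stretches, spike artefacts) and excluded.  With
additive Gaussian noise of SD σ the slope estimate carries noise of SD
`σ·√(3/(τ(τ+1)(2τ+1)))` — smaller than the `σ/√(2τ+1)` of a plain local
average for every `τ ≥ 2`, which is why the slope features are the robust
ones (`slopesync.noise_theory` has both closed forms plus a Monte-Carlo
check).

Phase locking of a neuron pair is quantified by the standard deviation of
the delays between corresponding salient points; a change of that SD between
conditions (e.g. before/after dopamine) is tested with a two-sided
variance-ratio F-test at α = 0.05 per comparison.

## Worked example

Simulate a two-neuron rhythm (60 cycles, 1.5 ms sampling, per-cycle timing
jitter SD 4.5 ms, noise SD 5 % of plateau height), create a "treatment"
condition with the jitter doubled, and run the full pairwise workflow:

```python
import slopesync as ss

config = ss.PopulationConfig(seed=42, n_neurons=2, n_cycles=60, jitter_sd=4.5)
control, treatment = ss.make_condition_pair(config, desync_factor=2.0)

params = ss.SyncParams(detection=ss.DetectionParams(tau=40))
result = ss.run_sync_experiment(control.traces, treatment.traces, params)
print(result.grid[["pair", "kind", "n_control", "sd_control", "sd_treatment",
                   "f_statistic", "p_value", "direction"]].round(4).to_string(index=False))
print(result.counts)
```

prints

```
   pair          kind  n_control  sd_control  sd_treatment  f_statistic  p_value direction
PY1-PY2     max_slope         60     10.2389       11.7548       1.3180   0.2917      none
PY1-PY2 plateau_begin         60      9.1152       13.7130       2.2632   0.0021    larger
PY1-PY2   plateau_end         60     12.4697       12.1590       0.9508   0.8470      none
PY1-PY2     min_slope         60      7.9338       13.2586       2.7927   0.0001    larger
SignificanceCounts(n_larger=2, n_lower=0, n_ns=2)
```

Delay SDs are in milliseconds.  Doubling the timing jitter quadruples the
true delay variance; at this noise level two of the four feature kinds reach
significance for this pair, both in the "larger" direction — the signature of
de-synchronisation.  (Detection timing error adds equally to both
conditions, which dilutes the observed variance ratio below 4.)

The same pipeline is available from the shell:

```sh
slopesync simulate --seed 42 --neurons 2 --cycles 60 --desync-factor 2 --out-dir sim/
slopesync sync --control sim/control_traces.csv --treatment sim/treatment_traces.csv \
          --tau 40 --out-grid grid.csv --out-summary summary.json
slopesync noise-check --tau 5 --sigma 1.0
```

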