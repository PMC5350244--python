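"""Ground-truth-labelled synthetic traces of rhythmically bursting neurons.

The waveform is a piecewise-linear trapezoid per burst cycle: a linear ramp-up
from baseline to the plateau level, a flat plateau carrying optional brief
triangular spikes at Poisson times, a linear ramp-down, and silence until the
next cycle.  A trapezoid is used instead of a conductance-based model because
its corner and ramp-midpoint times are exact integers, which is precisely what
the detector is validated against.  Two amplitude regimes are provided:
*plateau-dominant* (plateau height >> spike amplitude, typical of invertebrate
central-pattern-generator neurons seen through voltage-sensitive dyes) and
*spike-dominant* (spikes >> plateau, typical of cortical neurons).

Multi-neuron rhythms are jittered, phase-offset copies of one template: cycle
``k`` of neuron ``i`` starts at ``k*period + offset_i + N(0, jitter_sd_i)``.
Scaling the per-cycle timing jitter between two generated conditions emulates
neuromodulator-induced de-synchronisation.  All randomness flows from a single
mandatory seed; identical configurations are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .slope_estimation import DEFAULT_SAMPLING_INTERVAL_MS, Trace

__all__ = [
    "CycleTemplate",
    "PopulationConfig",
    "PopulationDataset",
    "generate_trace",
    "generate_population",
    "make_condition_pair",
]

TRUTH_COLUMNS = [
    "neuron_id",
    "cycle",
    "t_start",
    "t_ramp_up_mid",
    "t_plateau_begin",
    "t_plateau_end",
    "t_ramp_down_mid",
]


@dataclass(frozen=True)
class CycleTemplate:
    """Shape of one burst cycle; all durations in milliseconds.

    Defaults describe a pyloric-range rhythm (900 ms period) in the
    plateau-dominant regime.  ``spike_rate`` is spikes per millisecond on the
    plateau; ``spike_width`` is the half-width of the triangular deflection.
    """

    period: float = 900.0
    ramp_up: float = 120.0
    plateau: float = 360.0
    ramp_down: float = 120.0
    baseline: float = 0.0
    plateau_height: float = 1.0
    spike_amplitude: float = 0.0
    spike_rate: float = 0.0
    spike_width: float = 4.5

    def __post_init__(self) -> None:
        for name in ("period", "ramp_up", "plateau", "ramp_down"):
            if not (getattr(self, name) > 0):
                raise InvalidInputError(f"{name} must be positive")
        if self.ramp_up + self.plateau + self.ramp_down > self.period:
            raise InvalidInputError("ramp_up + plateau + ramp_down must fit in the period")
        if self.spike_rate < 0 or self.spike_width <= 0:
            raise InvalidInputError("spike_rate must be >= 0 and spike_width > 0")

    @classmethod
    def plateau_dominant(cls) -> "CycleTemplate":
        """Plateau much taller than spikes; all four salient points usable."""
        return cls(spike_amplitude=0.15, spike_rate=0.03)

    @classmethod
    def spike_dominant(cls) -> "CycleTemplate":
        """Spikes much taller than the plateau; only slope extrema are
        usable and acceptance bands must be set by the analyst.  Spikes are
        brief (~1.5 ms), as somatic action potentials are."""
        return cls(
            plateau_height=0.2, spike_amplitude=1.0, spike_rate=0.02, spike_width=1.5
        )


def _samples(duration_ms: float, si: float) -> int:
    return int(round(duration_ms / si))


def _template_samples(template: CycleTemplate, si: float) -> tuple[int, int, int, int]:
    ru = _samples(template.ramp_up, si)
    pl = _samples(template.plateau, si)
    rd = _samples(template.ramp_down, si)
    per = _samples(template.period, si)
    if min(ru, pl, rd) < 1:
        raise InvalidInputError("every phase must span at least one sample")
    if ru + pl + rd > per:
        raise InvalidInputError("cycle phases do not fit in the sampled period")
    return per, ru, pl, rd


def _trapezoid(template: CycleTemplate, ru: int, pl: int, rd: int) -> np.ndarray:
    h = template.plateau_height
    shape = np.empty(ru + pl + rd + 1)
    shape[:ru] = h * np.arange(ru) / ru
    shape[ru : ru + pl + 1] = h
    shape[ru + pl + 1 :] = h * (1.0 - np.arange(1, rd + 1) / rd)
    return shape


def _place_cycle(
    values: np.ndarray,
    start: int,
    shape: np.ndarray,
    template: CycleTemplate,
    ru: int,
    pl: int,
    si: float,
    rng: np.random.Generator,
) -> None:
    values[start : start + shape.size] += shape
    if template.spike_amplitude > 0 and template.spike_rate > 0:
        n_spikes = rng.poisson(template.spike_rate * template.plateau)
        spike_times = start + ru + np.sort(rng.uniform(0, pl, size=n_spikes))
        half = max(1, _samples(template.spike_width, si))
        bump = template.spike_amplitude * (1.0 - np.abs(np.arange(-half, half + 1)) / half)
        for st in np.round(spike_times).astype(int):
            lo, hi = st - half, st + half + 1
            blo, bhi = max(0, -lo), bump.size - max(0, hi - values.size)
            values[max(0, lo) : min(values.size, hi)] += bump[blo:bhi]


def generate_trace(
    template: CycleTemplate,
    n_cycles: int,
    noise_sigma: float = 0.0,
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL_MS,
    seed: int = 0,
    neuron_id: str = "sim",
    lead_in: float = 0.0,
) -> tuple[Trace, pd.DataFrame]:
    """Generate one neuron's trace plus its exact ground-truth feature table.

    The trace holds ``lead_in`` plus ``n_cycles`` periods of samples; cycle
    ``k`` starts at ``lead_in + k*period``.  The ground-truth table records,
    per cycle, the exact sample indices of the ramp-up midpoint, plateau
    begin/end corners and ramp-down midpoint.
    """
    if n_cycles < 1:
        raise InvalidInputError("n_cycles must be >= 1")
    si = sampling_interval
    per, ru, pl, rd = _template_samples(template, si)
    lead = _samples(lead_in, si)
    n = lead + n_cycles * per
    rng = np.random.default_rng(seed)
    values = np.full(n, float(template.baseline))

    shape = _trapezoid(template, ru, pl, rd)
    rows = []
    for k in range(n_cycles):
        start = lead + k * per
        if start + shape.size > n:
            break
        _place_cycle(values, start, shape, template, ru, pl, si, rng)
        rows.append(
            {
                "neuron_id": neuron_id,
                "cycle": k,
                "t_start": start,
                "t_ramp_up_mid": start + ru // 2,
                "t_plateau_begin": start + ru,
                "t_plateau_end": start + ru + pl,
                "t_ramp_down_mid": start + ru + pl + rd // 2,
            }
        )
    if noise_sigma > 0:
        values += rng.normal(0.0, noise_sigma, size=n)
    trace = Trace(values=values, neuron_id=neuron_id, sampling_interval=si)
    return trace, pd.DataFrame(rows, columns=TRUTH_COLUMNS)


@dataclass(frozen=True)
class PopulationConfig:
    """A multi-neuron rhythm: jittered, phase-offset copies of one template.

    ``jitter_sd`` (ms) may be a scalar or a per-neuron sequence; ``seed`` is
    mandatory so that every dataset is reproducible.  Defaults mirror the
    recording conditions the detector targets: three PY-like neurons, 60
    cycles each, 1.5 ms sampling, noise SD 5 % of plateau height.
    """

    seed: int
    n_neurons: int = 3
    template: CycleTemplate = field(default_factory=CycleTemplate.plateau_dominant)
    n_cycles: int = 60
    phase_offsets: tuple[float, ...] | None = None
    jitter_sd: float | tuple[float, ...] = 4.5
    noise_sigma: float = 0.05
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL_MS

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise InvalidInputError("n_neurons must be >= 1")
        jit = self.jitter_sd
        if np.isscalar(jit):
            jit = (float(jit),) * self.n_neurons
        else:
            jit = tuple(float(j) for j in jit)
        if len(jit) != self.n_neurons:
            raise InvalidInputError("jitter_sd must be scalar or one value per neuron")
        if any(j < 0 for j in jit):
            raise InvalidInputError("jitter_sd must be nonnegative")
        object.__setattr__(self, "jitter_sd", jit)
        offsets = self.phase_offsets
        if offsets is None:
            offsets = tuple(15.0 * i for i in range(self.n_neurons))
        else:
            offsets = tuple(float(o) for o in offsets)
        if len(offsets) != self.n_neurons:
            raise InvalidInputError("phase_offsets must have one value per neuron")
        object.__setattr__(self, "phase_offsets", offsets)


@dataclass(frozen=True)
class PopulationDataset:
    """Generated traces plus the exact ground-truth feature table."""

    traces: dict[str, Trace]
    truth: pd.DataFrame
    config: PopulationConfig


def generate_population(config: PopulationConfig) -> PopulationDataset:
    """Generate the multi-neuron dataset described by ``config``.

    Each neuron gets an independent noise stream and independent per-cycle
    Gaussian start-time jitter; a half-period lead-in and tail of baseline
    keep every cycle's slope windows inside the trace.  True pairwise delays
    between any two neurons are derivable exactly from the truth table.
    """
    si = config.sampling_interval
    template = config.template
    per, ru, pl, rd = _template_samples(template, si)
    lead = per // 2
    n = lead + config.n_cycles * per + per  # half-period lead-in, full-period tail
    shape = _trapezoid(template, ru, pl, rd)

    streams = np.random.SeedSequence(config.seed).spawn(config.n_neurons)
    traces: dict[str, Trace] = {}
    rows = []
    for i in range(config.n_neurons):
        rng = np.random.default_rng(streams[i])
        neuron_id = f"PY{i + 1}"
        values = np.full(n, float(template.baseline))
        jitters = rng.normal(0.0, config.jitter_sd[i], size=config.n_cycles)
        for k in range(config.n_cycles):
            start_ms = k * template.period + config.phase_offsets[i] + jitters[k]
            start = lead + _samples(start_ms, si)
            if start < 0 or start + shape.size > n:
                continue
            _place_cycle(values, start, shape, template, ru, pl, si, rng)
            rows.append(
                {
                    "neuron_id": neuron_id,
                    "cycle": k,
                    "t_start": start,
                    "t_ramp_up_mid": start + ru // 2,
                    "t_plateau_begin": start + ru,
                    "t_plateau_end": start + ru + pl,
                    "t_ramp_down_mid": start + ru + pl + rd // 2,
                }
            )
        if config.noise_sigma > 0:
            values += rng.normal(0.0, config.noise_sigma, size=n)
        traces[neuron_id] = Trace(values=values, neuron_id=neuron_id, sampling_interval=si)
    return PopulationDataset(
        traces=traces, truth=pd.DataFrame(rows, columns=TRUTH_COLUMNS), config=config
    )


def make_condition_pair(
    config: PopulationConfig, desync_factor: float
) -> tuple[PopulationDataset, PopulationDataset]:
    """Generate a (control, treatment) dataset pair.

    The treatment dataset is structurally identical but has every neuron's
    per-cycle timing jitter SD multiplied by ``desync_factor`` (>= 1), with
    fresh per-condition seeds derived deterministically from ``config.seed``.
    A factor of 1 yields statistically exchangeable conditions; a factor of
    ``f`` scales the true pairwise delay variance by ``f**2``.
    """
    if desync_factor < 1:
        raise InvalidInputError("desync_factor must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(2)
    seed_c, seed_t = (int(c.generate_state(1)[0] % (2**31)) for c in children)
    control_cfg = replace(config, seed=seed_c)
    treatment_cfg = replace(
        config,
        seed=seed_t,
        jitter_sd=tuple(j * desync_factor for j in config.jitter_sd),
    )
    return generate_population(control_cfg), generate_population(treatment_cfg)
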