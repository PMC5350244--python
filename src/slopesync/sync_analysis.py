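"""Temporal-delay statistics and variance-change assays for neuron pairs.

Phase locking between two rhythmic neurons shows up as a small standard
deviation of the delays between their corresponding salient points; a loss of
locking (de-synchronisation, e.g. after neuromodulator exposure) shows up as
an increase of that SD.  The assay is therefore: match same-kind salient
points across a neuron pair within each condition, compute the delay SD per
condition, and compare the two SDs with a two-sided variance-ratio F-test at
a per-comparison significance level (no multiple-testing correction by
default; a Bonferroni option exists).

The matching rule (nearest neighbour within +/- half the median cycle period,
greedy on |delay|, each point used once) is a deterministic convention of this
package; it is robust to single missed cycles on either side.
"""

from __future__ import annotations

import itertools
from collections import namedtuple
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError, InvalidInputError
from .feature_detection import KINDS, DetectionParams, SalientPoint, analyse_trace
from .slope_estimation import Trace

__all__ = [
    "DelaySeries",
    "VarianceComparison",
    "TriggerEvents",
    "SignificanceCounts",
    "SyncParams",
    "SyncResult",
    "match_points",
    "delay_stats",
    "f_test",
    "count_significant",
    "count_significant_pvalues",
    "load_reference_pvalues",
    "event_triggered_average",
    "run_sync_experiment",
]


@dataclass(frozen=True)
class DelaySeries:
    """Signed delays between matched same-kind salient points of a pair.

    ``delays`` holds ``t_b - t_a`` per matched pair, in ``units`` ("samples"
    or "ms"); ``n_unmatched`` counts the points dropped on either side.
    """

    pair_id: tuple[str, str]
    kind: str
    condition: str
    delays: np.ndarray
    units: str = "samples"
    n_unmatched: int = 0

    def __post_init__(self) -> None:
        delays = np.asarray(self.delays, dtype=float)
        if delays.size and not np.all(np.isfinite(delays)):
            raise InvalidInputError("delays must be finite")
        object.__setattr__(self, "delays", delays)

    @property
    def n(self) -> int:
        return self.delays.size

    def to_ms(self, sampling_interval: float) -> "DelaySeries":
        if self.units == "ms":
            return self
        return replace(self, delays=self.delays * sampling_interval, units="ms")


@dataclass(frozen=True)
class VarianceComparison:
    """F-test result comparing delay SDs between two conditions.

    ``f_statistic`` is oriented treatment/control; ``direction`` reports which
    way the treatment SD moved when the change is significant at ``alpha``.
    """

    pair_id: tuple[str, str]
    kind: str
    sd_control: float
    sd_treatment: float
    n_control: int
    n_treatment: int
    f_statistic: float
    p_value: float
    direction: str
    significant: bool
    alpha: float = 0.05


@dataclass(frozen=True)
class TriggerEvents:
    """Strictly increasing sample indices of analyst-marked rhythm events
    (e.g. onsets of the LP phase of the pyloric rhythm)."""

    times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=int)
        if times.ndim != 1 or times.size == 0:
            raise InvalidInputError("triggers must be a non-empty 1-d sequence")
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError("trigger times must be strictly increasing")
        object.__setattr__(self, "times", times)

    @property
    def n(self) -> int:
        return self.times.size


def _point_times(points: Sequence[SalientPoint], kind: str | None) -> np.ndarray:
    times = [
        p.t
        for p in points
        if (kind is None or p.kind == kind) and p.valid is not False
    ]
    return np.asarray(sorted(times), dtype=float)


def match_points(
    a: Sequence[SalientPoint],
    b: Sequence[SalientPoint],
    kind: str | None = None,
    max_lag: float | None = None,
    pair_id: tuple[str, str] = ("a", "b"),
    condition: str = "",
) -> DelaySeries:
    """Greedy nearest-neighbour matching of same-kind valid salient points.

    Candidate pairs within ``+/- max_lag`` samples are accepted in order of
    increasing |delay| (ties: earlier point in ``a`` first), each point used
    at most once.  ``max_lag`` defaults to half the median inter-point period
    of ``a``.  Delays are ``t_b - t_a`` in samples.
    """
    ta = _point_times(a, kind)
    tb = _point_times(b, kind)
    if ta.size == 0 or tb.size == 0:
        return DelaySeries(pair_id, kind or "any", condition, np.empty(0),
                           n_unmatched=ta.size + tb.size)
    if max_lag is None:
        if ta.size < 2:
            raise InvalidInputError("max_lag required when neuron a has < 2 points")
        max_lag = float(np.median(np.diff(ta))) / 2.0
    if not (max_lag > 0):
        raise InvalidInputError("max_lag must be positive")

    lags = tb[None, :] - ta[:, None]
    ii, jj = np.nonzero(np.abs(lags) <= max_lag)
    order = np.lexsort((jj, ii, np.abs(lags[ii, jj])))
    used_a = np.zeros(ta.size, bool)
    used_b = np.zeros(tb.size, bool)
    matches: list[tuple[int, float]] = []
    for k in order:
        i, j = ii[k], jj[k]
        if not used_a[i] and not used_b[j]:
            used_a[i] = used_b[j] = True
            matches.append((i, lags[i, j]))
    matches.sort()  # report delays in a's temporal order
    delays = np.asarray([d for _, d in matches], dtype=float)
    n_unmatched = int((~used_a).sum() + (~used_b).sum())
    return DelaySeries(
        pair_id, kind or "any", condition, delays, n_unmatched=n_unmatched
    )


def delay_stats(d: DelaySeries) -> tuple[float, float]:
    """Sample mean and sample SD (``n - 1`` denominator) of the delays."""
    if d.n < 2:
        raise InsufficientDataError("need at least 2 delays for mean/SD")
    return float(np.mean(d.delays)), float(np.std(d.delays, ddof=1))


def f_test(
    control: DelaySeries, treatment: DelaySeries, alpha: float = 0.05
) -> VarianceComparison:
    """Two-sided variance-ratio F-test on delay SDs across conditions.

    ``F = s_treatment^2 / s_control^2`` with ``(n_t - 1, n_c - 1)`` degrees of
    freedom; ``p = 2 * min(P(F <= f), P(F >= f))`` capped at 1.  Two-sided
    because both loosening and tightening of phase locking are of interest.
    """
    if control.n < 2 or treatment.n < 2:
        raise InsufficientDataError("both conditions need at least 2 delays")
    sd_c = float(np.std(control.delays, ddof=1))
    sd_t = float(np.std(treatment.delays, ddof=1))
    if sd_c == 0.0 and sd_t == 0.0:
        raise DegenerateInputError("both conditions have zero delay variance")
    dfn, dfd = treatment.n - 1, control.n - 1
    if sd_c == 0.0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (sd_t / sd_c) ** 2
        dist = stats.f(dfn, dfd)
        p = min(1.0, 2.0 * min(dist.cdf(f_stat), dist.sf(f_stat)))
    significant = p < alpha
    if significant and sd_t > sd_c:
        direction = "larger"
    elif significant and sd_t < sd_c:
        direction = "lower"
    else:
        direction = "none"
    return VarianceComparison(
        pair_id=control.pair_id,
        kind=control.kind,
        sd_control=sd_c,
        sd_treatment=sd_t,
        n_control=control.n,
        n_treatment=treatment.n,
        f_statistic=f_stat,
        p_value=float(p),
        direction=direction,
        significant=significant,
        alpha=alpha,
    )


SignificanceCounts = namedtuple("SignificanceCounts", ["n_larger", "n_lower", "n_ns"])


def count_significant(
    comparisons: Iterable[VarianceComparison], alpha: float = 0.05
) -> SignificanceCounts:
    """Partition comparisons into (larger, lower, not significant) at ``alpha``.

    Significance is re-evaluated as ``p < alpha``; direction comes from the
    SDs.  The three counts sum to the input size.
    """
    n_larger = n_lower = n_ns = 0
    for c in comparisons:
        if c.p_value < alpha and c.sd_treatment > c.sd_control:
            n_larger += 1
        elif c.p_value < alpha and c.sd_treatment < c.sd_control:
            n_lower += 1
        else:
            n_ns += 1
    return SignificanceCounts(n_larger, n_lower, n_ns)


def count_significant_pvalues(pvalues: Iterable[float], alpha: float = 0.05) -> int:
    """Number of p-values strictly below ``alpha``.

    For published comparison tables that report p-values without the
    underlying SDs, so no direction can be attributed.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must be finite and within [0, 1]")
    return int(np.sum(p < alpha))


def load_reference_pvalues() -> pd.DataFrame:
    """Reference table of 44 published F-test p-values (11 PY neuron pairs x
    4 salient-point kinds) from a dopamine de-synchronisation experiment.

    Columns: ``pair`` (1-11), ``kind``, ``p_value``.
    """
    with resources.files("slopesync.data").joinpath("da_ftest_pvalues.csv").open() as fh:
        return pd.read_csv(fh)


def event_triggered_average(
    trace: Trace, triggers: TriggerEvents, cycles_per_window: int = 3
) -> Trace:
    """Average trace windows spanning consecutive trigger runs.

    Window ``i`` runs from trigger ``i`` to trigger ``i + cycles_per_window``;
    all windows are truncated to the shortest one (no resampling) and averaged
    elementwise.  Used to denoise rhythmic recordings and identify neurons.
    """
    if cycles_per_window < 1:
        raise InvalidInputError("cycles_per_window must be >= 1")
    times = triggers.times
    if times.size < cycles_per_window + 1:
        raise InsufficientDataError(
            f"need at least {cycles_per_window + 1} triggers, got {times.size}"
        )
    if times[0] < 0 or times[-1] > trace.n:
        raise InvalidInputError("trigger times fall outside the trace")
    starts = times[:-cycles_per_window]
    stops = times[cycles_per_window:]
    length = int(np.min(stops - starts))
    windows = np.stack([trace.values[s : s + length] for s in starts])
    return Trace(
        values=windows.mean(axis=0),
        neuron_id=f"{trace.neuron_id}_eta",
        sampling_interval=trace.sampling_interval,
        t0=0,
    )


@dataclass(frozen=True)
class SyncParams:
    """Parameters of the pairwise synchronisation experiment."""

    detection: DetectionParams
    max_lag: float | None = None  # samples; default: half median period
    alpha: float = 0.05
    units: str = "ms"
    bonferroni: bool = False


@dataclass(frozen=True)
class SyncResult:
    """Comparison grid (one row per pair x kind) plus summary counts."""

    grid: pd.DataFrame
    comparisons: tuple[VarianceComparison, ...]
    counts: SignificanceCounts
    alpha: float


def _condition_points(
    dataset: Mapping[str, Trace], params: SyncParams
) -> dict[str, dict[str, list[SalientPoint]]]:
    return {
        neuron_id: analyse_trace(trace, params.detection).points_by_kind()
        for neuron_id, trace in dataset.items()
    }


def run_sync_experiment(
    control: Mapping[str, Trace],
    treatment: Mapping[str, Trace],
    params: SyncParams,
) -> SyncResult:
    """Full workflow: detection per neuron and condition, delay series per
    (pair, kind), F-test per row, and summary significance counts.

    Both datasets must share neuron labels.  Rows with fewer than two matched
    delays in either condition are reported with NaN statistics and counted as
    not significant.  Delay SDs are reported in ``params.units``.
    """
    shared = sorted(set(control) & set(treatment))
    if len(shared) < 2:
        raise InvalidInputError("need at least two shared neuron labels")
    if set(control) != set(treatment):
        raise InvalidInputError("control and treatment must share neuron labels")

    pts_c = _condition_points(control, params)
    pts_t = _condition_points(treatment, params)
    si = next(iter(control.values())).sampling_interval
    scale = si if params.units == "ms" else 1.0

    pairs = list(itertools.combinations(shared, 2))
    alpha = params.alpha
    if params.bonferroni:
        alpha = alpha / (len(pairs) * len(KINDS))

    comparisons: list[VarianceComparison] = []
    rows = []
    for a, b in pairs:
        for kind in KINDS:
            d_c = match_points(
                pts_c[a][kind], pts_c[b][kind], kind=kind,
                max_lag=params.max_lag, pair_id=(a, b), condition="control",
            )
            d_t = match_points(
                pts_t[a][kind], pts_t[b][kind], kind=kind,
                max_lag=params.max_lag, pair_id=(a, b), condition="treatment",
            )
            row = {
                "pair": f"{a}-{b}",
                "kind": kind,
                "n_control": d_c.n,
                "n_treatment": d_t.n,
            }
            try:
                comp = f_test(d_c, d_t, alpha=alpha)
            except (InsufficientDataError, DegenerateInputError):
                row.update(
                    mean_control=np.nan, mean_treatment=np.nan,
                    sd_control=np.nan, sd_treatment=np.nan,
                    f_statistic=np.nan, p_value=np.nan,
                    direction="none", significant=False,
                )
                rows.append(row)
                continue
            mean_c, sd_c = delay_stats(d_c)
            mean_t, sd_t = delay_stats(d_t)
            comparisons.append(comp)
            row.update(
                mean_control=mean_c * scale,
                mean_treatment=mean_t * scale,
                sd_control=sd_c * scale,
                sd_treatment=sd_t * scale,
                f_statistic=comp.f_statistic,
                p_value=comp.p_value,
                direction=comp.direction,
                significant=comp.significant,
            )
            rows.append(row)
    grid = pd.DataFrame(rows)
    counts = count_significant(comparisons, alpha=alpha)
    return SyncResult(
        grid=grid, comparisons=tuple(comparisons), counts=counts, alpha=alpha
    )
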