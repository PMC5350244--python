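"""Detection of salient activity-pattern points from local slope series.

Four kinds of salient point are extracted per burst cycle:

* ``max_slope`` -- the time ``t*`` maximising the centred slope; proxy for the
  midpoint of the ramp-up phase (burst onset timing).
* ``min_slope`` -- the time ``t**`` minimising the centred slope; proxy for the
  midpoint of the ramp-down phase (burst offset timing).
* ``plateau_begin`` / ``plateau_end`` -- the first time after ``t*`` whose
  *forward* slope is inside the near-zero band, and the last time before
  ``t**`` whose *backward* slope is inside that band.

Slope extrema whose slope value falls outside an analyst-set acceptability
band are *spurious* (they arise from silent stretches or from spikes) and are
flagged invalid rather than dropped.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidInputError
from .slope_estimation import SlopeSeries, SmoothingSpec, Trace, slope_series, smooth_trace

__all__ = [
    "KINDS",
    "AcceptanceBands",
    "SalientPoint",
    "ActivityCycle",
    "DetectionParams",
    "TraceFeatures",
    "max_slope_point",
    "min_slope_point",
    "default_bands",
    "detect_cycles",
    "classify_points",
    "plateau_bounds",
    "analyse_trace",
    "features_frame",
]

#: Salient-point kinds, in within-cycle temporal order.
KINDS = ("max_slope", "plateau_begin", "plateau_end", "min_slope")


@dataclass(frozen=True)
class AcceptanceBands:
    """Acceptability bands separating valid from spurious slope extrema.

    ``max_slope_band`` / ``min_slope_band`` are closed intervals (``inf``
    endpoints allowed) of admissible maximum/minimum slope values; the max
    band must be entirely positive and the min band entirely negative.
    ``zero_range`` is the symmetric near-zero band ``[-z*, z*]`` used for
    plateau begin/end detection, conventionally ``z* = epsilon * m_max`` with
    ``m_max`` the largest absolute slope among the accepted extrema and
    ``epsilon`` small (default 0.1).
    """

    max_slope_band: tuple[float, float]
    min_slope_band: tuple[float, float]
    zero_range: tuple[float, float]
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.max_slope_band
        if not (0 < lo <= hi):
            raise InvalidInputError("max_slope_band must be entirely positive")
        lo, hi = self.min_slope_band
        if not (lo <= hi < 0):
            raise InvalidInputError("min_slope_band must be entirely negative")
        zlo, zhi = self.zero_range
        if not (zhi >= 0 and np.isclose(zlo, -zhi)):
            raise InvalidInputError("zero_range must be symmetric about 0")
        if not (self.epsilon > 0):
            raise InvalidInputError("epsilon must be positive")

    def band_for(self, kind: str) -> tuple[float, float]:
        if kind == "max_slope":
            return self.max_slope_band
        if kind == "min_slope":
            return self.min_slope_band
        if kind in ("plateau_begin", "plateau_end"):
            return self.zero_range
        raise InvalidInputError(f"unknown salient-point kind {kind!r}")


@dataclass(frozen=True)
class SalientPoint:
    """A detected feature point: its kind, sample index, slope value and
    validity (``None`` until classified against acceptance bands)."""

    kind: str
    t: int
    slope_value: float
    valid: bool | None = None


@dataclass(frozen=True)
class ActivityCycle:
    """One burst cycle: max/min slope points plus optional plateau bounds.

    When all four points are present they satisfy
    ``t* < t_begin <= t_end < t**``.  ``plateau_undetermined`` marks cycles
    where no forward/backward slope entered the zero band on the required
    side; such cycles still contribute their slope extrema downstream.
    """

    max_slope_point: SalientPoint
    min_slope_point: SalientPoint
    plateau_begin: SalientPoint | None = None
    plateau_end: SalientPoint | None = None
    plateau_undetermined: bool = False

    def points(self) -> list[SalientPoint]:
        pts = [self.max_slope_point]
        if self.plateau_begin is not None:
            pts.append(self.plateau_begin)
        if self.plateau_end is not None:
            pts.append(self.plateau_end)
        pts.append(self.min_slope_point)
        return pts


def _require_centered(slopes: SlopeSeries) -> np.ndarray:
    if slopes.centered is None:
        raise InvalidInputError("SlopeSeries has no centered component")
    return slopes.centered


def _extremum_point(
    slopes: SlopeSeries, T1: int, T2: int, kind: str
) -> SalientPoint:
    values = _require_centered(slopes)
    lo, hi = slopes.centered_valid
    if not (lo <= T1 < T2 <= hi):
        raise InvalidInputError(
            f"[{T1}, {T2}] is not a valid interval inside the slope valid range [{lo}, {hi}]"
        )
    window = values[T1 : T2 + 1]
    # argmax/argmin return the earliest index on ties
    offset = int(np.argmax(window) if kind == "max_slope" else np.argmin(window))
    t = T1 + offset
    return SalientPoint(kind=kind, t=t, slope_value=float(values[t]))


def max_slope_point(slopes: SlopeSeries, T1: int, T2: int) -> SalientPoint:
    """The time ``t*`` attaining the maximum centred slope on ``[T1, T2]``.

    Ties are broken by the earliest index; the validity flag is left unset
    (use :func:`classify_points`).
    """
    return _extremum_point(slopes, T1, T2, "max_slope")


def min_slope_point(slopes: SlopeSeries, T1: int, T2: int) -> SalientPoint:
    """The time ``t**`` attaining the minimum centred slope on ``[T1, T2]``."""
    return _extremum_point(slopes, T1, T2, "min_slope")


def default_bands(
    slopes: SlopeSeries, epsilon: float = 0.1, fraction: float = 0.5
) -> AcceptanceBands:
    """Derive acceptance bands from the observed slope distribution.

    Suitable for the plateau-dominant regime (ramp slopes dominate the slope
    distribution): the max band keeps slopes above ``fraction`` of the global
    maximum, the min band mirrors it, and the zero band is
    ``[-epsilon * m_max, epsilon * m_max]`` with ``m_max`` the largest
    absolute slope among band-passing extrema.  In the spike-dominant regime
    bands must be supplied by the analyst instead.
    """
    if not (0 < fraction < 1):
        raise InvalidInputError("fraction must be in (0, 1)")
    if not (epsilon > 0):
        raise InvalidInputError("epsilon must be positive")
    values = _require_centered(slopes)
    finite = values[np.isfinite(values)]
    if finite.size == 0 or np.all(finite == 0):
        raise DegenerateInputError("all slope values are zero or missing")
    smax = float(np.max(finite))
    smin = float(np.min(finite))
    if smax <= 0 or smin >= 0:
        raise DegenerateInputError(
            "slope series lacks both positive and negative excursions"
        )
    max_band = (fraction * smax, np.inf)
    min_band = (-np.inf, fraction * smin)
    # The global extrema always pass their own band (fraction < 1), so the
    # largest absolute slope over band-passing extrema is max(|smax|, |smin|).
    m_max = max(abs(smax), abs(smin))
    return AcceptanceBands(
        max_slope_band=max_band,
        min_slope_band=min_band,
        zero_range=(-epsilon * m_max, epsilon * m_max),
        epsilon=epsilon,
    )


def _run_candidates(
    values: np.ndarray, band: tuple[float, float], kind: str
) -> list[SalientPoint]:
    """Extremum of each maximal contiguous run of in-band slope values."""
    lo, hi = band
    mask = np.isfinite(values) & (values >= lo) & (values <= hi)
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    out = []
    for start, stop in zip(starts, stops):
        seg = values[start:stop]
        off = int(np.argmax(seg) if kind == "max_slope" else np.argmin(seg))
        t = start + off
        out.append(SalientPoint(kind=kind, t=int(t), slope_value=float(values[t]), valid=True))
    return out


def detect_cycles(slopes: SlopeSeries, bands: AcceptanceBands) -> list[ActivityCycle]:
    """Detect burst cycles over a whole recording.

    Finds maximal contiguous runs where the centred slope lies inside the
    max- (resp. min-) slope band, takes the within-run extremum as a
    candidate point, then pairs alternating max -> min candidates into
    cycles.  Unpaired leading/trailing candidates are discarded; when several
    same-kind candidates occur in a row (a threshold run split by noise), the
    one with the most extreme slope value is kept.  Deterministic; returns an
    empty list when no candidate runs exist.
    """
    values = _require_centered(slopes)
    maxima = _run_candidates(values, bands.max_slope_band, "max_slope")
    minima = _run_candidates(values, bands.min_slope_band, "min_slope")
    events = sorted(maxima + minima, key=lambda p: p.t)

    # Collapse consecutive same-kind candidates (threshold runs split by
    # noise) to the steepest one, earliest on ties, then pair max -> min.
    collapsed: list[SalientPoint] = []
    for pt in events:
        if collapsed and collapsed[-1].kind == pt.kind:
            prev = collapsed[-1]
            better = (
                pt.slope_value > prev.slope_value
                if pt.kind == "max_slope"
                else pt.slope_value < prev.slope_value
            )
            if better:
                collapsed[-1] = pt
        else:
            collapsed.append(pt)

    cycles: list[ActivityCycle] = []
    pending: SalientPoint | None = None
    for pt in collapsed:
        if pt.kind == "max_slope":
            pending = pt
        elif pending is not None:
            cycles.append(ActivityCycle(max_slope_point=pending, min_slope_point=pt))
            pending = None
        # leading min candidates and the trailing unpaired max are discarded
    return cycles


def classify_points(
    points: Sequence[SalientPoint], bands: AcceptanceBands
) -> list[SalientPoint]:
    """Set each point's validity flag by membership of its kind's band."""
    out = []
    for pt in points:
        lo, hi = bands.band_for(pt.kind)
        out.append(dataclasses.replace(pt, valid=bool(lo <= pt.slope_value <= hi)))
    return out


def plateau_bounds(
    forward: SlopeSeries,
    backward: SlopeSeries,
    cycle: ActivityCycle,
    bands: AcceptanceBands,
) -> ActivityCycle:
    """Estimate plateau begin/end for one cycle from forward/backward slopes.

    The begin point is the first time after ``t*`` whose forward slope lies in
    the zero band; the end point is the last time before ``t**`` whose
    backward slope does.  The search is restricted to the open interval
    ``(t*, t**)``; if either side yields nothing, or the bounds cross, the
    cycle is returned flagged ``plateau_undetermined``.
    """
    t_star = cycle.max_slope_point.t
    t_dstar = cycle.min_slope_point.t
    if t_star >= t_dstar:
        raise InvalidInputError("max slope point must precede min slope point")
    if forward.forward is None or backward.backward is None:
        raise InvalidInputError("forward/backward slope components required")
    zlo, zhi = bands.zero_range

    fwd = forward.forward
    inner = np.arange(t_star + 1, t_dstar)
    f_ok = inner[
        np.isfinite(fwd[inner]) & (fwd[inner] >= zlo) & (fwd[inner] <= zhi)
    ]
    bwd = backward.backward
    b_ok = inner[
        np.isfinite(bwd[inner]) & (bwd[inner] >= zlo) & (bwd[inner] <= zhi)
    ]
    if f_ok.size == 0 or b_ok.size == 0 or f_ok[0] > b_ok[-1]:
        return dataclasses.replace(cycle, plateau_undetermined=True)
    t_b = int(f_ok[0])
    t_e = int(b_ok[-1])
    begin = SalientPoint("plateau_begin", t_b, float(fwd[t_b]), valid=True)
    end = SalientPoint("plateau_end", t_e, float(bwd[t_e]), valid=True)
    return dataclasses.replace(
        cycle, plateau_begin=begin, plateau_end=end, plateau_undetermined=False
    )


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the smoothing -> slope -> detection pipeline.

    ``tau`` should be about half the ramp duration (in samples) or slightly
    less.  ``bands`` overrides the automatic :func:`default_bands` (mandatory
    in the spike-dominant regime).
    """

    tau: int
    smoothing: SmoothingSpec = field(default_factory=SmoothingSpec)
    fraction: float = 0.5
    epsilon: float = 0.1
    bands: AcceptanceBands | None = None


@dataclass(frozen=True)
class TraceFeatures:
    """Detection output for one trace: cycles, the bands used, and slopes."""

    neuron_id: str
    cycles: tuple[ActivityCycle, ...]
    bands: AcceptanceBands
    slopes: SlopeSeries
    sampling_interval: float

    def points_by_kind(self, valid_only: bool = True) -> dict[str, list[SalientPoint]]:
        out: dict[str, list[SalientPoint]] = {k: [] for k in KINDS}
        for cycle in self.cycles:
            for pt in cycle.points():
                if valid_only and pt.valid is False:
                    continue
                out[pt.kind].append(pt)
        return out


def analyse_trace(trace: Trace, params: DetectionParams) -> TraceFeatures:
    """Full single-trace pipeline: smooth, slopes, bands, cycles, plateaus.

    The same smoothed trace feeds the centred, forward and backward slope
    series.
    """
    smoothed = smooth_trace(trace, params.smoothing)
    slopes = slope_series(smoothed, params.tau)
    bands = params.bands
    if bands is None:
        bands = default_bands(slopes, epsilon=params.epsilon, fraction=params.fraction)
    cycles = [
        plateau_bounds(slopes, slopes, cycle, bands)
        for cycle in detect_cycles(slopes, bands)
    ]
    return TraceFeatures(
        neuron_id=trace.neuron_id,
        cycles=tuple(cycles),
        bands=bands,
        slopes=slopes,
        sampling_interval=trace.sampling_interval,
    )


def features_frame(features: TraceFeatures | Iterable[TraceFeatures]) -> pd.DataFrame:
    """Tabulate detected salient points (one row per point).

    Columns: neuron_id, cycle_index, kind, t_samples, t_ms, slope_value,
    valid.
    """
    if isinstance(features, TraceFeatures):
        features = [features]
    rows = []
    for feats in features:
        for i, cycle in enumerate(feats.cycles):
            for pt in cycle.points():
                rows.append(
                    {
                        "neuron_id": feats.neuron_id,
                        "cycle_index": i,
                        "kind": pt.kind,
                        "t_samples": pt.t,
                        "t_ms": pt.t * feats.sampling_interval,
                        "slope_value": pt.slope_value,
                        "valid": True if pt.valid is None else pt.valid,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "neuron_id",
            "cycle_index",
            "kind",
            "t_samples",
            "t_ms",
            "slope_value",
            "valid",
        ],
    )
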