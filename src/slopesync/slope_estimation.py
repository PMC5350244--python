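"""Local least-squares slope estimation for uniformly sampled activity traces.

The central quantity is the *local slope*: for each time step ``t`` the slope
of the best least-squares line through the ``2*tau + 1`` samples centred on
``t``.  Because the window is symmetric the estimator has the closed form

    m_t = 3 / (tau*(tau+1)*(2*tau+1)) * sum_{u=t-tau}^{t+tau} (u - t) * x_u

which is what this module implements (a Savitzky-Golay-style first-derivative
filter of polynomial order 1).  *Forward* and *backward* slopes are the
least-squares slopes over the windows ``t .. t+2*tau`` and ``t-2*tau .. t``
respectively; only the slope (never the intercept) is used downstream, and for
a symmetric-weight estimator these are exactly the centred slope evaluated at
``t + tau`` and ``t - tau``.

Slope values outside the window's valid index range are *missing* (NaN), never
zero-filled: padding would fabricate spurious slope extrema at the trace edges.
All time quantities are 0-based sample indices; conversion to milliseconds
happens only at reporting time via ``sampling_interval``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "Trace",
    "SmoothingSpec",
    "SlopeSeries",
    "smooth_trace",
    "centered_slope",
    "forward_slope",
    "backward_slope",
    "slope_series",
]

#: Default acquisition interval in milliseconds (666 frames per second).
DEFAULT_SAMPLING_INTERVAL_MS = 1.5


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled activity time series for one neuron.

    Parameters
    ----------
    values
        Measured (or smoothed) activity samples in arbitrary fluorescence /
        voltage units.
    neuron_id
        Text label of the neuron.
    sampling_interval
        Duration of one sample step in milliseconds (> 0).
    t0
        0-based index of the first sample, for traces cut out of a longer
        recording.
    """

    values: np.ndarray
    neuron_id: str = ""
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL_MS
    t0: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise InvalidInputError("trace values must be one-dimensional")
        if values.size < 1:
            raise InvalidInputError("trace must contain at least one sample")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("trace values must be finite")
        if not (self.sampling_interval > 0):
            raise InvalidInputError("sampling_interval must be positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "t0", int(self.t0))

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in milliseconds (``(t0 + i) * sampling_interval``)."""
        return (self.t0 + np.arange(self.n)) * self.sampling_interval


@dataclass(frozen=True)
class SmoothingSpec:
    """Sliding-window mean smoother specification.

    ``window`` is the number of samples averaged (default 10); ``alignment``
    is ``"centered"`` (window centred on the output sample; for even windows
    the extra sample lies to the right) or ``"trailing"`` (window ends at the
    output sample).  Centered alignment is the default because a trailing
    window delays every feature time by about half the window.
    """

    window: int = 10
    alignment: str = "centered"

    def __post_init__(self) -> None:
        if int(self.window) != self.window or self.window < 1:
            raise InvalidInputError("smoothing window must be a positive integer")
        object.__setattr__(self, "window", int(self.window))
        if self.alignment not in ("centered", "trailing"):
            raise InvalidInputError(
                f"alignment must be 'centered' or 'trailing', got {self.alignment!r}"
            )


@dataclass(frozen=True)
class SlopeSeries:
    """Centered / forward / backward local slope values for one trace.

    Each component is a full-length array aligned with the source trace;
    positions where the window does not fit are NaN.  ``tau`` is the
    half-window: the centred fit uses ``2*tau + 1`` samples.
    Units are activity units per sample.
    """

    tau: int
    n: int
    centered: np.ndarray | None = None
    forward: np.ndarray | None = None
    backward: np.ndarray | None = None
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL_MS

    @property
    def centered_valid(self) -> tuple[int, int]:
        """Inclusive index range on which the centred slope is defined."""
        return (self.tau, self.n - 1 - self.tau)

    @property
    def forward_valid(self) -> tuple[int, int]:
        return (0, self.n - 1 - 2 * self.tau)

    @property
    def backward_valid(self) -> tuple[int, int]:
        return (2 * self.tau, self.n - 1)


def smooth_trace(trace: Trace, spec: SmoothingSpec = SmoothingSpec()) -> Trace:
    """Smooth a trace by a sliding-window arithmetic mean.

    Edge windows are truncated to the available samples, so the output has the
    same length as the input.  Raises :class:`InvalidInputError` if the trace
    is shorter than the window.
    """
    if trace.n < spec.window:
        raise InvalidInputError(
            f"trace of length {trace.n} is shorter than smoothing window {spec.window}"
        )
    idx = np.arange(trace.n)
    w = spec.window
    if spec.alignment == "centered":
        lo = np.maximum(0, idx - (w - 1) // 2)
        hi = np.minimum(trace.n, idx + w // 2 + 1)
    else:  # trailing
        lo = np.maximum(0, idx - w + 1)
        hi = idx + 1
    csum = np.concatenate(([0.0], np.cumsum(trace.values)))
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return dataclasses.replace(trace, values=smoothed)


def _check_slope_args(trace: Trace, tau: int) -> int:
    if int(tau) != tau or tau < 1:
        raise InvalidInputError("tau must be a positive integer")
    tau = int(tau)
    if trace.n < 2 * tau + 1:
        raise InvalidInputError(
            f"trace of length {trace.n} too short for tau={tau} (needs >= {2 * tau + 1})"
        )
    return tau


def _centered_slope_values(values: np.ndarray, tau: int) -> np.ndarray:
    """Closed-form centred least-squares slope; NaN where the window overruns."""
    denom = tau * (tau + 1) * (2 * tau + 1)
    weights = 3.0 * np.arange(-tau, tau + 1) / denom
    # correlation: m_t = sum_k weights[k+tau] * x[t+k]
    core = np.convolve(values, weights[::-1], mode="valid")
    out = np.full(values.size, np.nan)
    out[tau : values.size - tau] = core
    return out


def centered_slope(trace: Trace, tau: int) -> SlopeSeries:
    """Centred local slope ``m_t`` over windows ``t-tau .. t+tau``."""
    tau = _check_slope_args(trace, tau)
    return SlopeSeries(
        tau=tau,
        n=trace.n,
        centered=_centered_slope_values(trace.values, tau),
        sampling_interval=trace.sampling_interval,
    )


def forward_slope(trace: Trace, tau: int) -> SlopeSeries:
    """Forward local slope ``m_t^f``: least-squares slope over ``t .. t+2*tau``.

    Valid for ``t <= n - 1 - 2*tau``; NaN at the trailing edge.
    """
    tau = _check_slope_args(trace, tau)
    centered = _centered_slope_values(trace.values, tau)
    out = np.full(trace.n, np.nan)
    out[: trace.n - 2 * tau] = centered[tau : trace.n - tau]
    return SlopeSeries(
        tau=tau, n=trace.n, forward=out, sampling_interval=trace.sampling_interval
    )


def backward_slope(trace: Trace, tau: int) -> SlopeSeries:
    """Backward local slope ``m_t^b``: least-squares slope over ``t-2*tau .. t``.

    Valid for ``t >= 2*tau``; NaN at the leading edge.
    """
    tau = _check_slope_args(trace, tau)
    centered = _centered_slope_values(trace.values, tau)
    out = np.full(trace.n, np.nan)
    out[2 * tau :] = centered[tau : trace.n - tau]
    return SlopeSeries(
        tau=tau, n=trace.n, backward=out, sampling_interval=trace.sampling_interval
    )


def slope_series(trace: Trace, tau: int) -> SlopeSeries:
    """All three slope components (centred, forward, backward) in one pass."""
    tau = _check_slope_args(trace, tau)
    centered = _centered_slope_values(trace.values, tau)
    forward = np.full(trace.n, np.nan)
    forward[: trace.n - 2 * tau] = centered[tau : trace.n - tau]
    backward = np.full(trace.n, np.nan)
    backward[2 * tau :] = centered[tau : trace.n - tau]
    return SlopeSeries(
        tau=tau,
        n=trace.n,
        centered=centered,
        forward=forward,
        backward=backward,
        sampling_interval=trace.sampling_interval,
    )
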