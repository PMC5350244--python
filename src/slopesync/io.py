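"""Delimited-text I/O for traces, triggers, feature tables and configs.

Trace files are comma- or tab-separated with a header row: the first column is
time (sample index or milliseconds, uniformly spaced), each further column is
one neuron.  A two-column file is the single-neuron dialect.  Missing values
are not permitted; parse errors name the offending line.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, TraceParseError
from .slope_estimation import DEFAULT_SAMPLING_INTERVAL_MS, Trace
from .sync_analysis import TriggerEvents

__all__ = [
    "read_traces",
    "write_traces",
    "read_triggers",
    "load_config",
    "KNOWN_CONFIG_KEYS",
]

#: Config keys accepted by :func:`load_config`; anything else fails loudly.
KNOWN_CONFIG_KEYS = frozenset(
    {
        "smoothing.window",
        "smoothing.alignment",
        "slope.tau",
        "detect.fraction",
        "detect.epsilon",
        "detect.max_band",
        "detect.min_band",
        "detect.zero_range",
        "matching.max_lag",
        "alpha",
        "units",
        "sampling_interval",
        "seed",
    }
)


def _detect_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def read_traces(
    path: str | Path, sampling_interval: float | None = None
) -> list[Trace]:
    """Read one or more traces from a delimited text file.

    The time column must be strictly increasing and uniformly spaced.  If its
    spacing is 1 it is treated as a sample index and ``sampling_interval``
    (default 1.5 ms) supplies the time base; otherwise the spacing itself is
    taken as the sampling interval in milliseconds.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        first = fh.readline()
        if not first:
            raise TraceParseError(f"{path}: empty file")
        delim = _detect_delimiter(first)
        header = next(csv.reader([first], delimiter=delim))
        ncols = len(header)
        if ncols < 2:
            raise TraceParseError(f"{path}, line 1: need a time column plus >= 1 neuron column")
        rows = []
        for lineno, row in enumerate(csv.reader(fh, delimiter=delim), start=2):
            if not row:
                continue
            if len(row) != ncols:
                raise TraceParseError(
                    f"{path}, line {lineno}: expected {ncols} columns, got {len(row)}"
                )
            try:
                values = [float(cell) for cell in row]
            except ValueError:
                raise TraceParseError(f"{path}, line {lineno}: non-numeric cell") from None
            if not all(np.isfinite(values)):
                raise TraceParseError(f"{path}, line {lineno}: missing/non-finite value")
            rows.append(values)
    if len(rows) < 2:
        raise TraceParseError(f"{path}: need at least 2 data rows")
    data = np.asarray(rows)
    time = data[:, 0]
    steps = np.diff(time)
    if np.any(steps <= 0):
        bad = int(np.argmax(steps <= 0)) + 3  # header + 1-based + offset
        raise TraceParseError(f"{path}, line {bad}: time column not strictly increasing")
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise TraceParseError(f"{path}: time column is not uniformly spaced")
    step = float(steps[0])
    if sampling_interval is not None:
        si = sampling_interval
    elif np.isclose(step, 1.0):
        si = DEFAULT_SAMPLING_INTERVAL_MS  # sample-index time base
    else:
        si = step  # time given in ms
    return [
        Trace(values=data[:, j], neuron_id=header[j], sampling_interval=si)
        for j in range(1, ncols)
    ]


def write_traces(path: str | Path, traces: Sequence[Trace] | Mapping[str, Trace]) -> None:
    """Write traces as a comma-delimited file with a sample-index time column."""
    if isinstance(traces, Mapping):
        traces = list(traces.values())
    if not traces:
        raise TraceParseError("no traces to write")
    n = traces[0].n
    if any(t.n != n for t in traces):
        raise TraceParseError("all traces must share a time base")
    frame = pd.DataFrame({"t": np.arange(n)})
    for trace in traces:
        frame[trace.neuron_id or f"neuron{len(frame.columns)}"] = trace.values
    frame.to_csv(path, index=False)


def read_triggers(path: str | Path) -> TriggerEvents:
    """Read trigger sample indices, one integer per line (header optional)."""
    path = Path(path)
    times = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().split(",")[0]
            if not token:
                continue
            try:
                times.append(int(float(token)))
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise TraceParseError(f"{path}, line {lineno}: non-numeric trigger") from None
    if not times:
        raise TraceParseError(f"{path}: no trigger times found")
    return TriggerEvents(times=np.asarray(times))


def _flatten(prefix: str, node, out: dict) -> None:
    if isinstance(node, dict):
        for key, val in node.items():
            _flatten(f"{prefix}.{key}" if prefix else str(key), val, out)
    else:
        out[prefix] = node


def load_config(path: str | Path) -> dict:
    """Load a YAML config into a flat dotted-key dict, rejecting unknown keys.

    Malformed or unrecognised keys raise :class:`ConfigError` rather than
    being silently replaced by defaults.
    """
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    flat: dict = {}
    _flatten("", raw, flat)
    unknown = set(flat) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    return flat
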