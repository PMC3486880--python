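"""Core time-series containers and plumbing.

Everything downstream operates on uniformly sampled traces: a skin-temperature
stimulus ``T(t)`` in °C and a continuous pain rating ``P(t)`` on the 0-100
finger-span scale.  This module owns the containers, delimited-file I/O,
resampling, numerical differentiation and stimulus/rating alignment.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusTrace",
    "RatingTrace",
    "PairedSeries",
    "TraceError",
    "read_trace",
    "write_trace",
    "resample",
    "derivative",
    "align",
]

#: tolerance on grid uniformity (seconds)
_GRID_TOL = 1e-9


class TraceError(ValueError):
    """Malformed trace data or incompatible grids."""


def _validate_grid(t: np.ndarray) -> float:
    if t.ndim != 1 or t.size < 2:
        raise TraceError("trace needs at least 2 samples on a 1-d time grid")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise TraceError("time grid must be strictly increasing")
    if np.max(dt) - np.min(dt) > _GRID_TOL:
        raise TraceError("time grid must be uniform (to within 1e-9 s)")
    return float(np.mean(dt))


@dataclass(frozen=True)
class StimulusTrace:
    """Uniformly sampled skin-temperature time series.

    Parameters
    ----------
    t : array of float
        Time grid in seconds, uniform spacing.
    T : array of float
        Temperature in °C, same length as ``t``.
    """

    t: np.ndarray
    T: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "T", np.asarray(self.T, dtype=float))
        _validate_grid(self.t)
        if self.T.shape != self.t.shape:
            raise TraceError("t and T must have the same length")
        if not np.all(np.isfinite(self.T)):
            raise TraceError("temperature values must be finite")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def values(self) -> np.ndarray:
        return self.T

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class RatingTrace:
    """Uniformly sampled pain-rating time series on the 0-100 scale.

    Measured or synthesized ratings live in [0, 100]; model output is only
    required to be non-negative (the models place no ceiling on perceived
    magnitude).
    """

    t: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "P", np.asarray(self.P, dtype=float))
        _validate_grid(self.t)
        if self.P.shape != self.t.shape:
            raise TraceError("t and P must have the same length")
        if not np.all(np.isfinite(self.P)):
            raise TraceError("rating values must be finite")
        if np.any(self.P < -1e-9):
            raise TraceError("ratings must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def values(self) -> np.ndarray:
        return self.P

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class PairedSeries:
    """A (stimulus, rating) pair on one common uniform grid.

    Produced by :func:`align`; this is the object every model fit consumes.
    """

    t: np.ndarray
    T: np.ndarray
    P: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "T", np.asarray(self.T, dtype=float))
        object.__setattr__(self, "P", np.asarray(self.P, dtype=float))
        _validate_grid(self.t)
        if self.T.shape != self.t.shape or self.P.shape != self.t.shape:
            raise TraceError("T and P must be defined on the identical grid")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def stimulus(self) -> StimulusTrace:
        return StimulusTrace(self.t, self.T)

    @property
    def rating(self) -> RatingTrace:
        return RatingTrace(self.t, self.P)

    def __len__(self) -> int:
        return self.t.size


# ---------------------------------------------------------------------------
# file I/O: 2-column delimited (time, value); '#' comments; header optional
# ---------------------------------------------------------------------------

def _parse_rows(text: str):
    rows = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "," in line:
            parts = [p.strip() for p in line.split(",")]
        else:
            parts = line.split()
        if len(parts) < 2:
            raise TraceError(f"line {lineno}: expected 2 columns, got {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError:
            if rows:
                raise TraceError(f"line {lineno}: non-numeric data") from None
            # tolerate a single header line before any data
            continue
    return rows


def read_trace(path, kind: str):
    """Read a 2-column delimited (time, value) file.

    Parameters
    ----------
    path : str or path-like or file object
        Comma-, tab- or whitespace-delimited text; ``#`` starts a comment
        line; one optional header line is tolerated.
    kind : {"stimulus", "rating"}
        Interpret the value column as °C or as a 0-100 rating.

    Returns
    -------
    StimulusTrace or RatingTrace
        The raw grid is preserved; no resampling is applied.
    """
    if kind not in ("stimulus", "rating"):
        raise ValueError(f"kind must be 'stimulus' or 'rating', got {kind!r}")
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    rows = _parse_rows(text)
    if len(rows) < 2:
        raise TraceError("malformed input: need at least 2 data rows")
    t = np.array([r[0] for r in rows])
    v = np.array([r[1] for r in rows])
    if np.any(np.diff(t) <= 0):
        raise TraceError("time column must be strictly increasing")
    if kind == "stimulus":
        return StimulusTrace(t, v)
    return RatingTrace(t, v)


def write_trace(trace, path, delimiter: str = ",") -> None:
    """Write a trace as 2-column delimited text (full float precision)."""
    lines = [f"{ti:.17g}{delimiter}{vi:.17g}" for ti, vi in zip(trace.t, trace.values)]
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# resampling / differentiation / alignment
# ---------------------------------------------------------------------------

def resample(trace, dt_out: float):
    """Linearly interpolate a trace onto a uniform grid of spacing ``dt_out``.

    The output grid spans ``[t0, t_end]``; both endpoints are preserved
    (the final point is included when ``t_end`` falls on the grid to within
    rounding; otherwise the last grid point is the largest multiple of
    ``dt_out`` inside the span).
    """
    if dt_out <= 0:
        raise ValueError("dt_out must be positive")
    span = trace.t[-1] - trace.t[0]
    if dt_out > span:
        raise TraceError("dt_out exceeds the total time span")
    n = int(np.floor(span / dt_out + 1e-9)) + 1
    t_new = trace.t[0] + dt_out * np.arange(n)
    v_new = np.interp(t_new, trace.t, trace.values)
    if isinstance(trace, StimulusTrace):
        return StimulusTrace(t_new, v_new)
    return RatingTrace(t_new, v_new)


def derivative(trace) -> np.ndarray:
    """Time derivative of a trace on its own grid (units value/s).

    Central differences at interior points, first-order one-sided at the
    endpoints — exact for affine inputs and second-order accurate in the
    interior for smooth ones.
    """
    if len(trace) < 2:
        raise TraceError("derivative needs at least 2 samples")
    return np.gradient(trace.values, trace.dt, edge_order=1)


def align(stim: StimulusTrace, rating: RatingTrace, dt: float) -> PairedSeries:
    """Resample a stimulus and a rating onto their common overlap at grid dt."""
    t0 = max(stim.t[0], rating.t[0])
    t1 = min(stim.t[-1], rating.t[-1])
    if t1 - t0 < dt:
        raise TraceError("stimulus and rating have disjoint (or too short) overlap")
    n = int(np.floor((t1 - t0) / dt + 1e-9)) + 1
    t_new = t0 + dt * np.arange(n)
    T = np.interp(t_new, stim.t, stim.T)
    P = np.interp(t_new, rating.t, rating.P)
    return PairedSeries(t_new, T, P)
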