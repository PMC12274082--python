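"""Exposure-history functionals: cumulative average and moving average.

The cumulative average at visit j is the interval-weighted mean of the point
exposures at visits 1..j-1,

    s(t_j) = sum_{k<j} (t_{k+1} - t_k) * x(t_k) / (t_j - t_1),

with the first-visit convention s(t_1) = x(t_1) (the formula is 0/0 at j=1).
The calendar-window moving average at visit j averages point exposures over
the half-open window (t_j - window, t_j], weighted by interval length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .panel import ID, SURROGATE, TIME, TRUE, Panel

__all__ = [
    "HistoryFunctionSpec",
    "cumulative_average",
    "cumulative_average_weights",
    "batched_cumavg_weights",
    "cumavg_by_cluster",
    "moving_average",
    "apply_history_function",
]

#: column written by calibration.predict_exposure
CALIBRATED = "c_hat"

_SOURCES = {"true": TRUE, "surrogate": SURROGATE, "calibrated": CALIBRATED}


@dataclass(frozen=True)
class HistoryFunctionSpec:
    """Which summary of the exposure history to use.

    kind:
        ``"cumulative_average"`` or ``"moving_average"``.
    window:
        Window length in the panel's time units (moving average only).
    """

    kind: str = "cumulative_average"
    window: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("cumulative_average", "moving_average"):
            raise ValueError(f"unknown history function kind: {self.kind!r}")
        if self.kind == "moving_average":
            if self.window is None or self.window <= 0:
                raise ValueError("moving_average requires window > 0")


def _check_times(times: np.ndarray) -> None:
    if times.ndim != 1 or len(times) < 1:
        raise ValueError("times must be a nonempty 1-d vector")
    if np.any(np.diff(times) <= 0):
        raise ValueError("visit times must be strictly increasing")


def cumulative_average_weights(times: np.ndarray) -> np.ndarray:
    """Lower-triangular weight matrix w with s = w @ values.

    Row j (0-based) holds the interval weights (t_{k+1}-t_k)/(t_j-t_1) on
    visits k < j; row 0 is the first-visit convention (weight 1 on visit 1).
    """
    times = np.asarray(times, dtype=float)
    _check_times(times)
    m = len(times)
    w = np.zeros((m, m))
    w[0, 0] = 1.0
    gaps = np.diff(times)  # t_{k+1} - t_k, length m-1
    for j in range(1, m):
        w[j, :j] = gaps[:j] / (times[j] - times[0])
    return w


def batched_cumavg_weights(times: np.ndarray) -> np.ndarray:
    """Cumulative-average weight matrices for a stack of clusters.

    ``times`` has shape (ncl, m) with strictly increasing rows; returns
    (ncl, m, m) lower-triangular weights so that s = w @ values row-wise.
    """
    times = np.asarray(times, dtype=float)
    ncl, m = times.shape
    if np.any(np.diff(times, axis=1) <= 0):
        raise ValueError("visit times must be strictly increasing")
    w = np.zeros((ncl, m, m))
    w[:, 0, 0] = 1.0
    gaps = np.diff(times, axis=1)
    for j in range(1, m):
        w[:, j, :j] = gaps[:, :j] / (times[:, j] - times[:, 0])[:, None]
    return w


def cumavg_by_cluster(ids: np.ndarray, times: np.ndarray,
                      values: np.ndarray) -> np.ndarray:
    """Cumulative average applied within clusters, vectorized by size.

    Rows must be ordered by (id, time); clusters of equal size are processed
    together with stacked linear algebra.
    """
    ids = np.asarray(ids)
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    _, start, inv = np.unique(ids, return_index=True, return_inverse=True)
    order = np.argsort(start, kind="mergesort")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    cl = rank[inv]
    sizes = np.bincount(cl)
    row_order = np.argsort(cl, kind="mergesort")
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    out = np.empty_like(values)
    for m in np.unique(sizes):
        which = np.flatnonzero(sizes == m)
        idx = np.stack([row_order[offsets[c]:offsets[c] + m] for c in which])
        w = batched_cumavg_weights(times[idx])
        out[idx.ravel()] = np.einsum("cjk,ck->cj", w, values[idx]).ravel()
    return out


def cumulative_average(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Interval-weighted cumulative average of ``values`` along ``times``."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.shape != times.shape:
        raise ValueError("times and values must have equal length")
    return cumulative_average_weights(times) @ values


def moving_average(times: np.ndarray, values: np.ndarray,
                   window: float) -> np.ndarray:
    """Interval-weighted average over the half-open window (t_j - window, t_j].

    Visit k carries its nominal interval length t_{k+1} - t_k; the current
    (last eligible) visit carries the preceding gap, so for an equally spaced
    series the result is the arithmetic mean of the in-window values.  The
    left-most in-window interval is truncated at the window boundary.  NaN
    values are excluded with their weights; an entry with no non-missing
    in-window value is NaN.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    _check_times(times)
    m = len(times)
    gaps = np.diff(times)
    out = np.full(m, np.nan)
    for j in range(m):
        lo = times[j] - window
        lengths = []
        vals = []
        for k in range(j + 1):
            if not (lo < times[k] <= times[j]):
                continue
            if k < j:
                # interval [t_k, t_{k+1}) truncated at the window boundary
                length = min(gaps[k], times[k + 1] - lo)
            else:
                # current visit: carries the preceding gap (1.0 if singleton)
                length = gaps[j - 1] if j > 0 else 1.0
            if np.isnan(values[k]) or length <= 0:
                continue
            lengths.append(length)
            vals.append(values[k])
        if lengths:
            lengths = np.asarray(lengths)
            out[j] = np.dot(lengths, vals) / lengths.sum()
    return out


def apply_history_function(panel: Panel, spec: HistoryFunctionSpec,
                           source: str = "surrogate",
                           name: str = "h") -> Panel:
    """Append per-individual history columns ``name`` and ``name_x_t``.

    ``source`` selects the point-exposure series: ``"true"`` (c),
    ``"surrogate"`` (C) or ``"calibrated"`` (the ``c_hat`` column written by
    ``calibration.predict_exposure``).
    """
    try:
        col = _SOURCES[source]
    except KeyError:
        raise ValueError(f"unknown source {source!r}") from None
    if col not in panel.data.columns:
        raise KeyError(f"source column {col!r} absent from panel")
    df = panel.data
    if spec.kind == "cumulative_average":
        h = cumavg_by_cluster(df[ID].to_numpy(),
                              df[TIME].to_numpy(dtype=float),
                              df[col].to_numpy(dtype=float))
    else:
        h = np.empty(len(df))
        for _, idx in df.groupby(ID, sort=False).indices.items():
            t = df[TIME].to_numpy(dtype=float)[idx]
            v = df[col].to_numpy(dtype=float)[idx]
            h[idx] = moving_average(t, v, spec.window)
    out = panel.with_column(name, h)
    return out.with_column(f"{name}_x_t", h * df[TIME].to_numpy(dtype=float))
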