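"""Fluorescence trace extraction, modal-baseline dF/F, and activity filtering.

Traces are the weighted mean intensity inside each ROI mask (a seeded
stand-in for factorization-based source extraction, which is out of
scope).  The baseline F0 is the modal fluorescence value in 3-minute
windows, which — unlike a mean or median — is insensitive to sparse
positive calcium transients riding on a slowly varying baseline.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "extract_traces",
    "modal_baseline",
    "histogram_mode",
    "dff",
    "active_cell_filter",
]

_F0_EPS = 1e-6


def extract_traces(movie: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Weighted mean intensity per mask per frame -> (n_cells, T)."""
    movie = np.asarray(movie, dtype=float)
    masks = np.asarray(masks, dtype=float)
    if masks.ndim == 2:
        masks = masks[None]
    if masks.shape[1:] != movie.shape[1:]:
        raise ValueError("mask shape does not match frame shape")
    weights = masks.reshape(masks.shape[0], -1)
    totals = weights.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("empty mask encountered")
    flat = movie.reshape(movie.shape[0], -1)
    return (weights @ flat.T) / totals[:, None]


def histogram_mode(x: np.ndarray) -> float:
    """Mode of a continuous sample.

    The histogram (Freedman-Diaconis bin width, falling back to Sturges
    when the IQR degenerates, as numpy's ``auto`` rule does) locates the
    modal bin — ties break toward the lower bin — and the value returned
    is the median of the samples inside it, which pins the mode exactly
    for traces whose baseline samples repeat a single value.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if np.ptp(x) == 0:
        return float(x[0])
    counts, edges = np.histogram(x, bins="auto")
    k = int(np.argmax(counts))          # argmax takes the first (lower) bin on ties
    lo, hi = edges[k], edges[k + 1]
    inside = x[(x >= lo) & (x <= hi)] if k == len(counts) - 1 else x[(x >= lo) & (x < hi)]
    return float(np.median(inside)) if inside.size else float(0.5 * (lo + hi))


def modal_baseline(
    trace: np.ndarray, frame_rate_hz: float, window_minutes: float = 3.0
) -> np.ndarray:
    """Per-frame baseline F0: windowed histogram mode, interpolated.

    Windows are ``window_minutes`` long with a hop of half a window;
    window-center modes are linearly interpolated to every frame with
    constant extrapolation at the ends.  Traces shorter than one window
    fall back to a single whole-trace mode.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    win = int(round(window_minutes * 60.0 * frame_rate_hz))
    if n < 1:
        raise ValueError("empty trace")
    if n <= win:
        f0 = np.full(n, histogram_mode(trace))
    else:
        hop = max(win // 2, 1)
        starts = list(range(0, n - win + 1, hop))
        if starts[-1] != n - win:
            starts.append(n - win)
        centers = np.array([s + (win - 1) / 2.0 for s in starts])
        modes = np.array([histogram_mode(trace[s : s + win]) for s in starts])
        f0 = np.interp(np.arange(n), centers, modes)
    if np.any(f0 <= 0):
        warnings.warn("non-positive modal baseline floored at epsilon")
        f0 = np.maximum(f0, _F0_EPS)
    return f0


def dff(trace: np.ndarray, f0: np.ndarray) -> np.ndarray:
    """Fractional fluorescence change (F - F0) / F0."""
    trace = np.asarray(trace, dtype=float)
    f0 = np.asarray(f0, dtype=float)
    if trace.shape != f0.shape:
        raise ValueError("trace and F0 length mismatch")
    return (trace - f0) / f0


def compute_dff(
    traces: np.ndarray, frame_rate_hz: float, window_minutes: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Modal-baseline dF/F for a (n_cells, T) trace array; returns (dff, F0)."""
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    f0 = np.stack([modal_baseline(t, frame_rate_hz, window_minutes) for t in traces])
    return (traces - f0) / f0, f0


def active_cell_filter(dff_traces: np.ndarray, threshold: float = 0.03) -> np.ndarray:
    """Indices of cells whose session-mean dF/F strictly exceeds ``threshold``.

    Mirrors the session-wide activity criterion used before decoding;
    silent cells (flat traces, dF/F = 0) are always removed.
    """
    dff_traces = np.atleast_2d(np.asarray(dff_traces, dtype=float))
    if dff_traces.shape[1] == 0:
        raise ValueError("empty traces")
    means = dff_traces.mean(axis=1)
    # strict inequality: a mean exactly at threshold (up to accumulation
    # round-off) is excluded
    return np.where(means - threshold > 1e-12)[0]
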