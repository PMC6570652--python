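"""Repetition of correlation structure via sliding-window overlap statistics.

A 1 s window slid in 200 ms steps yields a time-indexed series of pairwise
correlation matrices C(t); their pairwise overlap
M(t, t') = (1/(N(N-1))) * sum_{i != j} C_ij^t * C_ij^{t'} quantifies how
often a correlation pattern recurs, and the time-summed M_total(t) and its
span sum feed a Monte-Carlo shuffle null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals_io import SessionSet, TraceMatrix
from .synthetic_data import circular_shift_traces, shuffle_traces


@dataclass
class CorrelationWindowSeries:
    matrices: np.ndarray  # (n_windows, N, N)
    midpoints: np.ndarray  # window-midpoint times, seconds
    window_s: float
    step_s: float

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrices.shape[1]


@dataclass
class OverlapResult:
    M: np.ndarray  # (n_windows, n_windows)
    M_total: np.ndarray  # row sums
    repetition_sum: float
    midpoints: np.ndarray
    n_cells: int


@dataclass
class ShuffleNull:
    samples: np.ndarray  # repetition_sum per shuffle
    original: float
    percentile: float  # percentile of the original within the null


def sliding_correlations(
    traces: TraceMatrix,
    frame_rate_hz: float,
    window_s: float = 1.0,
    step_s: float = 0.2,
) -> CorrelationWindowSeries:
    """Pearson correlations per cell pair within each sliding window.

    Zero-variance rows within a window contribute 0 correlations (and a 0
    diagonal entry) by convention so matrix shapes stay stable.
    """
    w = window_s * frame_rate_hz
    st = step_s * frame_rate_hz
    if abs(w - round(w)) > 1e-9 or abs(st - round(st)) > 1e-9:
        raise ValueError("window_s and step_s must be integral in frames")
    w, st = int(round(w)), int(round(st))
    vals = traces.values
    n, T = vals.shape
    if T < w:
        raise ValueError(f"trace too short ({T} frames) for window of {w}")
    starts = np.arange(0, T - w + 1, st)
    # windows: (n_windows, N, w) via stride tricks
    sw = np.lib.stride_tricks.sliding_window_view(vals, w, axis=1)  # (N, T-w+1, w)
    wins = sw[:, starts, :].transpose(1, 0, 2).astype(float)
    centered = wins - wins.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(centered, axis=2)  # (n_windows, N)
    cov = np.einsum("wit,wjt->wij", centered, centered)
    denom = norms[:, :, None] * norms[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    # exact unit diagonal where variance is nonzero
    dg = (norms > 0).astype(float)
    idx = np.arange(n)
    corr[:, idx, idx] = dg
    mid = (starts + (w - 1) / 2.0) / frame_rate_hz
    return CorrelationWindowSeries(corr, mid, window_s, step_s)


def overlap_matrix(
    cw: CorrelationWindowSeries, span_s: float | None = None
) -> OverlapResult:
    """All-pairs overlap M(t, t'), its row sums, and the span-restricted sum.

    ``span_s`` restricts the analysis to window midpoints <= span_s
    (default: whole series).  M_total includes the t' = t term.
    """
    if cw.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if cw.n_windows < 2:
        raise ValueError("need at least 2 windows")
    mats = cw.matrices
    mid = cw.midpoints
    if span_s is not None:
        keep = mid <= span_s
        mats, mid = mats[keep], mid[keep]
        if mats.shape[0] < 2:
            raise ValueError("fewer than 2 windows within the analysis span")
    n = cw.n_cells
    off = ~np.eye(n, dtype=bool)
    V = mats[:, off]  # (n_windows, N(N-1)) off-diagonal entries, both orders
    M = (V @ V.T) / (n * (n - 1))
    M_total = M.sum(axis=1)
    return OverlapResult(M, M_total, float(M_total.sum()), mid, n)


def repetition_sum(
    traces: TraceMatrix,
    frame_rate_hz: float,
    window_s: float = 1.0,
    step_s: float = 0.2,
    span_s: float | None = 60.0,
) -> float:
    cw = sliding_correlations(traces, frame_rate_hz, window_s, step_s)
    return overlap_matrix(cw, span_s).repetition_sum


def overlap_shuffle_null(
    traces: TraceMatrix,
    frame_rate_hz: float,
    n_shuffles: int = 10_000,
    seed: int = 0,
    scope: str = "circular",
    window_s: float = 1.0,
    step_s: float = 0.2,
    span_s: float | None = 60.0,
) -> ShuffleNull:
    """Monte-Carlo null of the repetition sum.

    ``scope`` selects the resampling scheme: ``circular`` (default,
    per-cell independent circular time shifts) or ``permute`` (per-cell
    independent bin permutation).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if scope not in ("circular", "permute"):
        raise ValueError(f"unknown shuffle scope {scope!r}")
    original = repetition_sum(traces, frame_rate_hz, window_s, step_s, span_s)
    rng = np.random.default_rng(seed)
    samples = np.empty(n_shuffles)
    for k in range(n_shuffles):
        if scope == "circular":
            sh = circular_shift_traces(traces, rng)
        else:
            sh = shuffle_traces(traces, "timestamps", rng)
        samples[k] = repetition_sum(sh, frame_rate_hz, window_s, step_s, span_s)
    pct = 100.0 * np.mean(samples < original)
    return ShuffleNull(samples, original, float(pct))


def repetition_report(
    session_set: SessionSet,
    label: str = "A",
    window_s: float = 1.0,
    step_s: float = 0.2,
    span_s: float | None = 60.0,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> dict:
    """Per-group repetition sums for one session, relative to non-engram.

    Returns repetition sums for engram, non-engram, and time-shuffled
    engram traces, the engram/non-engram and shuffled/non-engram ratios,
    and the percentile of the engram value within its shuffle null.
    """
    fr = session_set[label].frame_rate_hz
    sums: dict[str, float] = {}
    for group in ("engram", "non_engram"):
        tm = session_set.group_traces(label, group)
        if tm.n_cells < 2:
            raise ValueError(f"group {group!r} has fewer than 2 cells")
        sums[group] = repetition_sum(tm, fr, window_s, step_s, span_s)
    eng = session_set.group_traces(label, "engram")
    null = overlap_shuffle_null(
        eng, fr, n_shuffles=n_shuffles, seed=seed,
        window_s=window_s, step_s=step_s, span_s=span_s,
    )
    shuffled_mean = float(null.samples.mean())
    return {
        "session": label,
        "repetition_sum": {
            "engram": sums["engram"],
            "non_engram": sums["non_engram"],
            "shuffled_engram_mean": shuffled_mean,
        },
        "ratio_engram_vs_nonengram": sums["engram"] / sums["non_engram"],
        "ratio_shuffled_vs_nonengram": shuffled_mean / sums["non_engram"],
        "engram_null_percentile": null.percentile,
        "n_shuffles": n_shuffles,
        "span_s": span_s,
    }
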