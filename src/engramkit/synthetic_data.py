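"""Seeded synthetic experiments with planted co-active sub-ensembles.

Traces are built as background Poisson events plus synchronous pattern
activations (member amplitudes proportional to participation weights),
convolved with a difference-of-exponentials calcium kernel, with additive
Gaussian noise clipped at zero.  Every engram pattern carries a *fate plan*
— the set of sessions in which it activates — so cross-session analyses
have exact ground truth.  A reporter snapshot with a Gaussian blob per
expressing cell accompanies each experiment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .signals_io import (
    Cell,
    CellRegistry,
    Session,
    SessionSet,
    TraceMatrix,
)

DEFAULT_SESSION_PLAN: list[tuple[str, str, float]] = [
    ("A", "awake", 360.0),
    ("B", "NREM", 60.0),
    ("C", "NREM", 60.0),
    ("D", "REM", 60.0),
    ("E", "awake", 180.0),
    ("F", "awake", 180.0),
]

#: default fate plans keyed by category; presence set over session labels
ALIGNED = frozenset("ABCDE")
ISOLATED = frozenset("A")


@dataclass
class ImageConfig:
    shape: tuple[int, int] = (256, 256)  # (height, width)
    blob_sigma_px: float = 3.0
    blob_peak: float = 2000.0
    background: float = 200.0
    noise_sd: float = 20.0
    bit_depth: int = 16


@dataclass
class SynthConfig:
    n_cells: int = 200
    engram_fraction: float = 0.1
    n_engram_patterns: int = 4
    n_nonengram_patterns: int = 4
    pattern_size: tuple[int, int] = (6, 9)  # inclusive range of cells per pattern
    session_plan: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_SESSION_PLAN)
    )
    frame_rate_hz: float = 20.0
    event_rate_hz: float = 0.05  # per-cell background events
    pattern_activation_rate_hz: float = 0.25
    nonengram_pattern_rate_hz: float | None = None  # defaults to engram rate
    participation_low: float = 0.5  # weights ~ U(low, 1]
    kernel_rise_s: float = 0.05
    kernel_decay_s: float = 0.5
    noise_sd: float = 0.02
    amplitude: float = 1.0
    amplitude_jitter: float = 0.2  # event amplitude ~ U(1-j, 1+j) * amplitude
    fate_plan: list[frozenset] | None = None  # per engram pattern
    f_shared_fraction: float = 0.5  # of aligned patterns also present in F
    nonengram_session_unique: bool = True
    max_pattern_cosine: float = 0.6  # rejection bound between planted patterns
    image: ImageConfig = field(default_factory=ImageConfig)
    seed: int = 0

    @property
    def n_engram(self) -> int:
        return int(round(self.engram_fraction * self.n_cells))

    def validate(self) -> None:
        lo, hi = self.pattern_size
        if not (1 <= lo <= hi):
            raise ValueError("invalid pattern_size range")
        if self.n_engram_patterns > 0 and hi > self.n_engram:
            raise ValueError(
                f"largest engram pattern ({hi}) exceeds engram pool ({self.n_engram})"
            )
        n_non = self.n_cells - self.n_engram
        if self.n_nonengram_patterns > 0 and hi > n_non:
            raise ValueError("largest non-engram pattern exceeds non-engram pool")
        for _, _, dur in self.session_plan:
            if abs(dur * self.frame_rate_hz - round(dur * self.frame_rate_hz)) > 1e-9:
                raise ValueError("session duration x frame rate must be integral")
        for r in (self.event_rate_hz, self.pattern_activation_rate_hz):
            if r < 0:
                raise ValueError("rates must be non-negative")


@dataclass
class GroundTruth:
    """Planted parameters of one synthetic experiment."""

    engram_ids: list[str]
    #: unit-norm cell-length weight vectors, index = pattern id
    engram_pattern_vectors: np.ndarray  # (n_engram_patterns, n_cells)
    nonengram_pattern_vectors: dict  # session label -> (n_pat, n_cells)
    #: session label -> pattern id -> activation frame indices
    activation_times: dict
    #: per engram pattern: presence set over session labels
    fate_plan: list[frozenset]

    def fate_category(self, pattern: int, sleep_labels: Sequence[str] = ("B", "C")) -> str:
        """Triplet over (learning, sleep, retrieval): e.g. '+++' aligned, '+--' isolated."""
        present = self.fate_plan[pattern]
        sleep = "+" if any(s in present for s in sleep_labels) else "-"
        retr = "+" if "E" in present else "-"
        return "+" + sleep + retr

    def session_pattern_sets(
        self, group: str = "engram", cell_indices: np.ndarray | None = None
    ) -> dict:
        """Planted unit pattern vectors per session.

        ``cell_indices`` restricts vectors to a cell subset (e.g. the
        group's own cells, matching per-group factorizations); planted
        vectors are supported only on their group, so restriction to that
        group preserves unit norm.
        """
        out: dict[str, np.ndarray] = {}
        if group == "engram":
            for label in self.activation_times:
                rows = [
                    self.engram_pattern_vectors[p]
                    for p, present in enumerate(self.fate_plan)
                    if label in present
                ]
                out[label] = (
                    np.vstack(rows) if rows else np.empty((0, self.engram_pattern_vectors.shape[1]))
                )
        else:
            out = dict(self.nonengram_pattern_vectors)
        if cell_indices is not None:
            out = {
                lab: v[:, cell_indices] if v.size else v[:, :0]
                for lab, v in out.items()
            }
        return out


def calcium_kernel(rise_s: float, decay_s: float, frame_rate_hz: float) -> np.ndarray:
    """Difference-of-exponentials kernel, amplitude-normalized to peak 1."""
    if decay_s <= rise_s:
        raise ValueError("decay must exceed rise time")
    t = np.arange(0, decay_s * 6, 1.0 / frame_rate_hz)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


def _sample_pattern(
    rng: np.random.Generator,
    pool: np.ndarray,
    size_range: tuple[int, int],
    n_cells: int,
    low: float,
    existing: list[np.ndarray],
    max_cos: float,
    max_tries: int = 200,
) -> np.ndarray:
    """Unit-norm non-negative weight vector over a random subset of ``pool``.

    Rejection-samples so planted patterns stay mutually distinguishable
    (pairwise cosine <= max_cos) when the pool allows it.
    """
    lo, hi = size_range
    best = None
    for _ in range(max_tries):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(pool, size=size, replace=False)
        w = np.zeros(n_cells)
        w[members] = rng.uniform(low, 1.0, size=size)
        w /= np.linalg.norm(w)
        cosmax = max((float(w @ e) for e in existing), default=0.0)
        if best is None or cosmax < best[0]:
            best = (cosmax, w)
        if cosmax <= max_cos:
            return w
    return best[1]


def _poisson_times(rng: np.random.Generator, rate_hz: float, n_frames: int, fr: float) -> np.ndarray:
    n = rng.poisson(rate_hz * n_frames / fr)
    return np.sort(rng.integers(0, n_frames, size=n)) if n else np.empty(0, dtype=int)


def default_fate_plan(n_patterns: int, f_shared_fraction: float) -> list[frozenset]:
    """Half aligned (first ones F-shared), remainder alternating isolated/mixed."""
    plans: list[frozenset] = []
    n_aligned = max(1, n_patterns // 2)
    n_f = int(round(f_shared_fraction * n_aligned))
    for i in range(n_patterns):
        if i < n_aligned:
            plans.append(ALIGNED | {"F"} if i < n_f else ALIGNED)
        elif (i - n_aligned) % 2 == 0:
            plans.append(ISOLATED)
        else:
            plans.append(frozenset("ABCD"))  # replayed but not retrieved: '++-'
    return plans


def generate_experiment(
    cfg: SynthConfig,
) -> tuple[SessionSet, GroundTruth, np.ndarray]:
    """Generate sessions, ground truth, and a reporter snapshot.

    Deterministic given ``cfg.seed``.  The snapshot is a 16-bit image with
    one blob per engram cell.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    n_eng = cfg.n_engram
    fr = cfg.frame_rate_hz

    # registry: centroids on a jittered grid, engram cells a random subset
    h, w = cfg.image.shape
    margin = 4 * cfg.image.blob_sigma_px
    xs = rng.uniform(margin, w - margin, size=n)
    ys = rng.uniform(margin, h - margin, size=n)
    # enforce a minimum separation so snapshot blobs stay resolvable
    min_sep = 4 * cfg.image.blob_sigma_px
    for i in range(1, n):
        for _ in range(100):
            d2 = (xs[:i] - xs[i]) ** 2 + (ys[:i] - ys[i]) ** 2
            if d2.min() >= min_sep**2:
                break
            xs[i] = rng.uniform(margin, w - margin)
            ys[i] = rng.uniform(margin, h - margin)
    engram_idx = np.sort(rng.choice(n, size=n_eng, replace=False))
    engram_set = set(engram_idx.tolist())
    cells = [
        Cell(f"c{i:04d}", float(xs[i]), float(ys[i]), engram=(i in engram_set))
        for i in range(n)
    ]
    registry = CellRegistry(cells)
    engram_ids = [cells[i].id for i in engram_idx]
    nonengram_idx = np.array(sorted(set(range(n)) - engram_set), dtype=int)

    # planted engram patterns + fate plans
    eng_vectors: list[np.ndarray] = []
    for _ in range(cfg.n_engram_patterns):
        eng_vectors.append(
            _sample_pattern(
                rng, engram_idx, cfg.pattern_size, n, cfg.participation_low,
                eng_vectors, cfg.max_pattern_cosine,
            )
        )
    eng_mat = (
        np.vstack(eng_vectors) if eng_vectors else np.empty((0, n))
    )
    fate_plan = (
        list(cfg.fate_plan)
        if cfg.fate_plan is not None
        else default_fate_plan(cfg.n_engram_patterns, cfg.f_shared_fraction)
    )
    if len(fate_plan) != cfg.n_engram_patterns:
        raise ValueError("fate_plan length must equal n_engram_patterns")

    kernel = calcium_kernel(cfg.kernel_rise_s, cfg.kernel_decay_s, fr)
    non_rate = (
        cfg.nonengram_pattern_rate_hz
        if cfg.nonengram_pattern_rate_hz is not None
        else cfg.pattern_activation_rate_hz
    )

    # persistent non-engram patterns when not session-unique
    shared_non: list[np.ndarray] = []
    if not cfg.nonengram_session_unique:
        for _ in range(cfg.n_nonengram_patterns):
            shared_non.append(
                _sample_pattern(
                    rng, nonengram_idx, cfg.pattern_size, n, cfg.participation_low,
                    shared_non, cfg.max_pattern_cosine,
                )
            )

    sessions: list[Session] = []
    activation_times: dict[str, dict[int, np.ndarray]] = {}
    non_vectors: dict[str, np.ndarray] = {}
    jlo, jhi = 1.0 - cfg.amplitude_jitter, 1.0 + cfg.amplitude_jitter
    for label, stage, dur in cfg.session_plan:
        n_frames = int(round(dur * fr))
        impulses = np.zeros((n, n_frames))
        # background events, all cells
        if cfg.event_rate_hz > 0:
            for i in range(n):
                for t in _poisson_times(rng, cfg.event_rate_hz, n_frames, fr):
                    impulses[i, t] += cfg.amplitude * rng.uniform(jlo, jhi)
        # engram pattern activations per fate plan
        acts: dict[int, np.ndarray] = {}
        for p, present in enumerate(fate_plan):
            if label not in present:
                acts[p] = np.empty(0, dtype=int)
                continue
            times = _poisson_times(rng, cfg.pattern_activation_rate_hz, n_frames, fr)
            if times.size == 0:  # presence implies >= 1 activation
                times = rng.integers(0, n_frames, size=1)
            acts[p] = times
            for t in times:
                impulses[:, t] += (
                    eng_mat[p] * cfg.amplitude * rng.uniform(jlo, jhi)
                )
        activation_times[label] = acts
        # non-engram patterns
        if cfg.nonengram_session_unique:
            sess_non: list[np.ndarray] = []
            for _ in range(cfg.n_nonengram_patterns):
                sess_non.append(
                    _sample_pattern(
                        rng, nonengram_idx, cfg.pattern_size, n,
                        cfg.participation_low, sess_non, cfg.max_pattern_cosine,
                    )
                )
        else:
            sess_non = shared_non
        for v in sess_non:
            for t in _poisson_times(rng, non_rate, n_frames, fr):
                impulses[:, t] += v * cfg.amplitude * rng.uniform(jlo, jhi)
        non_vectors[label] = (
            np.vstack(sess_non) if sess_non else np.empty((0, n))
        )

        traces = np.apply_along_axis(
            lambda r: np.convolve(r, kernel)[:n_frames], 1, impulses
        )
        if cfg.noise_sd > 0:
            traces = traces + rng.normal(0, cfg.noise_sd, size=traces.shape)
        traces = np.clip(traces, 0, None)
        sessions.append(
            Session(label, stage, fr, TraceMatrix(traces, normalized=True))
        )

    truth = GroundTruth(
        engram_ids=engram_ids,
        engram_pattern_vectors=eng_mat,
        nonengram_pattern_vectors=non_vectors,
        activation_times=activation_times,
        fate_plan=fate_plan,
    )
    snapshot = generate_snapshot(registry, engram_ids, cfg.image, seed=cfg.seed + 1)
    return SessionSet(sessions, registry), truth, snapshot


def generate_snapshot(
    registry: CellRegistry,
    expressing_ids: Sequence[str],
    image_cfg: ImageConfig | None = None,
    seed: int = 0,
) -> np.ndarray:
    """16-bit grayscale snapshot with a Gaussian blob per expressing cell."""
    cfg = image_cfg or ImageConfig()
    h, w = cfg.shape
    rng = np.random.default_rng(seed)
    unknown = set(expressing_ids) - set(registry.cell_ids)
    if unknown:
        raise ValueError(f"expressing ids not in registry: {sorted(unknown)[:5]}")
    img = np.full((h, w), cfg.background, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    by_id = {c.id: c for c in registry.cells}
    for cid in expressing_ids:
        c = by_id[cid]
        if not (0 <= c.x < w and 0 <= c.y < h):
            raise ValueError(f"centroid of {cid} outside image bounds")
        img += cfg.blob_peak * np.exp(
            -((xx - c.x) ** 2 + (yy - c.y) ** 2) / (2 * cfg.blob_sigma_px**2)
        )
    if cfg.noise_sd > 0:
        img += rng.normal(0, cfg.noise_sd, size=img.shape)
    maxval = 2**cfg.bit_depth - 1
    return np.clip(img, 0, maxval).astype(np.uint16)


def shuffle_traces(
    traces: TraceMatrix,
    mode: str = "both",
    seed: int | np.random.Generator = 0,
) -> TraceMatrix:
    """Shuffle control: permute timestamps per cell, neuron identities, or both.

    ``timestamps`` permutes time bins independently for each cell (per-row
    value multisets preserved); ``neuron_indices`` permutes rows; ``both``
    composes the two.
    """
    if traces.values.size == 0:
        raise ValueError("empty trace matrix")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    vals = traces.values.copy()
    if mode not in ("timestamps", "neuron_indices", "both"):
        raise ValueError(f"unknown shuffle mode {mode!r}")
    if mode in ("timestamps", "both"):
        for i in range(vals.shape[0]):
            vals[i] = vals[i, rng.permutation(vals.shape[1])]
    if mode in ("neuron_indices", "both"):
        vals = vals[rng.permutation(vals.shape[0])]
    return TraceMatrix(vals, traces.normalized)


def circular_shift_traces(
    traces: TraceMatrix, rng: np.random.Generator
) -> TraceMatrix:
    """Per-cell independent circular time shifts (autocorrelation-preserving null)."""
    vals = traces.values
    T = vals.shape[1]
    shifts = rng.integers(0, T, size=vals.shape[0])
    out = np.empty_like(vals)
    for i, s in enumerate(shifts):
        out[i] = np.roll(vals[i], int(s))
    return TraceMatrix(out, traces.normalized)


def generate_planted_patterns(
    n_cells: int,
    n_patterns: int,
    pattern_size: int,
    rng: np.random.Generator,
    participation_low: float = 0.5,
    disjoint: bool = True,
) -> np.ndarray:
    """(n_patterns, n_cells) unit-norm planted pattern vectors.

    ``disjoint`` assigns members from a shuffled partition so supports do
    not overlap (requires n_patterns * pattern_size <= n_cells).
    """
    if disjoint and n_patterns * pattern_size > n_cells:
        raise ValueError("disjoint patterns exceed the cell pool")
    vecs = np.zeros((n_patterns, n_cells))
    perm = rng.permutation(n_cells)
    for k in range(n_patterns):
        if disjoint:
            mem = perm[k * pattern_size : (k + 1) * pattern_size]
        else:
            mem = rng.choice(n_cells, size=pattern_size, replace=False)
        vecs[k, mem] = rng.uniform(participation_low, 1.0, size=pattern_size)
        vecs[k] /= np.linalg.norm(vecs[k])
    return vecs


def generate_rank_selection_session(
    n_patterns: int,
    n_cells: int = 40,
    n_frames: int = 1200,
    seed: int = 0,
    pattern_size: int = 8,
    activation_rate_hz: float = 0.3,
    frame_rate_hz: float = 20.0,
    noise_sd: float = 0.05,
    baseline: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """High-SNR single-session matrix with a known pattern count.

    Plants ``n_patterns`` ensembles — one tonic baseline ensemble (every
    cell weakly active throughout, carrying the session's fluorescence
    floor) plus ``n_patterns - 1`` phasic ensembles with Poisson
    activations.  Dense Gaussian noise rides on the positive floor so the
    matrix stays non-negative without clipping, keeping the residual
    spectrum isotropic; this is the construction used for model-order
    recovery benchmarks.  Returns (D, planted pattern vectors).
    """
    rng = np.random.default_rng(seed)
    kern = calcium_kernel(0.05, 0.5, frame_rate_hz)
    n_phasic = n_patterns - 1
    phasic = generate_planted_patterns(n_cells, n_phasic, pattern_size, rng)
    D = np.zeros((n_cells, n_frames))
    for k in range(n_phasic):
        times = _poisson_times(rng, activation_rate_hz, n_frames, frame_rate_hz)
        for t in times:
            D[:, t] += phasic[k] * rng.uniform(0.9, 1.1)
    D = np.apply_along_axis(lambda r: np.convolve(r, kern)[:n_frames], 1, D)
    tonic = rng.uniform(0.8, 1.2, size=n_cells)
    tonic /= np.linalg.norm(tonic)
    drift = 1.0 + 0.1 * np.sin(np.linspace(0, 20, n_frames))
    D += baseline * math.sqrt(n_cells) * np.outer(tonic, drift)
    D += rng.normal(0, noise_sd, size=D.shape)
    D = np.clip(D, 0.0, None)  # floor >= ~8 sd, so clipping is negligible
    vectors = np.vstack([tonic[None, :], phasic]) if n_phasic else tonic[None, :]
    return D, vectors


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    doc = {
        "engram_ids": truth.engram_ids,
        "engram_pattern_vectors": truth.engram_pattern_vectors.tolist(),
        "fate_plan": [sorted(p) for p in truth.fate_plan],
        "activation_times": {
            lab: {str(p): t.tolist() for p, t in acts.items()}
            for lab, acts in truth.activation_times.items()
        },
        "nonengram_pattern_vectors": {
            lab: v.tolist() for lab, v in truth.nonengram_pattern_vectors.items()
        },
    }
    Path(path).write_text(json.dumps(doc))
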