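"""Cross-session pattern comparison: matching scores, shuffle nulls, fates.

Pattern sets are compared by the cosine of unit-norm non-negative pattern
vectors; the matching score MS(X, Y) is the fraction of X's patterns with
at least one partner in Y whose cosine strictly exceeds the threshold c
(default 0.6).  Session-A patterns are tracked through sleep and retrieval
into aligned / isolated / mixed fate categories, and similar patterns
across sessions form a pattern network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import ensembles
from .synthetic_data import shuffle_traces
from .signals_io import TraceMatrix

DEFAULT_C = 0.6
DEFAULT_D = 0.5  # any d in (0, 1) is equivalent for integer inner sums


@dataclass
class PatternSet:
    session: str
    group: str  # "engram" | "non_engram"
    vectors: np.ndarray  # (n_patterns, n_cells), unit L2 rows

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.vectors.shape[0]:
            norms = np.linalg.norm(self.vectors, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("pattern vectors must be unit L2 norm")

    @property
    def n_patterns(self) -> int:
        return self.vectors.shape[0]


@dataclass
class MatchResult:
    ms: float
    c: float
    d: float
    best_cosine: np.ndarray  # per X-pattern best cosine into Y
    best_partner: np.ndarray  # argmax index into Y (-1 if Y empty)
    shuffled_mean: float | None = None
    shuffled_sd: float | None = None
    normalized_ms: float | None = None


@dataclass
class FateTable:
    categories: list  # per session-A pattern: triplet string like '+++'
    aligned: list  # bool per pattern
    isolated: list
    presence: dict  # pattern index -> {session label -> bool}
    fractions: dict  # category -> fraction of session-A patterns
    sleep_variant: str  # "NREM" or "REM"


def cosine(v: np.ndarray, w: np.ndarray) -> float:
    """Cosine similarity of two non-negative vectors (in [0, 1])."""
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0 or nw == 0:
        raise ValueError("zero vector")
    return float(v @ w / (nv * nw))


def _cosine_matrix(X: PatternSet, Y: PatternSet) -> np.ndarray:
    if X.vectors.shape[1] != Y.vectors.shape[1]:
        raise ValueError("pattern sets must share the cell dimension")
    return X.vectors @ Y.vectors.T


def matching_score(
    X: PatternSet, Y: PatternSet, c: float = DEFAULT_C, d: float = DEFAULT_D
) -> MatchResult:
    """MS(X, Y): fraction of X's patterns with a partner in Y at cosine > c.

    The step function is strict — a cosine exactly equal to c does not
    count.  Asymmetric in (X, Y) by definition.
    """
    if X.n_patterns == 0:
        raise ValueError("empty pattern set X")
    if not (0 < d < 1):
        raise ValueError("d must lie in (0, 1)")
    if Y.n_patterns == 0:
        best = np.zeros(X.n_patterns)
        partner = np.full(X.n_patterns, -1)
        return MatchResult(0.0, c, d, best, partner)
    cm = _cosine_matrix(X, Y)
    inner = (cm > c).sum(axis=1)  # sum_j Theta(v_i . v_j - c)
    matched = inner > d
    best = cm.max(axis=1)
    partner = cm.argmax(axis=1)
    return MatchResult(float(matched.mean()), c, d, best, partner)


def ms_profile(
    patterns_by_session: dict,
    c: float = DEFAULT_C,
    reference: str = "A",
) -> dict:
    """MS(reference, session) for every other session, per group.

    ``patterns_by_session`` maps group -> {session label -> PatternSet}.
    Returns {"engram": {...}, "non_engram": {...}, "difference": {...}}
    with engram - non-engram differences where both groups have a value.
    """
    out: dict[str, dict[str, float]] = {}
    for group, by_sess in patterns_by_session.items():
        if reference not in by_sess:
            raise ValueError(f"missing reference session {reference!r} for {group}")
        ref = by_sess[reference]
        out[group] = {
            lab: matching_score(ref, ps, c=c).ms
            for lab, ps in by_sess.items()
            if lab != reference
        }
    if "engram" in out and "non_engram" in out:
        out["difference"] = {
            lab: out["engram"][lab] - out["non_engram"][lab]
            for lab in out["engram"]
            if lab in out["non_engram"]
        }
    return out


def ms_shuffle_null(
    D_X: np.ndarray,
    D_Y: np.ndarray,
    k_range,
    n_shuffles: int = 40,
    seed: int = 0,
    restarts: int = 50,
    c: float = DEFAULT_C,
    d: float = DEFAULT_D,
    freeze_k: tuple | None = None,
    refine_top: int = 3,
) -> MatchResult:
    """Matching score with a shuffled-data null and normalized MS.

    Both raw matrices are shuffled (timestamps and neuron indices), then
    refactorized with the same AICc K-selection procedure (or with K
    frozen to ``freeze_k = (K_X, K_Y)``), and the MS recomputed per
    resample.  normalized MS = MS_original - mean(shuffled MS).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")

    def factorize(D: np.ndarray, sd, K: int | None) -> PatternSet:
        if K is not None:
            dec = ensembles.nmf_factorize(
                D, K, restarts=restarts, seed=sd, refine_top=refine_top
            )
        else:
            dec = ensembles.select_num_patterns(
                D, k_range, restarts=restarts, seed=sd, refine_top=refine_top
            ).best
        return PatternSet("X", "any", dec.B.T)

    ss = np.random.SeedSequence(seed)
    ints = [int(s.generate_state(1)[0]) for s in ss.spawn(2 + 4 * n_shuffles)]
    kx, ky = freeze_k if freeze_k is not None else (None, None)
    px = factorize(D_X, ints[0], kx)
    py = factorize(D_Y, ints[1], ky)
    orig = matching_score(px, py, c=c, d=d)
    vals = np.empty(n_shuffles)
    for i in range(n_shuffles):
        s0, s1, s2, s3 = ints[2 + 4 * i : 6 + 4 * i]
        DXs = shuffle_traces(TraceMatrix(D_X), "both", s0).values
        DYs = shuffle_traces(TraceMatrix(D_Y), "both", s1).values
        psx = factorize(DXs, s2, kx)
        psy = factorize(DYs, s3, ky)
        vals[i] = matching_score(psx, psy, c=c, d=d).ms
    orig.shuffled_mean = float(vals.mean())
    orig.shuffled_sd = float(vals.std())
    orig.normalized_ms = orig.ms - orig.shuffled_mean
    return orig


SLEEP_VARIANTS = {"NREM": ("B", "C"), "REM": ("D",)}


def classify_fates(
    patterns_by_session: dict,
    c: float = DEFAULT_C,
    sleep_variant: str = "NREM",
    reference: str = "A",
    retrieval: str = "E",
    extra_sessions: tuple = ("F",),
) -> FateTable:
    """Track each session-A pattern through sleep and retrieval.

    ``patterns_by_session`` maps session label -> PatternSet for one
    group.  A pattern is present in a session iff some pattern there has
    cosine > c with it.  Category triplet = (learning, sleep, retrieval);
    aligned = '+++', isolated = '+--'.
    """
    if sleep_variant not in SLEEP_VARIANTS:
        raise ValueError(f"unknown sleep variant {sleep_variant!r}")
    sleep_labels = [s for s in SLEEP_VARIANTS[sleep_variant] if s in patterns_by_session]
    if reference not in patterns_by_session:
        raise ValueError(f"missing session {reference!r}")
    if not sleep_labels:
        raise ValueError(f"no {sleep_variant} sleep session present")
    if retrieval not in patterns_by_session:
        raise ValueError(f"missing retrieval session {retrieval!r}")
    ref = patterns_by_session[reference]
    presence: dict[int, dict[str, bool]] = {}
    for i in range(ref.n_patterns):
        presence[i] = {}
        for lab, ps in patterns_by_session.items():
            if lab == reference:
                continue
            if ps.n_patterns == 0:
                presence[i][lab] = False
                continue
            cm = ref.vectors[i] @ ps.vectors.T
            presence[i][lab] = bool((cm > c).any())
    categories = []
    aligned = []
    isolated = []
    for i in range(ref.n_patterns):
        slept = any(presence[i][s] for s in sleep_labels)
        retrieved = presence[i][retrieval]
        cat = "+" + ("+" if slept else "-") + ("+" if retrieved else "-")
        categories.append(cat)
        aligned.append(cat == "+++")
        isolated.append(cat == "+--")
    n = max(1, ref.n_patterns)
    fractions = {
        cat: categories.count(cat) / n for cat in ("+++", "++-", "+-+", "+--")
    }
    return FateTable(categories, aligned, isolated, presence, fractions, sleep_variant)


def pattern_network(patterns_by_session: dict, c: float = DEFAULT_C) -> nx.Graph:
    """Graph with a node per (session, pattern) and edges between patterns
    of different sessions whose cosine exceeds c."""
    if len(patterns_by_session) < 2:
        raise ValueError("need >= 2 sessions")
    G = nx.Graph()
    items = sorted(patterns_by_session.items())
    for lab, ps in items:
        for i in range(ps.n_patterns):
            G.add_node((lab, i))
    for a in range(len(items)):
        la, pa = items[a]
        for b in range(a + 1, len(items)):
            lb, pb = items[b]
            if pa.n_patterns == 0 or pb.n_patterns == 0:
                continue
            cm = pa.vectors @ pb.vectors.T
            for i, j in zip(*np.nonzero(cm > c)):
                G.add_edge((la, int(i)), (lb, int(j)), cosine=float(cm[i, j]))
    return G


def network_edge_list(G: nx.Graph) -> list[dict]:
    return [
        {
            "src_session": u[0],
            "src_pattern": u[1],
            "dst_session": v[0],
            "dst_pattern": v[1],
            "cosine": data["cosine"],
        }
        for u, v, data in G.edges(data=True)
    ]
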