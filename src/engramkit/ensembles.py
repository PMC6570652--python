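"""Sub-ensemble decomposition: multi-restart NMF with AICc rank selection.

The data matrix D (cells x frames, non-negative) is factorized as
D ~ B @ H with B the cells x K pattern matrix and H the K x frames
intensity matrix, minimizing the squared Frobenius cost
E = sum_ij (D_ij - (BH)_ij)^2.  Each restart runs multiplicative
(Lee-Seung) updates to near-convergence; the best restarts are then
refined with an additive projected-gradient scheme.  The pattern count is
chosen by minimizing the second-order-corrected Akaike criterion over a
candidate range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-12


@dataclass
class NmfDecomposition:
    B: np.ndarray  # cells x K, columns unit-norm after normalization
    H: np.ndarray  # K x frames
    cost: float
    K: int
    restarts_used: int
    seed: int | None = None
    clipped_fraction: float = 0.0

    def reconstruction(self) -> np.ndarray:
        return self.B @ self.H


@dataclass
class ModelSelection:
    k_range: list[int]
    costs: dict  # K -> best cost
    aicc_curve: dict  # K -> AICc (None if infeasible)
    chosen_k: int
    decompositions: dict = field(default_factory=dict)  # K -> NmfDecomposition

    @property
    def best(self) -> NmfDecomposition:
        return self.decompositions[self.chosen_k]


def _cost(D: np.ndarray, B: np.ndarray, H: np.ndarray) -> float:
    R = D - B @ H
    return float(np.sum(R * R))


def multiplicative_descent(
    D: np.ndarray,
    B: np.ndarray,
    H: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Lee-Seung multiplicative updates for the Frobenius cost.

    Returns updated factors and the cost history (cost after each
    iteration, preceded by the initial cost); the sequence is
    non-increasing.
    """
    B = B.copy()
    H = H.copy()
    history = [_cost(D, B, H)]
    for _ in range(max_iter):
        H *= (B.T @ D) / (B.T @ B @ H + _EPS)
        B *= (D @ H.T) / (B @ (H @ H.T) + _EPS)
        c = _cost(D, B, H)
        history.append(c)
        prev = history[-2]
        if prev > 0 and (prev - c) / prev < tol:
            break
    return B, H, history


def projected_gradient_refine(
    D: np.ndarray,
    B: np.ndarray,
    H: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Additive refinement: alternating projected gradient with backtracking."""
    B = B.copy()
    H = H.copy()
    cost = _cost(D, B, H)
    step_b = step_h = 1.0
    for _ in range(max_iter):
        # H step
        G = 2.0 * (B.T @ (B @ H - D))
        step_h, H, cost = _backtrack(lambda M: _cost(D, B, M), H, G, step_h, cost)
        # B step
        G = 2.0 * ((B @ H - D) @ H.T)
        step_b, B, cost_new = _backtrack(lambda M: _cost(D, M, H), B, G, step_b, cost)
        if cost > 0 and (cost - cost_new) / max(cost, _EPS) < tol:
            cost = cost_new
            break
        cost = cost_new
    return B, H, cost


def _backtrack(f, X, G, step, cost, shrink=0.5, grow=1.2, max_tries=20):
    for _ in range(max_tries):
        Xn = np.maximum(X - step * G, 0.0)
        cn = f(Xn)
        if cn <= cost:
            return step * grow, Xn, cn
        step *= shrink
    return step, X, cost


def nmf_factorize(
    D: np.ndarray,
    K: int,
    restarts: int = 1000,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    refine_top: int = 5,
    refine_iter: int = 100,
) -> NmfDecomposition:
    """Best-of-``restarts`` NMF of D at rank K.

    Negative entries of D (e.g. ΔF/F dips) are clipped at zero before
    factorization; the clipped fraction is recorded on the result.  The
    ``refine_top`` best multiplicative restarts receive additive
    projected-gradient refinement.  Deterministic given ``seed``.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.size == 0:
        raise ValueError("D must be a non-empty 2-D matrix")
    clipped = float(np.mean(D < 0))
    if clipped:
        D = np.clip(D, 0.0, None)
    n, T = D.shape
    if K < 1 or K > min(n, T):
        raise ValueError(f"K={K} outside [1, min(cells, frames)={min(n, T)}]")
    if not D.any():
        raise ValueError("all-zero data matrix")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    scale = math.sqrt(D.mean() / K)
    candidates = []
    for r in range(restarts):
        B0 = rng.uniform(_EPS, 1.0, size=(n, K)) * scale
        H0 = rng.uniform(_EPS, 1.0, size=(K, T)) * scale
        B1, H1, hist = multiplicative_descent(D, B0, H0, max_iter=max_iter, tol=tol)
        candidates.append((hist[-1], r, B1, H1))
    candidates.sort(key=lambda c: (c[0], c[1]))
    best_cost, _, Bb, Hb = candidates[0]
    for c, _, B1, H1 in candidates[: max(1, refine_top)]:
        B2, H2, c2 = projected_gradient_refine(D, B1, H1, max_iter=refine_iter)
        if c2 < best_cost:
            best_cost, Bb, Hb = c2, B2, H2
    dec = NmfDecomposition(
        Bb, Hb, best_cost, K, restarts_used=restarts, clipped_fraction=clipped
    )
    return normalize_patterns(dec)


def normalize_patterns(d: NmfDecomposition) -> NmfDecomposition:
    """Unit-L2 pattern columns; scale absorbed into H so B @ H is unchanged.

    All-zero pattern columns are dropped (K decremented).
    """
    norms = np.linalg.norm(d.B, axis=0)
    keep = norms > 0
    B = d.B[:, keep] / norms[keep]
    H = d.H[keep] * norms[keep][:, None]
    return NmfDecomposition(
        B, H, d.cost, int(keep.sum()), d.restarts_used, d.seed, d.clipped_fraction
    )


def aicc(
    cost: float,
    n_obs: int,
    n_params: int,
    cost_floor: float = 1e-300,
) -> float:
    """Gaussian-residual AICc: n ln(E/n) + 2p + 2p(p+1)/(n - p - 1)."""
    if n_obs <= n_params + 1:
        raise ValueError(
            f"n_obs ({n_obs}) must exceed n_params + 1 ({n_params + 1})"
        )
    E = max(cost, cost_floor)
    p = n_params
    return (
        n_obs * math.log(E / n_obs)
        + 2 * p
        + 2 * p * (p + 1) / (n_obs - p - 1)
    )


def nmf_param_count(K: int, n_cells: int, n_frames: int, gauge_adjusted: bool = False) -> int:
    """Parameter count for rank-K factorization: K(N+T), or K(N+T-1) with
    the per-pattern scale gauge removed."""
    return K * (n_cells + n_frames - (1 if gauge_adjusted else 0))


def select_num_patterns(
    D: np.ndarray,
    k_range,
    restarts: int = 1000,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    refine_top: int = 5,
    gauge_adjusted: bool = False,
    keep_decompositions: bool = True,
) -> ModelSelection:
    """Fit every K in ``k_range`` and pick the AICc minimizer (ties -> smaller K)."""
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("empty k_range")
    D = np.asarray(D, dtype=float)
    n, T = D.shape
    n_obs = n * T
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(k_range))
    costs: dict[int, float] = {}
    curve: dict[int, float | None] = {}
    decs: dict[int, NmfDecomposition] = {}
    for K, cs in zip(k_range, child_seeds):
        p = nmf_param_count(K, n, T, gauge_adjusted)
        if K > min(n, T) or n_obs <= p + 1:
            curve[K] = None
            continue
        dec = nmf_factorize(
            D, K, restarts=restarts, seed=np.random.default_rng(cs),
            tol=tol, max_iter=max_iter, refine_top=refine_top,
        )
        costs[K] = dec.cost
        curve[K] = aicc(dec.cost, n_obs, p)
        if keep_decompositions:
            decs[K] = dec
    feasible = {K: v for K, v in curve.items() if v is not None}
    if not feasible:
        raise ValueError("no feasible K in k_range")
    chosen = min(feasible, key=lambda K: (feasible[K], K))
    return ModelSelection(k_range, costs, curve, chosen, decs)
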