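"""Cross-session population-vector distance (restricted Mahalanobis).

Each session contributes one sample cloud of per-frame population vectors.
The distance between two sessions is computed in the eigenbasis of the
pooled covariance: per eigendimension i the term
s_i = (v_i . (mu_X - mu_Y))^2 / lambda_i, and the distance is the square
root of the sum of the ``dims`` largest terms — the maximum over any
bijective reordering of eigendimensions restricted to ``dims`` of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals_io import SessionSet

DEFAULT_DIMS = 10


@dataclass
class PvdValue:
    distance: float
    dims_used: int
    n_excluded: int  # eigenvalues under the floor
    terms: np.ndarray  # selected s_i, descending


@dataclass
class PvdResult:
    """Distances of sessions B-F to the learning session A, per cell group."""

    distances: dict  # group -> {session label -> PvdValue}
    dims: int
    difference: dict = field(default_factory=dict)  # label -> non_engram - engram


def restricted_mahalanobis(
    X: np.ndarray,
    Y: np.ndarray,
    dims: int = DEFAULT_DIMS,
    eigen_floor: float | None = None,
) -> PvdValue:
    """Restricted Mahalanobis distance between two sample clouds.

    Parameters
    ----------
    X, Y : (samples, cells) arrays over the same cell set and order.
    dims : number of eigendimensions summed (largest terms first).
    eigen_floor : eigenvalues at or below this are excluded from candidacy;
        default 1e-10 * trace(cov)/n_cells.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must share the cell dimension")
    if X.shape[0] < 2 or Y.shape[0] < 2:
        raise ValueError("each session needs >= 2 samples")
    pooled = np.vstack([X, Y])
    if pooled.shape[0] < dims:
        raise ValueError(f"pooled samples ({pooled.shape[0]}) < dims ({dims})")
    cov = np.cov(pooled, rowvar=False)
    cov = np.atleast_2d(cov)
    lam, vec = np.linalg.eigh(cov)
    if eigen_floor is None:
        eigen_floor = 1e-10 * np.trace(cov) / cov.shape[0]
    usable = lam > eigen_floor
    n_excluded = int((~usable).sum())
    dmu = X.mean(axis=0) - Y.mean(axis=0)
    proj = vec[:, usable].T @ dmu
    terms = proj**2 / lam[usable]
    terms = np.sort(terms)[::-1]
    k = min(dims, terms.size)
    sel = terms[:k]
    return PvdValue(float(np.sqrt(sel.sum())), k, n_excluded, sel)


def session_population_sample(
    session_set: SessionSet, label: str, group: str, bin_frames: int = 1
) -> np.ndarray:
    """(frames, cells) population-vector sample for one session and group.

    ``bin_frames`` > 1 averages consecutive frames into coarser bins.
    """
    tm = session_set.group_traces(label, group)
    vals = tm.values.T  # frames x cells
    if bin_frames > 1:
        T = (vals.shape[0] // bin_frames) * bin_frames
        vals = vals[:T].reshape(-1, bin_frames, vals.shape[1]).mean(axis=1)
    return vals


def pvd_profile(
    session_set: SessionSet,
    dims: int = DEFAULT_DIMS,
    reference: str = "A",
    bin_frames: int = 1,
) -> PvdResult:
    """PVD of every non-reference session to the learning session, per group."""
    if reference not in session_set:
        raise ValueError(f"missing reference session {reference!r}")
    others = [lab for lab in session_set.labels if lab != reference]
    distances: dict[str, dict[str, PvdValue]] = {}
    for group in ("engram", "non_engram"):
        ref = session_population_sample(session_set, reference, group, bin_frames)
        distances[group] = {}
        for lab in others:
            cur = session_population_sample(session_set, lab, group, bin_frames)
            distances[group][lab] = restricted_mahalanobis(cur, ref, dims=dims)
    diff = {
        lab: distances["non_engram"][lab].distance - distances["engram"][lab].distance
        for lab in others
    }
    return PvdResult(distances, dims, diff)


def pvd_report(result: PvdResult) -> dict:
    return {
        "dims": result.dims,
        "distances": {
            group: {lab: v.distance for lab, v in by_lab.items()}
            for group, by_lab in result.distances.items()
        },
        "difference_nonengram_minus_engram": result.difference,
    }
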