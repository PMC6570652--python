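"""Data model and I/O for multi-session transient matrices.

Sessions are stored on disk as comma-delimited text, one file per session,
frames as rows and cells as columns (header ``frame,<cell_id>,...``); in
memory traces are kept cells x frames.  A JSON manifest ties session files
to labels (A-F), sleep/wake stage, frame rate, and the shared cell
registry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

SESSION_LABELS = ("A", "B", "C", "D", "E", "F")
STAGES = ("awake", "NREM", "REM")

EngramLabel = Literal["engram", "non_engram"]


class ManifestError(ValueError):
    """Raised when a manifest or its session files are inconsistent."""


@dataclass(frozen=True)
class Cell:
    id: str
    x: float
    y: float
    engram: bool | None = None


@dataclass
class CellRegistry:
    """Ordered registry of cells shared by every session of an experiment.

    ``engram`` flags may be unset (``None``) until labelling has run.
    """

    cells: list[Cell]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ManifestError("duplicate cell_ids in registry")
        for c in self.cells:
            if c.x < 0 or c.y < 0:
                raise ManifestError(f"negative centroid for cell {c.id!r}")

    @property
    def cell_ids(self) -> list[str]:
        return [c.id for c in self.cells]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) array of (x, y) centroids."""
        return np.array([(c.x, c.y) for c in self.cells], dtype=float).reshape(-1, 2)

    def engram_mask(self) -> np.ndarray:
        flags = [c.engram for c in self.cells]
        if any(f is None for f in flags):
            raise ValueError("engram flags unset; run labelling or load a labels file")
        return np.array(flags, dtype=bool)

    def with_engram_ids(self, engram_ids: Sequence[str]) -> "CellRegistry":
        wanted = set(engram_ids)
        unknown = wanted - set(self.cell_ids)
        if unknown:
            raise ManifestError(f"unknown cell ids in labels: {sorted(unknown)}")
        return CellRegistry(
            [replace(c, engram=(c.id in wanted)) for c in self.cells]
        )

    def indices_of(self, group: EngramLabel) -> np.ndarray:
        mask = self.engram_mask()
        return np.flatnonzero(mask if group == "engram" else ~mask)


@dataclass
class TraceMatrix:
    """cells x frames fluorescence matrix; ``normalized`` marks ΔF/F traces."""

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trace matrix must be 2-D (cells x frames)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries in trace matrix")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class Session:
    label: str
    stage: str
    frame_rate_hz: float
    traces: TraceMatrix

    def __post_init__(self) -> None:
        if self.label not in SESSION_LABELS:
            raise ManifestError(f"unknown session label {self.label!r}")
        if self.stage not in STAGES:
            raise ManifestError(f"unknown stage {self.stage!r}")
        if not self.frame_rate_hz > 0:
            raise ManifestError("frame_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.traces.n_frames / self.frame_rate_hz


@dataclass
class SessionSet:
    """Ordered sessions over one shared cell registry."""

    sessions: list[Session]
    registry: CellRegistry

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sessions]
        if len(set(labels)) != len(labels):
            raise ManifestError("duplicate session label")
        n = self.registry.n_cells
        for s in self.sessions:
            if s.traces.n_cells != n:
                raise ManifestError(
                    f"session {s.label}: {s.traces.n_cells} cells, registry has {n}"
                )
        rates = {s.frame_rate_hz for s in self.sessions}
        if len(rates) > 1:
            raise ManifestError(f"frame rates differ across sessions: {sorted(rates)}")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.sessions]

    def __getitem__(self, label: str) -> Session:
        for s in self.sessions:
            if s.label == label:
                return s
        raise KeyError(f"no session {label!r}")

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def group_traces(self, label: str, group: EngramLabel) -> TraceMatrix:
        """Traces of one session restricted to the engram or non-engram group."""
        idx = self.registry.indices_of(group)
        sess = self[label]
        return TraceMatrix(sess.traces.values[idx], sess.traces.normalized)


# ---------------------------------------------------------------------------
# ΔF/F


def deltaf_over_f(
    raw: TraceMatrix,
    baseline: str = "mean",
    percentile: float = 20.0,
    cell_ids: Sequence[str] | None = None,
) -> TraceMatrix:
    """Per-cell ΔF/F: (F(t) - F0) / F0 with F0 the session baseline.

    ``baseline`` is ``"mean"`` (default, the per-trace analogue of a
    session-mean baseline image) or ``"percentile"``.
    """
    F = raw.values
    if baseline == "mean":
        f0 = F.mean(axis=1)
    elif baseline == "percentile":
        f0 = np.percentile(F, percentile, axis=1)
    else:
        raise ValueError(f"unknown baseline strategy {baseline!r}")
    bad = np.flatnonzero(f0 <= 0)
    if bad.size:
        names = (
            [cell_ids[i] for i in bad[:5]] if cell_ids is not None else bad[:5].tolist()
        )
        raise ValueError(f"non-positive baseline F0 for cells {names}")
    return TraceMatrix((F - f0[:, None]) / f0[:, None], normalized=True)


# ---------------------------------------------------------------------------
# manifest I/O


def write_session_set(s: SessionSet, out_dir: str | Path) -> Path:
    """Write one CSV per session plus ``manifest.json``; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = s.registry.cell_ids
    header = ",".join(["frame"] + ids)
    entries = []
    for sess in s.sessions:
        fname = f"session_{sess.label}.csv"
        lines = [header]
        vals = sess.traces.values.T  # frames x cells on disk
        for f in range(vals.shape[0]):
            lines.append(
                ",".join([str(f)] + [repr(float(v)) for v in vals[f]])
            )
        (out / fname).write_text("\n".join(lines) + "\n")
        entries.append(
            {
                "label": sess.label,
                "stage": sess.stage,
                "file": fname,
                "frame_rate_hz": sess.frame_rate_hz,
                "normalized": sess.traces.normalized,
            }
        )
    manifest = {
        "sessions": entries,
        "registry": {
            "cells": [
                {"id": c.id, "x": c.x, "y": c.y}
                | ({} if c.engram is None else {"engram": c.engram})
                for c in s.registry.cells
            ]
        },
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def _read_session_csv(path: Path) -> tuple[list[str], np.ndarray]:
    text = path.read_text().strip()
    if not text:
        raise ManifestError(f"empty session file {path}")
    lines = text.splitlines()
    cols = lines[0].split(",")
    if cols[0] != "frame":
        raise ManifestError(f"{path}: header must start with 'frame'")
    ids = cols[1:]
    rows = []
    for ln in lines[1:]:
        parts = ln.split(",")
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ManifestError(f"{path}: non-numeric cell value ({exc})") from exc
    vals = (
        np.array(rows, dtype=float)
        if rows
        else np.empty((0, len(ids)), dtype=float)
    )
    return ids, vals.T  # cells x frames in memory


def load_session_set(manifest_path: str | Path) -> SessionSet:
    """Load a session set written by :func:`write_session_set`.

    Columns of every session file are harmonized to registry order; a
    session whose cell-id set differs from the registry is an error.
    """
    mpath = Path(manifest_path)
    if not mpath.exists():
        raise ManifestError(f"missing manifest {mpath}")
    doc = json.loads(mpath.read_text())
    registry = CellRegistry(
        [
            Cell(c["id"], float(c["x"]), float(c["y"]), c.get("engram"))
            for c in doc["registry"]["cells"]
        ]
    )
    reg_ids = registry.cell_ids
    sessions = []
    for ent in doc["sessions"]:
        fpath = mpath.parent / ent["file"]
        if not fpath.exists():
            raise ManifestError(f"missing session file {fpath}")
        ids, vals = _read_session_csv(fpath)
        if set(ids) != set(reg_ids):
            raise ManifestError(
                f"session {ent['label']}: cell set mismatch with registry"
            )
        order = [ids.index(i) for i in reg_ids]
        sessions.append(
            Session(
                label=ent["label"],
                stage=ent["stage"],
                frame_rate_hz=float(ent["frame_rate_hz"]),
                traces=TraceMatrix(vals[order], bool(ent.get("normalized", False))),
            )
        )
    return SessionSet(sessions, registry)


def write_labels(registry: CellRegistry, path: str | Path) -> None:
    """Labels file: JSON map cell_id -> "engram" | "non_engram"."""
    mask = registry.engram_mask()
    doc = {
        c.id: ("engram" if m else "non_engram")
        for c, m in zip(registry.cells, mask)
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_labels(path: str | Path) -> dict[str, EngramLabel]:
    doc = json.loads(Path(path).read_text())
    bad = {v for v in doc.values()} - {"engram", "non_engram"}
    if bad:
        raise ManifestError(f"unknown labels {sorted(bad)}")
    return doc


def apply_labels(registry: CellRegistry, labels: dict[str, EngramLabel]) -> CellRegistry:
    missing = set(registry.cell_ids) - set(labels)
    if missing:
        raise ManifestError(f"labels missing for cells {sorted(missing)[:5]}")
    return registry.with_engram_ids(
        [cid for cid in registry.cell_ids if labels[cid] == "engram"]
    )
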