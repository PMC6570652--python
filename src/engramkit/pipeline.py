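"""One-command orchestration of the full analysis chain.

Stage order: labels -> repetition -> pvd -> ensembles -> matching -> fates.
Each stage writes a JSON artifact keyed by a content hash of its inputs
and parameters, so reruns with an unchanged config skip completed stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import (
    engram_id,
    ensembles,
    pattern_matching,
    population_distance,
    repetition,
    signals_io,
)

log = logging.getLogger("engramkit.pipeline")

#: parameter presets: "paper" mirrors the printed defaults, "test" is a
#: scaled-down profile for desk-scale runs.
PRESETS = {
    "paper": dict(
        window_s=1.0, step_s=0.2, span_s=60.0, dims=10,
        k_min=1, k_max=15, restarts=1000, refine_top=5,
        c=0.6, d=0.5, overlap_shuffles=10_000, ms_shuffles=40,
    ),
    "test": dict(
        window_s=1.0, step_s=0.2, span_s=60.0, dims=10,
        k_min=1, k_max=6, restarts=50, refine_top=3,
        c=0.6, d=0.5, overlap_shuffles=200, ms_shuffles=5,
    ),
}


@dataclass
class PipelineConfig:
    manifest: str
    out_dir: str
    labels: str | None = None
    snapshot: str | None = None
    seed: int = 0
    preset: str = "paper"
    stages: tuple = ("labels", "repetition", "pvd", "ensembles", "matching", "fates")
    params: dict = field(default_factory=dict)
    translate: tuple = (0.0, 0.0)

    def resolved_params(self) -> dict:
        base = dict(PRESETS[self.preset])
        base.update(self.params)
        return base


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _cached(path: Path, key: str):
    if path.exists():
        doc = json.loads(path.read_text())
        if doc.get("_cache_key") == key:
            return doc
    return None


def _store(path: Path, key: str, doc: dict) -> dict:
    doc = dict(doc)
    doc["_cache_key"] = key
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=1, default=float))
    return doc


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute enabled stages in dependency order and return the run report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.resolved_params()
    sset = signals_io.load_session_set(cfg.manifest)
    report: dict = {
        "config": {
            "manifest": cfg.manifest,
            "seed": cfg.seed,
            "preset": cfg.preset,
            "params": params,
        },
        "stages": {},
    }

    # --- labels ------------------------------------------------------------
    if cfg.labels:
        labels = signals_io.load_labels(cfg.labels)
        sset.registry = signals_io.apply_labels(sset.registry, labels)
        report["stages"]["labels"] = {"source": cfg.labels}
    elif "labels" in cfg.stages:
        if not cfg.snapshot:
            raise ValueError("snapshot required: engram_id stage enabled without labels")
        import tifffile

        snap = tifffile.imread(cfg.snapshot)
        registry, rois = engram_id.label_cells_from_snapshot(
            snap, sset.registry, translate=cfg.translate
        )
        sset.registry = registry
        labels_path = out / "labels.json"
        signals_io.write_labels(registry, labels_path)
        report["stages"]["labels"] = {
            "source": cfg.snapshot,
            "n_rois": len(rois),
            "n_engram": int(registry.engram_mask().sum()),
            "out": str(labels_path),
        }
    n_eng = int(sset.registry.engram_mask().sum())
    log.info("labels: %d engram / %d cells", n_eng, sset.registry.n_cells)

    # --- repetition ---------------------------------------------------------
    if "repetition" in cfg.stages:
        key = _hash(["repetition", cfg.manifest, cfg.seed, params])
        path = out / "repetition.json"
        doc = _cached(path, key)
        if doc is None:
            rep = repetition.repetition_report(
                sset, "A",
                window_s=params["window_s"], step_s=params["step_s"],
                span_s=params["span_s"],
                n_shuffles=params["overlap_shuffles"], seed=cfg.seed,
            )
            doc = _store(path, key, rep)
        report["stages"]["repetition"] = doc

    # --- pvd ----------------------------------------------------------------
    if "pvd" in cfg.stages:
        key = _hash(["pvd", cfg.manifest, params["dims"]])
        path = out / "pvd.json"
        doc = _cached(path, key)
        if doc is None:
            res = population_distance.pvd_profile(sset, dims=params["dims"])
            doc = _store(path, key, population_distance.pvd_report(res))
        report["stages"]["pvd"] = doc

    # --- ensembles ----------------------------------------------------------
    pattern_sets: dict = {}
    if {"ensembles", "matching", "fates"} & set(cfg.stages):
        k_range = range(params["k_min"], params["k_max"] + 1)
        sel_curves: dict = {}
        ss = np.random.SeedSequence(cfg.seed)
        seeds = iter(
            int(s.generate_state(1)[0])
            for s in ss.spawn(2 * len(sset.sessions))
        )
        for group in ("engram", "non_engram"):
            pattern_sets[group] = {}
            sel_curves[group] = {}
            for sess in sset.sessions:
                D = sset.group_traces(sess.label, group).values
                sel = ensembles.select_num_patterns(
                    D, k_range, restarts=params["restarts"],
                    seed=next(seeds), refine_top=params["refine_top"],
                )
                pattern_sets[group][sess.label] = pattern_matching.PatternSet(
                    sess.label, group, sel.best.B.T
                )
                sel_curves[group][sess.label] = {
                    "chosen_k": sel.chosen_k,
                    "aicc": {str(k): v for k, v in sel.aicc_curve.items()},
                }
        report["stages"]["ensembles"] = sel_curves
        (out / "ensembles.json").write_text(
            json.dumps(sel_curves, indent=1, default=float)
        )

    # --- matching -----------------------------------------------------------
    if "matching" in cfg.stages:
        prof = pattern_matching.ms_profile(pattern_sets, c=params["c"])
        report["stages"]["matching"] = prof
        (out / "matching.json").write_text(json.dumps(prof, indent=1, default=float))

    # --- fates --------------------------------------------------------------
    if "fates" in cfg.stages:
        fates: dict = {}
        for group in pattern_sets:
            fates[group] = {}
            for variant in ("NREM", "REM"):
                try:
                    ft = pattern_matching.classify_fates(
                        pattern_sets[group], c=params["c"], sleep_variant=variant
                    )
                except ValueError:
                    continue
                fates[group][variant] = {
                    "categories": ft.categories,
                    "fractions": ft.fractions,
                    "aligned_fraction": float(np.mean(ft.aligned)) if ft.aligned else 0.0,
                    "isolated_fraction": float(np.mean(ft.isolated)) if ft.isolated else 0.0,
                }
        report["stages"]["fates"] = fates
        (out / "fates.json").write_text(json.dumps(fates, indent=1, default=float))

    report["provenance"] = {"config_hash": _hash(asdict(cfg)), "seed": cfg.seed}
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report


def summarize(report: dict) -> dict:
    """Figure-style tables (CSV-ready lists of rows) from a run report.

    Emits one table per completed stage; missing stages are listed under
    ``"missing"``.
    """
    tables: dict = {"missing": []}
    stages = report.get("stages", {})

    if "repetition" in stages:
        rep = stages["repetition"]
        tables["repetition_ratios"] = {
            "header": ["group", "ratio_vs_nonengram"],
            "rows": [
                ["engram", rep["ratio_engram_vs_nonengram"]],
                ["non_engram", 1.0],
                ["shuffled_engram", rep["ratio_shuffled_vs_nonengram"]],
            ],
        }
    else:
        tables["missing"].append("repetition")

    if "pvd" in stages:
        dists = stages["pvd"]["distances"]
        sessions = sorted(next(iter(dists.values())).keys())
        tables["pvd_profile"] = {
            "header": ["group"] + sessions,
            "rows": [
                [g] + [dists[g][s] for s in sessions] for g in sorted(dists)
            ],
        }
    else:
        tables["missing"].append("pvd")

    if "matching" in stages:
        prof = stages["matching"]
        sessions = sorted(prof.get("engram", {}).keys())
        rows = [
            [g] + [prof[g][s] for s in sessions]
            for g in ("engram", "non_engram")
            if g in prof
        ]
        tables["ms_profile"] = {"header": ["group"] + sessions, "rows": rows}
    else:
        tables["missing"].append("matching")

    if "fates" in stages:
        rows = []
        for group, by_variant in stages["fates"].items():
            for variant, doc in by_variant.items():
                for cat, frac in doc["fractions"].items():
                    rows.append([group, variant, cat, frac])
        tables["fate_fractions"] = {
            "header": ["group", "sleep_variant", "category", "fraction"],
            "rows": rows,
        }
    else:
        tables["missing"].append("fates")
    return tables


def write_tables_csv(tables: dict, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, tab in tables.items():
        if name == "missing":
            continue
        path = out / f"{name}.csv"
        lines = [",".join(map(str, tab["header"]))]
        lines += [",".join(map(str, row)) for row in tab["rows"]]
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    return written
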