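# engramkit

Analysis toolkit for discriminating engram from non-engram cell populations in
head-mounted-microscope calcium imaging, with a bundled synthetic-experiment
generator so every stage is testable offline.

The pipeline covers five analyses over a shared multi-session data model
(sessions A–F: learning, NREM/REM sleep, retrieval, different context):

| stage | module | what it computes |
|---|---|---|
| repetition | `engramkit.repetition` | sliding-window (1 s / 200 ms) correlation matrices, their overlap `M(t,t′) = Σ_{i≠j} C_ij^t C_ij^{t′} / (N(N−1))`, time-summed `M_total`, and a Monte-Carlo shuffle null of the span-summed statistic |
| population distance | `engramkit.population_distance` | restricted Mahalanobis population-vector distance of each session to the learning session: sum of the 10 largest per-eigendimension terms `(vᵀΔμ)²/λ` of the pooled covariance |
| sub-ensembles | `engramkit.ensembles` | multi-restart NMF (multiplicative updates + additive projected-gradient refinement) with AICc model-order selection |
| pattern tracking | `engramkit.pattern_matching` | cosine matching score MS (threshold c = 0.6) across sessions, shuffle-normalized MS, aligned/isolated fate classification, pattern networks |
| engram labelling | `engramkit.engram_id` | reporter-snapshot enhancement (2× bin + flat-field by an r = 20 px low-pass), top-8 % intensity thresholding, watershed ROI segmentation, ROI-to-cell matching |

`engramkit.synthetic_data` generates seeded experiments — transient matrices
with planted co-active sub-ensembles whose cross-session fate is controlled,
plus reporter snapshots with ground-truth expressing cells.
`engramkit.signals_io` defines the data model and the plain-text session
format (CSV traces + JSON manifest).

## CLI

One entry point, `engramkit`, with per-stage subcommands:

```bash
# synthetic experiment (manifest + labels + ground truth + snapshot TIFF)
engramkit simulate --config cfg.json --seed 1 --out exp/

# engram/non-engram labels from a reporter snapshot
engramkit engram-id --snapshot exp/snapshot.tif --manifest exp/manifest.json --out labels.json

# individual analyses
engramkit repetition --manifest exp/manifest.json --labels labels.json --span-s 60 --shuffles 10000 --seed 1 --out rep.json
engramkit pvd        --manifest exp/manifest.json --labels labels.json --dims 10 --out pvd.json
engramkit ensembles  --manifest exp/manifest.json --labels labels.json --kmin 1 --kmax 15 --restarts 1000 --seed 1 --out patterns/
engramkit match      --patterns patterns/ --c 0.6 --out match.json
engramkit fates      --patterns patterns/ --out fates.csv

# or everything at once
engramkit pipeline run --config pipeline.json --preset paper
```

The `paper` preset keeps the published defaults (1 s / 200 ms windows, 60 s
analysis span, 10 PVD dimensions, 1000 NMF restarts, c = 0.6, 10,000 overlap
shuffles, 40 MS shuffles, 20 frames/s); the `test` preset is a scaled-down
profile for desk-scale runs. A pipeline config is JSON:

```json
{"manifest": "exp/manifest.json", "labels": "exp/labels.json",
 "out_dir": "out/", "seed": 1, "preset": "test"}
```

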