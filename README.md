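# cncorr

Cell-cycle-resolved decomposition of single-cell migration from paired
cell/nucleus trajectories, with companion tools for phenotype time-course
partitioning, cytoskeleton image analysis, DNA-content phase fitting and a
synthetic-data generator that makes every analysis testable end to end.

## Science overview

Adherent fibroblast-like cells migrate through a repeating sequence of
mechanical activities — leading-edge protrusion, trailing-edge detachment,
nucleus translocation — whose balance shifts across the cell cycle.
`cncorr` quantifies this balance from time-lapse centroid tracks of the
**cell body** and the **nucleus**:

1. **CN-correlation.** For each frame-to-frame step, the cell centroid
   displacement (CCD) and the nucleus displacement projected onto the cell's
   direction of motion (NCD<sub>∥</sub>) are combined into one angle,

   ```
   angle = atan2(CCD, NCD_par) · 180/π  ∈ [0°, 180°]
   ```

   Rigid cell-plus-nucleus translation gives exactly 45°; cell-boundary
   motion with a stationary nucleus gives exactly 90°; nucleus motion
   opposing the cell gives obtuse angles. Steps below a small motion floor
   are excluded as imaging noise.

2. **Unified normal-mixture (UNM) decomposition.** Pooled step angles from
   cells in one cell-cycle phase are decomposed by a hand-written EM fit of
   a mixture of Gaussians with a fixed component width (8° by default),
   initialised from a set of signature angles associated with known
   migratory activities (nucleus forward ≈25°, trailing-edge detachment
   ≈45°, simultaneous detachment/protrusion ≈65°, leading-edge protrusion
   ≈90°, side protrusion ≈115°, leading-edge retraction ≈145°). The fitted
   weights are the fraction of time a population devotes to each activity.
   When `k` is not given, the component count is chosen by BIC.

3. **CMPI.** A cell-motility-per-hour index summarising productive nucleus
   transport: the hourly rate of low-angle (co-moving) steps times their
   mean nucleus displacement.

Supporting modules:

- `cncorr.phenotype` — per-frame morphology/motility descriptors (area,
  aspect ratio, circularity, 3-minute instantaneous speed), an exhaustive
  least-squares three-period partitioner of whole-cycle time courses, and
  division-event alignment of multi-cell cohorts.
- `cncorr.cytoskeleton` — stress-fiber and focal-adhesion segmentation
  (background-model thresholding, matched filtering, watershed splitting,
  gap-aware fiber reconnection) plus radial localization profiles.
- `cncorr.cellcycle` — DNA-content histogram fitting (G1/S/G2-M
  compartments with a non-negative quadratic S bridge) and harvest-time
  selection for phase enrichment.
- `cncorr.simulate` — seeded generators for movies, images, DNA-content
  populations and phenotype series, each carrying ground-truth labels.
- `cncorr.pipeline` / `cncorr.cli` — declarative multi-stage runs with
  SHA-256 manifests and a `cncorr` command-line interface.

Estimators follow the scikit-learn convention: constructor parameters are
plain attributes, `fit` computes trailing-underscore attributes
(`means_`, `weights_`, `boundaries_`, …), and module-level functions are
thin wrappers around the estimators.

## Worked example

Decompose pooled S-phase step angles from five simulated 12-hour movies:

```python
import numpy as np
from cncorr.mixtures import PHASE_MIXTURES
from cncorr.simulate import MovieGenConfig, generate_cell_movie
from cncorr.cn import compute_cn_data, unm_decompose, cmpi, CNProfile

movies = [generate_cell_movie(PHASE_MIXTURES["S"],
                              MovieGenConfig(duration=720.0, seed=s))
          for s in range(5)]
profiles = [compute_cn_data(m, cell_id=i) for i, m in enumerate(movies)]
pooled = CNProfile.concatenate(profiles)
print(f"pooled steps: {len(pooled)}")

fit = unm_decompose(pooled.angle, k=4)
for mean, w, lab in zip(fit.means_, fit.weights_, fit.labels_):
    print(f"  {mean:6.1f} deg  weight {100*w:4.1f}%  {lab}")

r = cmpi(profiles[0])
print(f"CMPI = {r.cmpi:.3f} um/h  (occurrence {r.occurrence:.2f}/h, "
      f"mean NCD {r.mean_ncd:.3f} um)")
```

Output:

```
pooled steps: 3600
    17.0 deg  weight  4.0%  nucleus_forward
    41.3 deg  weight 17.7%  trailing_edge_detachment
    81.1 deg  weight 69.0%  leading_edge_protrusion
   144.6 deg  weight  9.3%  leading_edge_retraction
CMPI = 0.152 um/h  (occurrence 0.36/h, mean NCD 0.419 um)
```

The same analysis from the command line:

```
$ cncorr simulate movie --phase S --duration 720 --seed 3 --out movie
wrote movie.csv
$ cncorr cn profile movie.csv --out profile.csv
wrote profile.csv
$ cncorr cn decompose profile.csv --k 4
wrote unm.json
$ cncorr cn cmpi profile.csv
{"occurrence": 0.36527777777777776, "mean_ncd_um": 0.46375280859688, "cmpi_um": 0.16939859536247143, "n": 720}
```

DNA-content phase fitting:

```
$ cncorr simulate dna --g1 60 --s 25 --g2m 15 --n-cells 4000 --seed 7 --out dna.csv
wrote dna.csv
$ cncorr cellcycle fit dna.csv --out fit.json
{"g1": 60.31796477183765, "s": 25.981927264429824, "g2m": 13.700107963732522}
```

A full multi-stage run from a YAML config (any subset of
`simulate, cn, phenotype, cytoskeleton, cellcycle`):

```
$ cncorr run --config run.yaml --seed 1 --out runs/demo
```

writes every stage's artifacts plus `manifest.json` with SHA-256 digests;
rerunning the identical config reproduces byte-identical outputs.

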