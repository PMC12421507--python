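# evtrack

Segmentation and per-cell quantification of extracellular-vesicle (EV)
uptake in multi-channel fluorescence time-lapse microscopy.

Dye-labelled EVs appear as diffraction-limited puncta; the cells that take
them up are imaged with a membrane stain (cell bodies, often with dim,
partially broken outlines) and a DNA stain (nuclei).  `evtrack` answers, per
cell and per time point: *how many EVs are inside, and how much of the cell
do they cover?*

The pipeline:

1. **Dual-branch U-Net** — one encoder, two heads: per-pixel regression of
   the per-instance-normalized Euclidean distance transform (smooth L1
   loss), and background/interior/border classification (Dice loss).  A
   single network is trained on an *aggregated channel*, the per-pixel
   maximum of the three normalized planes, with targets merging all entity
   instances.
2. **Triple prediction** — at inference the same network runs independently
   on the nuclei, EV and merge channels; seeded watershed on the negated
   distance map, constrained to the predicted foreground, turns each map
   pair into instances.
3. **Fusion postprocessing** — a rule-based merge around one tunable
   hyperparameter τ: EV detections overlapping the nuclei foreground on more
   than τ of their area are deleted; nuclei without a supporting cell are
   deleted; cell masks are repaired against sparse borders by morphological
   closing.
4. **Uptake quantification** — the n largest first-frame cells are tracked
   by nearest centroid; per frame each tracked cell gets
   `evs_per_cell = (# internal EVs) / max(# nuclei, 1)` (an EV is internal
   iff ≥ 50 % of its pixels lie in the cell mask) and
   `coverage_percent = 100 · (internal EV area) / (cell area)`.

Because real microscopy of this kind is rarely shareable, the package ships
a seeded synthetic-scene generator with exact instance ground truth (cells,
nuclei, EVs, internal/external flags, per-cell truth tables) and a
time-lapse mode whose internal EV count follows a user-supplied uptake
curve on the standard acquisition schedule (every 5 min from 30 to 60 min
after administration, then every 10 min to 4 h).  The network is a compact
numpy implementation (im2col convolutions, hand-written backward passes,
Adam), gradient-checked in the test suite and sized for a single CPU.

## Worked example

```python
import numpy as np
from evtrack import (SceneParams, generate_scene, generate_timelapse,
                     triple_predict, fuse, select_tracked_cells,
                     quantify_timelapse)
from evtrack.dual_unet import ModelConfig, AugmentConfig, train_model

# 24 training scenes across four uptake conditions
train = [generate_scene(SceneParams(seed=1000 * ci + j, n_evs_internal=n))
         for ci, n in enumerate((2, 5, 8, 12)) for j in range(6)]
run = train_model(train, ModelConfig(), AugmentConfig(), epochs=50, seed=7)

# a time-lapse whose internal EV load rises linearly from 0 to 10 per cell
tl = generate_timelapse(SceneParams(seed=42),
                        lambda t: 10.0 * (t - 30.0) / 210.0)
results = [fuse(*triple_predict(run.model, f), tau=0.5) for f in tl.frames]
tracks = select_tracked_cells(results, 3)
table = quantify_timelapse(results, tracks, tl.schedule)
print(table[table.time_min == 240.0])
```

prints the last-frame rows of the uptake table (25 frames × 3 tracks in
total), e.g.:

```
    time_min  track_id  internal_ev_count  n_nuclei  evs_per_cell  cell_area_px  internal_ev_area_px  coverage_percent
72     240.0         7                  2         1           2.0           354                   23          6.497175
73     240.0        10                  3         1           3.0           403                   55         13.647643
74     240.0        12                  2         1           2.0           330                   33         10.000000
```

Each row: at 240 min this tracked cell contains 2–3 internalized EVs, one
nucleus (so 2.0–3.0 EVs per cell), and EV pixels cover ~6–14 % of its area.
Trajectories of `evs_per_cell` over time recover the simulated uptake curve
(Spearman ≥ 0.9 against ground truth on the default fixture).

The same stages are scriptable from the shell:

```sh
evtrack simulate --out data --seed 3
evtrack train    --data data --out ckpt --seed 7
evtrack segment  --ckpt ckpt --images data --out seg --tau 0.5
evtrack quantify --masks seg --manifest data/manifest.json --n-cells 3 --out uptake.csv
evtrack run      --images data --ckpt ckpt --out results   # all of the above
```

## Layout

| module | contents |
| --- | --- |
| `evtrack.synthetic` | seeded scene/time-lapse generator, TIFF+manifest dataset I/O |
| `evtrack.targets` | distance-transform and border-class training targets |
| `evtrack.dual_unet` | losses, aggregation, augmentation, training loop, checkpoints |
| `evtrack._nn` | numpy U-Net core (im2col conv, pooling, Adam) |
| `evtrack.fusion` | map→instance conversion, triple prediction, fusion rules |
| `evtrack.quantify` | cell tracking, internal/external split, uptake table |
| `evtrack.io` | pipeline config (strict schema), frame readers, pipeline driver |
| `evtrack.cli` | `evtrack` command: simulate / train / segment / quantify / run |

See `docs/methods.md` for the model, parameter defaults and limitations.
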