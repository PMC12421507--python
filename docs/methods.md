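# Methods

## Problem and model

`evtrack` quantifies the cellular uptake of dye-labelled extracellular
vesicles (EVs) from multi-channel fluorescence time-lapse microscopy.  Each
acquisition carries three planes: a DNA stain marking nuclei, a far-red
membrane dye marking EV puncta, and a membrane/merge channel delineating the
cell bodies.  The quantities of interest, per tracked cell and per time
point, are the number of internalized EVs normalized by the number of nuclei
in the cell area (*EVs per cell*) and the EV-covered fraction of the cell
area (*coverage percent*), the latter being more robust when EVs cluster
into puncta that cannot be resolved as individual particles.

Segmentation uses a dual-branch U-Net: one encoder feeds two heads,

* a **regression head** predicting, per pixel, the Euclidean distance to the
  instance boundary, normalized per instance to [0, 1] (sigmoid output);
* a **classification head** predicting a three-class map — background,
  instance interior, instance border (per-pixel softmax).

Per-instance max-normalization makes the regression target scale-free: the
network sees cell bodies (~20 px across) and EV puncta (~3 px) in a single
training channel, and both peak at 1.  The border class exists so that
touching instances remain separable: the ridge of border pixels between two
adjacent objects prevents their basins from merging.

A single network is trained on one **aggregated channel** — the per-pixel
maximum of the three min-max-normalized planes — with targets that merge all
entity instances (cells first, then nuclei, then EVs, smaller entities
overwriting larger where they overlap, each with its own border width).  At
inference the same network is applied independently to the three channels
(*triple prediction*); entity identity comes from the channel, not the
network.

### From maps to instances

The network's outputs are converted to instances by seeded watershed:
connected components of `{distance >= seed_threshold}` are seeds; regions
grow on the negated distance map, constrained to the predicted foreground
(interior ∪ border).  On ideal maps this procedure reconstructs the
generating label image exactly (verified as a zero-tolerance property over
100 random scenes), which separates errors of the learned model from errors
of the post-processing.

### Fusion postprocessing

Per frame, the three raw label images are merged by three rules governed by
one tunable hyperparameter `tau ∈ [0, 1]`:

1. an EV detection overlapping the nuclei foreground on more than
   `tau × (EV area)` pixels is deleted — DNA-channel bleed-through produces
   spurious punctate detections on nuclei;
2. a nucleus with zero overlap with the cell foreground is deleted;
3. each cell mask is repaired by morphological closing with a fixed
   3-px-radius disc (cell membranes image as dim, partially broken
   outlines — "sparse borders"), collisions resolved in favour of the larger
   cell, iterated to a fixed point so that fusion is idempotent.

The closing radius is a fixed constant rather than a second tunable, keeping
the postprocessing a one-hyperparameter step.  Rule 1 is evaluated against
the incoming nuclei foreground (before rule 2), which makes EV deletion
monotone in `tau` and the whole step idempotent.

### Counting pipeline

A fixed subset of cells (default: the 3 largest in the first frame) is
tracked through the sequence by nearest-centroid matching within a radius
(default 15 px; geometry drift in the synthetic data is zero, and adherent
cells move slowly at these time scales).  Per frame and tracked cell:

* an EV is **internal** iff ≥ 50 % of its pixels lie inside the cell mask;
  when an EV overlaps two tracked cells it is credited to the larger
  overlap (tie → lower track id), so no EV is double-counted;
* `evs_per_cell = internal count / max(n_nuclei, 1)`, with nuclei counted by
  the rounded-centroid-in-mask rule; the `max(·, 1)` guard keeps anucleate
  segmentation failures from dividing by zero;
* `coverage_percent = 100 × (internal EV pixels clipped to the cell mask) /
  cell area`.

The ≥ 50 % overlap rule (rather than centroid-in-mask) treats clustered,
partially overlapping EVs at cell edges symmetrically; the synthetic
generator uses the same rule for its truth flags, so truth and pipeline
share one definition of "internal".

## Synthetic data

Real microscopy of this kind is rarely shareable, so the generator is the
test substrate.  It emulates: star-convex cell bodies with mildly wobbled radii
(smoothed circular noise, ±35 % max) and dim interiors; membrane outlines
with a configurable fraction (default 0.3) of the perimeter suppressed in
one or two contiguous arcs (sparse borders); one nucleus per cell by default,
wholly inside the cell; EV puncta of radius ~1.6 px placed either in the
cytoplasm (internal, off-nucleus) or wholly outside all cells; Gaussian blur
(σ = 0.8 px) then additive Gaussian noise (σ = 0.03) clipped at zero.
Instances of the same class keep ≥ 2 px clearance so that ground truth is
unambiguous.  All randomness flows from one integer seed; identical
parameters give bit-identical scenes.

A time-lapse fixes cell/nucleus geometry and draws internal EV positions
once as a stream; frame *t* exposes the first `round(uptake_curve(t))` of
them, so a monotone curve produces nested internal EV sets and therefore
exactly non-decreasing truth counts.  The default acquisition schedule runs
from 30 min after EV administration, every 5 min to 60 min, then every
10 min to 240 min — 25 frames.

What the generator does **not** model: realistic point-spread functions,
photobleaching, z-structure, cell migration or division, EV docking at the
membrane, intensity heterogeneity within an entity class.  Passing tests
demonstrate the internal consistency of the method (segmentation recovers
the generating geometry; counting reproduces the constructed truth), not
performance on real microscopy.

## Training

The default configuration (depth 2, 16 base features, Adam at 1e-3, batch 2,
50 epochs) targets a single CPU at fixture scale (24 frames of 96 × 96);
these sizes mirror a 6-training / 3-test split per imaging condition with
four conditions.  Losses: soft Dice over the three classes (ε = 1e-6) for
the classification head, smooth L1 (β = 1) for the regression head, equal
weights.  A config switch adds pixel-wise cross-entropy to the Dice term;
pure Dice is the default.

One numerical choice matters: inside the training loop the smooth L1 is
applied with target-proportional pixel weights `1 + 15 t` (mean-normalized).
Distance peaks occupy a tiny fraction of a frame; unweighted, the
background term dominates and the regressor systematically undershoots the
peaks that seeding relies on, and inference finds no seeds.  The public
`smooth_l1` function keeps the plain closed form; the weighting is a
training-loop detail.

Augmentation (flip, scale 0.85–1.15, contrast 0.7–1.3, blur σ 0.4–1.0,
additive noise σ 0.01–0.05) fires independently per transform with
probabilities in [0.25, 0.3] by default; geometric transforms are applied
identically to image and targets (nearest-neighbour for the class map),
photometric transforms to the image only.

## Numerical and degenerate-input choices

* Seed thresholds: 0.5 for cells and nuclei, 0.3 for EVs (small objects have
  flat normalized distance peaks after blur).  Border widths: 2 px for cells
  and nuclei, 1 px for EVs.
* Seeds use 8-connectivity; a sub-border-width instance whose pixels are all
  border class is still seeded (seeding ignores class) and recovered.
* Distance/border targets at the image edge treat only in-image pixels as
  the instance complement.
* An empty distance map yields an empty labeling; an all-constant plane
  contributes zero to the aggregated channel; empty label images are valid
  inputs throughout.
* Instance labels are 16-bit throughout (≤ 65535 instances per frame).
* Training aborts with a diagnostic naming the epoch if a loss turns
  non-finite.

## Known limitations

* The cells channel oversegments where bright nuclei/EV structures sit
  inside a cell body; fusion's closing absorbs EV-sized fragments, but
  nucleus-sized holes can persist in cell masks.  The uptake metrics are
  insensitive to this (EVs are cytoplasmic), but cell-instance F1 on the
  merge channel is the weakest link.
* Tracking is nearest-centroid only; it is adequate for slowly moving
  adherent cells but has no appearance model and no handling of division or
  departure beyond dropping the track.
* EV identity is not linked across frames; counts are per frame, so the
  method measures accumulation, not individual EV trajectories.
* The numpy network trains at desk scale (≤ 128 × 128 patches, depth 2–3);
  it is a faithful but small realization of the architecture, not a
  GPU-scale training framework.
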