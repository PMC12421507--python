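"""Synthetic fluorescence-microscopy scenes with exact instance ground truth.

Emulates the imaging setup of an EV-uptake time-lapse experiment: adherent
cells stained with a membrane dye (merge channel), nuclei stained with a DNA
dye (nuclei channel), and dye-labelled extracellular vesicles appearing as
small bright puncta (EV channel).  Cell bodies are smoothed star-convex
polygons whose membrane outline is only partially rendered ("sparse cell
borders"); nuclei lie fully inside their cell; EV puncta are placed either in
the cytoplasm (internal) or wholly outside all cells (external).  Rendering
applies a Gaussian blur followed by additive Gaussian noise clipped at zero.

All randomness flows from the single integer seed in :class:`SceneParams`
through one ``numpy`` generator stream, so identical parameters produce
bit-identical scenes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.draw import disk as draw_disk
import tifffile


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place a requested instance."""


# number of rejection-sampling attempts before giving up on an instance
_MAX_ATTEMPTS = 200


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene.

    Attributes
    ----------
    image_size : (H, W) in pixels.
    n_cells : number of cell bodies.
    n_nuclei_per_cell : inclusive (min, max) of the per-cell nucleus count.
    n_evs_internal : EV puncta placed in the cytoplasm of some cell.
    n_evs_external : EV puncta placed wholly outside all cells.
    cell_radius : (mean, sd) of the cell radius in pixels.
    ev_radius : (mean, sd) of the EV punctum radius in pixels.
    border_gap_fraction : fraction in [0, 1] of each cell's membrane outline
        left dark, modelling sparse/broken cell borders.
    blur_sigma : Gaussian blur applied to every rendered plane (pixels).
    noise_sd : sd of additive Gaussian noise (intensity a.u.).
    seed : integer seed; the single source of randomness.
    """

    image_size: tuple[int, int] = (96, 96)
    n_cells: int = 4
    n_nuclei_per_cell: tuple[int, int] = (1, 1)
    n_evs_internal: int = 8
    n_evs_external: int = 5
    cell_radius: tuple[float, float] = (10.0, 1.5)
    ev_radius: tuple[float, float] = (1.6, 0.3)
    border_gap_fraction: float = 0.3
    blur_sigma: float = 0.8
    noise_sd: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError(f"image_size too small: {self.image_size}")
        for name in ("n_cells", "n_evs_internal", "n_evs_external"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.n_nuclei_per_cell
        if lo < 0 or hi < lo:
            raise ValueError(f"invalid n_nuclei_per_cell: {self.n_nuclei_per_cell}")
        if self.cell_radius[0] <= 0 or self.ev_radius[0] <= 0:
            raise ValueError("radii must be > 0")
        if not 0.0 <= self.border_gap_fraction <= 1.0:
            raise ValueError("border_gap_fraction must lie in [0, 1]")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise ValueError("blur_sigma and noise_sd must be >= 0")


@dataclass
class SceneTruth:
    """Exact ground truth of one scene.

    ``per_cell_truth`` maps cell label -> (n_nuclei, n_internal_evs,
    internal_ev_area in pixels).  ``ev_internal_flags[k]`` is the
    internal/external truth of EV instance ``k + 1`` under the majority
    (>= 50 % pixel overlap with the cell foreground) rule.
    """

    cells: np.ndarray
    nuclei: np.ndarray
    evs: np.ndarray
    ev_internal_flags: np.ndarray
    per_cell_truth: dict[int, tuple[int, int, int]]


@dataclass
class MultiChannelFrame:
    """One acquisition: three non-negative intensity planes plus a timestamp
    in minutes since EV administration."""

    nuclei_plane: np.ndarray
    ev_plane: np.ndarray
    merge_plane: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        shapes = {self.nuclei_plane.shape, self.ev_plane.shape, self.merge_plane.shape}
        if len(shapes) != 1:
            raise ValueError(f"planes differ in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclei_plane.shape

    def stack(self) -> np.ndarray:
        """Planes stacked as (3, H, W): nuclei, EV, merge."""
        return np.stack([self.nuclei_plane, self.ev_plane, self.merge_plane])


@dataclass
class TimeLapse:
    frames: list[MultiChannelFrame]
    truths: list[SceneTruth]
    schedule: list[float]


def default_schedule() -> list[float]:
    """Acquisition times in minutes: every 5 min from 30 to 60 min after EV
    administration, then every 10 min up to 240 min."""
    return [float(t) for t in range(30, 61, 5)] + [float(t) for t in range(70, 241, 10)]


# ----------------------------------------------------------------- geometry


def _star_polygon_mask(rng: np.random.Generator, center: tuple[float, float],
                       radius: float, shape: tuple[int, int],
                       n_vertices: int = 32, wobble: float = 0.16) -> np.ndarray:
    """Smoothed star-convex polygon: radius modulated by circularly smoothed
    noise.  Mild wobble keeps every superlevel set of the distance transform
    connected, which seeded watershed relies on."""
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    g = rng.standard_normal(n_vertices)
    kernel = np.exp(-0.5 * (np.arange(-4, 5) / 1.5) ** 2)
    kernel /= kernel.sum()
    sm = np.convolve(np.concatenate([g[-4:], g, g[:4]]), kernel, mode="same")[4:-4]
    sm = sm / (sm.std() + 1e-9)
    radii = radius * np.clip(1.0 + wobble * sm, 0.65, 1.35)
    rr = center[0] + radii * np.sin(theta)
    cc = center[1] + radii * np.cos(theta)
    mask = np.zeros(shape, dtype=bool)
    pr, pc = draw_polygon(rr, cc, shape=shape)
    mask[pr, pc] = True
    return mask


def _disk_mask(center: tuple[int, int], radius: float, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius + 0.5, shape=shape)
    mask[rr, cc] = True
    return mask


def _sample_candidate(rng: np.random.Generator, candidates: np.ndarray) -> tuple[int, int] | None:
    idx = np.flatnonzero(candidates.ravel())
    if idx.size == 0:
        return None
    k = int(rng.integers(idx.size))
    return np.unravel_index(idx[k], candidates.shape)  # type: ignore[return-value]


def _dist_outside(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance to the mask, evaluated outside it (0 on the mask)."""
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask)


@dataclass
class _Geometry:
    """Scene geometry independent of rendering: masks and bookkeeping."""

    shape: tuple[int, int]
    cell_masks: list[np.ndarray] = field(default_factory=list)
    cell_centers: list[tuple[float, float]] = field(default_factory=list)
    nucleus_masks: list[np.ndarray] = field(default_factory=list)
    nucleus_cell: list[int] = field(default_factory=list)      # cell label per nucleus
    ev_masks: list[np.ndarray] = field(default_factory=list)
    ev_cell: list[int] = field(default_factory=list)           # 0 = external

    def cells_label(self) -> np.ndarray:
        return _paint(self.cell_masks, self.shape)

    def nuclei_label(self) -> np.ndarray:
        return _paint(self.nucleus_masks, self.shape)

    def evs_label(self, order: Sequence[int] | None = None) -> np.ndarray:
        masks = self.ev_masks if order is None else [self.ev_masks[i] for i in order]
        return _paint(masks, self.shape)


def _paint(masks: Sequence[np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=np.uint16)
    for i, m in enumerate(masks, start=1):
        out[m] = i
    return out


def _place_cells(rng: np.random.Generator, params: SceneParams, geom: _Geometry) -> None:
    h, w = geom.shape
    occupied = np.zeros(geom.shape, dtype=bool)
    for i in range(params.n_cells):
        placed = False
        for _ in range(_MAX_ATTEMPTS):
            r0 = max(4.0, rng.normal(*params.cell_radius))
            margin = int(np.ceil(1.35 * r0)) + 2
            if 2 * margin >= min(h, w):
                continue
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            mask = _star_polygon_mask(rng, (cy, cx), r0, geom.shape)
            # keep >= 2 px clearance between cell instances
            if mask.sum() < 30 or (_dist_outside(occupied)[mask] < 2.5).any():
                continue
            geom.cell_masks.append(mask)
            geom.cell_centers.append((cy, cx))
            occupied |= mask
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place cell {i + 1} of {params.n_cells} "
                f"in a {h}x{w} image after {_MAX_ATTEMPTS} attempts")


def _place_nuclei(rng: np.random.Generator, params: SceneParams, geom: _Geometry) -> None:
    lo, hi = params.n_nuclei_per_cell
    placed_mask = np.zeros(geom.shape, dtype=bool)
    for cell_id, cmask in enumerate(geom.cell_masks, start=1):
        n_nuc = int(rng.integers(lo, hi + 1))
        inner = ndimage.distance_transform_edt(cmask)
        cell_r = float(inner.max())
        for j in range(n_nuc):
            nuc_r = float(np.clip(0.38 * cell_r, 2.0, 0.7 * cell_r))
            placed = False
            for _ in range(_MAX_ATTEMPTS):
                cand = (inner > nuc_r + 1.0) & (_dist_outside(placed_mask) > nuc_r + 2.0)
                pos = _sample_candidate(rng, cand)
                if pos is None:
                    nuc_r = max(2.0, nuc_r * 0.85)  # shrink and retry
                    if nuc_r <= 2.0 and not cand.any():
                        break
                    continue
                mask = _disk_mask(pos, nuc_r, geom.shape)
                if not mask.any() or not (mask <= cmask).all():
                    continue
                geom.nucleus_masks.append(mask)
                geom.nucleus_cell.append(cell_id)
                placed_mask |= mask
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place nucleus {j + 1}/{n_nuc} in cell {cell_id}")


def _place_evs(rng: np.random.Generator, params: SceneParams, geom: _Geometry,
               n_internal: int, n_external: int) -> None:
    cells_union = np.zeros(geom.shape, dtype=bool)
    for m in geom.cell_masks:
        cells_union |= m
    cells_inner = ndimage.distance_transform_edt(cells_union)
    nuclei_union = np.zeros(geom.shape, dtype=bool)
    for m in geom.nucleus_masks:
        nuclei_union |= m
    cell_label = geom.cells_label()
    ev_union = np.zeros(geom.shape, dtype=bool)
    h, w = geom.shape

    def sample_one(internal: bool, k: int) -> None:
        nonlocal ev_union
        for _ in range(_MAX_ATTEMPTS):
            r = float(np.clip(rng.normal(*params.ev_radius), 1.0, 3.0))
            clear = _dist_outside(ev_union) > r + 2.0   # >= ~2 px between EVs
            if internal:
                cand = (cells_inner > r + 1.0) & (_dist_outside(nuclei_union) > r) & clear
            else:
                cand = (_dist_outside(cells_union) > r + 2.0) & clear
                cand[: int(r) + 2, :] = False
                cand[h - int(r) - 2:, :] = False
                cand[:, : int(r) + 2] = False
                cand[:, w - int(r) - 2:] = False
            pos = _sample_candidate(rng, cand)
            if pos is None:
                continue
            mask = _disk_mask(pos, r, geom.shape)
            if not mask.any():
                continue
            geom.ev_masks.append(mask)
            geom.ev_cell.append(int(cell_label[pos]) if internal else 0)
            ev_union |= mask
            return
        kind = "internal" if internal else "external"
        raise PlacementError(
            f"could not place {kind} EV {k + 1} "
            f"(requested {n_internal} internal / {n_external} external)")

    for k in range(n_internal):
        if not cells_union.any():
            raise PlacementError(
                f"cannot place {n_internal} internal EVs with no cells")
        sample_one(True, k)
    for k in range(n_external):
        sample_one(False, k)


# ---------------------------------------------------------------- rendering

_CELL_INTERIOR = 0.30
_CELL_BORDER = 0.75
_NUC_INTENSITY = 0.85
_NUC_IN_MERGE = 0.45
_EV_INTENSITY = 1.0
_EV_IN_MERGE = 0.7


def _sparse_border(rng: np.random.Generator, mask: np.ndarray,
                   center: tuple[float, float], gap_fraction: float) -> np.ndarray:
    """Membrane outline of a cell with ``gap_fraction`` of its perimeter
    suppressed, as one or two contiguous angular arcs."""
    ring = mask & ~ndimage.binary_erosion(mask, ndimage.generate_binary_structure(2, 1))
    if gap_fraction <= 0 or not ring.any():
        return ring
    ys, xs = np.nonzero(ring)
    theta = np.arctan2(ys - center[0], xs - center[1])  # [-pi, pi]
    n_gaps = int(rng.integers(1, 3))
    widths = rng.dirichlet(np.ones(n_gaps)) * gap_fraction * 2 * np.pi
    keep = np.ones(theta.size, dtype=bool)
    for wdt in widths:
        start = rng.uniform(-np.pi, np.pi)
        rel = np.mod(theta - start, 2 * np.pi)
        keep &= rel > wdt
    out = np.zeros_like(ring)
    out[ys[keep], xs[keep]] = True
    return out


def _render(rng: np.random.Generator, params: SceneParams, geom: _Geometry,
            ev_subset: Sequence[int] | None = None,
            time: float = 0.0) -> MultiChannelFrame:
    h, w = geom.shape
    nuclei_plane = np.zeros((h, w), dtype=np.float64)
    ev_plane = np.zeros((h, w), dtype=np.float64)
    merge_plane = np.zeros((h, w), dtype=np.float64)

    for m, c in zip(geom.cell_masks, geom.cell_centers):
        body = np.where(m, _CELL_INTERIOR, 0.0)
        ring = _sparse_border(rng, m, c, params.border_gap_fraction)
        body = np.maximum(body, np.where(ring, _CELL_BORDER, 0.0))
        merge_plane = np.maximum(merge_plane, body)
    for m in geom.nucleus_masks:
        nuclei_plane = np.maximum(nuclei_plane, np.where(m, _NUC_INTENSITY, 0.0))
        merge_plane = np.maximum(merge_plane, np.where(m, _NUC_IN_MERGE, 0.0))
    ev_ids = range(len(geom.ev_masks)) if ev_subset is None else ev_subset
    for i in ev_ids:
        m = geom.ev_masks[i]
        ev_plane = np.maximum(ev_plane, np.where(m, _EV_INTENSITY, 0.0))
        merge_plane = np.maximum(merge_plane, np.where(m, _EV_IN_MERGE, 0.0))

    planes = []
    for plane in (nuclei_plane, ev_plane, merge_plane):
        if params.blur_sigma > 0:
            plane = ndimage.gaussian_filter(plane, params.blur_sigma)
        if params.noise_sd > 0:
            plane = plane + rng.normal(0.0, params.noise_sd, size=plane.shape)
        planes.append(np.clip(plane, 0.0, None))
    return MultiChannelFrame(planes[0], planes[1], planes[2], time=time)


def _truth(geom: _Geometry, ev_subset: Sequence[int] | None = None) -> SceneTruth:
    ev_ids = list(range(len(geom.ev_masks))) if ev_subset is None else list(ev_subset)
    cells = geom.cells_label()
    nuclei = geom.nuclei_label()
    evs = geom.evs_label(ev_ids)
    flags = np.array([geom.ev_cell[i] > 0 for i in ev_ids], dtype=bool)
    per_cell: dict[int, tuple[int, int, int]] = {}
    for cid in range(1, len(geom.cell_masks) + 1):
        n_nuc = sum(1 for c in geom.nucleus_cell if c == cid)
        internal = [i for i in ev_ids if geom.ev_cell[i] == cid]
        area = int(sum(int(geom.ev_masks[i].sum()) for i in internal))
        per_cell[cid] = (n_nuc, len(internal), area)
    return SceneTruth(cells, nuclei, evs, flags, per_cell)


# ------------------------------------------------------------------ public


def generate_scene(params: SceneParams) -> tuple[MultiChannelFrame, SceneTruth]:
    """Generate one scene: a rendered three-plane frame and its exact truth.

    Internal EVs are placed wholly inside the cytoplasm of a cell (so the
    majority-overlap rule labels them internal); external EVs are wholly
    outside every cell.  Raises :class:`PlacementError` when the requested
    counts do not fit.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    geom = _Geometry(shape=tuple(params.image_size))
    _place_cells(rng, params, geom)
    _place_nuclei(rng, params, geom)
    _place_evs(rng, params, geom, params.n_evs_internal, params.n_evs_external)
    frame = _render(rng, params, geom)
    return frame, _truth(geom)


def generate_timelapse(params: SceneParams,
                       uptake_curve: Callable[[float], float],
                       schedule: Sequence[float] | None = None) -> TimeLapse:
    """Time-lapse with fixed cell/nucleus geometry and internal EV counts
    following ``round(uptake_curve(t))`` per frame.

    Internal EV positions are drawn once as a single stream; frame ``t``
    exposes the first ``round(uptake_curve(t))`` of them, so a monotone curve
    yields nested (hence non-decreasing) internal EV sets.  External EVs are
    constant across frames.  Rendering noise is redrawn per frame from
    sub-streams of the scene seed.
    """
    params.validate()
    sched = [float(t) for t in (schedule if schedule is not None else default_schedule())]
    if any(b <= a for a, b in zip(sched, sched[1:])):
        raise ValueError("schedule times must be strictly increasing")
    counts = [int(round(float(uptake_curve(t)))) for t in sched]
    if any(c < 0 for c in counts):
        raise ValueError("uptake_curve must be non-negative on the schedule")
    n_internal_max = max(counts) if counts else 0

    ss = np.random.SeedSequence(params.seed)
    geom_seed, *frame_seeds = ss.spawn(len(sched) + 1)
    rng = np.random.default_rng(geom_seed)
    geom = _Geometry(shape=tuple(params.image_size))
    _place_cells(rng, params, geom)
    _place_nuclei(rng, params, geom)
    _place_evs(rng, params, geom, 0, params.n_evs_external)
    n_ext = len(geom.ev_masks)
    if n_internal_max > 0:
        _place_evs(rng, params, geom, n_internal_max, 0)
    external_ids = list(range(n_ext))
    internal_ids = list(range(n_ext, n_ext + n_internal_max))

    frames, truths = [], []
    for t, k, fseed in zip(sched, counts, frame_seeds):
        subset = internal_ids[:k] + external_ids
        frng = np.random.default_rng(fseed)
        frames.append(_render(frng, params, geom, ev_subset=subset, time=t))
        truths.append(_truth(geom, ev_subset=subset))
    return TimeLapse(frames=frames, truths=truths, schedule=sched)


_LABEL_KINDS = ("cells", "nuclei", "evs")


def write_dataset(frames: Sequence[MultiChannelFrame],
                  truths: Sequence[SceneTruth],
                  directory: str | Path,
                  params: SceneParams | None = None) -> dict:
    """Write frames and label images as TIFF plus a JSON manifest.

    One multi-plane float32 TIFF per frame and one 16-bit label TIFF per
    entity class per frame.  The manifest records file names, acquisition
    times, seed and parameters; a round-trip read reproduces every array
    bit-exactly.
    """
    if len(frames) == 0:
        raise ValueError("empty frame sequence: nothing to write")
    if len(frames) != len(truths):
        raise ValueError("frames and truths differ in length")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "n_frames": len(frames),
        "times_min": [float(f.time) for f in frames],
        "frames": [],
        "seed": params.seed if params is not None else None,
        "params": asdict(params) if params is not None else None,
    }
    for i, (frame, truth) in enumerate(zip(frames, truths)):
        entry = {"time_min": float(frame.time)}
        img_name = f"frame_{i:03d}.tif"
        tifffile.imwrite(directory / img_name, frame.stack().astype(np.float32),
                         photometric="minisblack")
        entry["image"] = img_name
        for kind in _LABEL_KINDS:
            lab = getattr(truth, kind).astype(np.uint16)
            name = f"frame_{i:03d}_{kind}.tif"
            tifffile.imwrite(directory / name, lab)
            entry[kind] = name
        entry["ev_internal_flags"] = [bool(b) for b in truth.ev_internal_flags]
        entry["per_cell_truth"] = {str(k): list(v) for k, v in truth.per_cell_truth.items()}
        manifest["frames"].append(entry)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_dataset(directory: str | Path) -> tuple[list[MultiChannelFrame], list[SceneTruth], dict]:
    """Inverse of :func:`write_dataset`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    frames, truths = [], []
    for entry in manifest["frames"]:
        stack = tifffile.imread(directory / entry["image"])
        frames.append(MultiChannelFrame(stack[0], stack[1], stack[2],
                                        time=entry["time_min"]))
        labs = {k: tifffile.imread(directory / entry[k]) for k in _LABEL_KINDS}
        flags = np.array(entry["ev_internal_flags"], dtype=bool)
        per_cell = {int(k): tuple(v) for k, v in entry["per_cell_truth"].items()}
        truths.append(SceneTruth(labs["cells"], labs["nuclei"], labs["evs"],
                                 flags, per_cell))
    return frames, truths, manifest
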