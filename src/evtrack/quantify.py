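"""Per-cell EV uptake quantification over a time-lapse.

A fixed subset of cells is selected on the first frame (largest areas) and
followed through the sequence by nearest-centroid matching.  Per frame and
per tracked cell the pipeline reports the internal EV count (majority pixel
overlap with the cell mask), the count normalized by the number of nuclei in
the cell area (EVs per cell), and the EV-covered fraction of the cell area —
the uptake metrics of the counting pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .fusion import SegmentationResult

logger = logging.getLogger(__name__)

#: column order of the uptake table / CSV
UPTAKE_COLUMNS = ["time_min", "track_id", "internal_ev_count", "n_nuclei",
                  "evs_per_cell", "cell_area_px", "internal_ev_area_px",
                  "coverage_percent"]


@dataclass
class TrackedCellSet:
    """Cells followed through a time-lapse.

    ``track_ids`` are the first-frame cell labels of the selected cells;
    ``frame_maps[f][tid]`` is the cell label carrying track ``tid`` in
    frame ``f``.
    """

    track_ids: list[int]
    frame_maps: list[dict[int, int]]


def _centroids(labels: np.ndarray) -> dict[int, tuple[float, float]]:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return {}
    cents = ndimage.center_of_mass(labels > 0, labels, ids)
    return {int(i): (float(c[0]), float(c[1])) for i, c in zip(ids, cents)}


def select_tracked_cells(results: list[SegmentationResult], n: int,
                         match_radius: float = 15.0) -> TrackedCellSet:
    """Choose the ``n`` largest first-frame cells trackable in every frame.

    A candidate is matched frame by frame to the nearest cell centroid within
    ``match_radius`` pixels; candidates that cannot be matched in some frame
    are dropped with a warning.  If fewer than ``n`` candidates survive, all
    matchable tracks are returned (with a warning).
    """
    if not results:
        raise ValueError("need at least one frame")
    first = results[0].cells
    areas = np.bincount(first.ravel())
    ids = [int(i) for i in np.argsort(areas[1:])[::-1] + 1
           if i < areas.size and areas[i] > 0]
    per_frame_centroids = [_centroids(r.cells) for r in results]

    track_ids: list[int] = []
    frame_maps: list[dict[int, int]] = [dict() for _ in results]
    for cid in ids:
        if len(track_ids) >= n:
            break
        cy, cx = per_frame_centroids[0][cid]
        mapping = {0: cid}
        ok = True
        ref = (cy, cx)
        for f in range(1, len(results)):
            cents = per_frame_centroids[f]
            if not cents:
                ok = False
                break
            dists = {lab: np.hypot(c[0] - ref[0], c[1] - ref[1])
                     for lab, c in cents.items()}
            best = min(dists, key=lambda k: (dists[k], k))
            if dists[best] > match_radius:
                ok = False
                break
            mapping[f] = best
            ref = cents[best]
        if ok:
            track_ids.append(cid)
            for f, lab in mapping.items():
                frame_maps[f][cid] = lab
        else:
            logger.warning("cell %d of frame 0 could not be tracked through "
                           "all frames; dropped", cid)
    if len(track_ids) < n:
        logger.warning("requested %d tracked cells but only %d are matchable "
                       "in every frame", n, len(track_ids))
    return TrackedCellSet(track_ids=track_ids, frame_maps=frame_maps)


def split_internal_external(evs: np.ndarray, cell_mask: np.ndarray
                            ) -> tuple[list[int], list[int]]:
    """Partition EV instances into internal/external wrt one cell mask.

    An EV is internal iff at least 50 % of its pixels lie inside
    ``cell_mask``; the partition is exhaustive and disjoint.
    """
    if evs.shape != cell_mask.shape:
        raise ValueError("shape mismatch between EV labels and cell mask")
    internal, external = [], []
    for eid in np.unique(evs):
        if eid == 0:
            continue
        mask = evs == eid
        if cell_mask[mask].sum() * 2 >= mask.sum():
            internal.append(int(eid))
        else:
            external.append(int(eid))
    return internal, external


def count_nuclei_in_cell(nuclei: np.ndarray, cell_mask: np.ndarray) -> int:
    """Number of nucleus instances whose centroid lies inside the cell mask.

    Centroids are rounded to the nearest pixel before the containment test.
    """
    if nuclei.shape != cell_mask.shape:
        raise ValueError("shape mismatch between nucleus labels and cell mask")
    count = 0
    for nid, (cy, cx) in _centroids(nuclei).items():
        iy = min(max(int(round(cy)), 0), cell_mask.shape[0] - 1)
        ix = min(max(int(round(cx)), 0), cell_mask.shape[1] - 1)
        if cell_mask[iy, ix]:
            count += 1
    return count


def _credit_evs(evs: np.ndarray, masks: dict[int, np.ndarray]) -> dict[int, list[int]]:
    """Assign each EV to at most one tracked cell: majority overlap decides
    internality, the largest overlap (tie -> lower track id) decides credit,
    so no EV is double-booked across tracked cells."""
    credited: dict[int, list[int]] = {tid: [] for tid in masks}
    for eid in np.unique(evs):
        if eid == 0:
            continue
        emask = evs == eid
        area = emask.sum()
        overlaps = {tid: int(m[emask].sum()) for tid, m in masks.items()}
        best = min(overlaps, key=lambda t: (-overlaps[t], t)) if overlaps else None
        if best is not None and overlaps[best] * 2 >= area and overlaps[best] > 0:
            credited[best].append(int(eid))
    return credited


def quantify_frame(result: SegmentationResult, tracks: TrackedCellSet,
                   time: float, frame_index: int = 0) -> list[dict]:
    """Uptake-table rows for one frame (one row per resolvable track)."""
    fmap = tracks.frame_maps[frame_index]
    masks: dict[int, np.ndarray] = {}
    for tid in tracks.track_ids:
        if tid not in fmap:
            logger.warning("track %d unresolvable at t=%s min; row omitted", tid, time)
            continue
        masks[tid] = result.cells == fmap[tid]
    credited = _credit_evs(result.evs, masks)
    rows = []
    for tid, cmask in masks.items():
        cell_area = int(cmask.sum())
        ev_ids = credited[tid]
        ev_area = int(sum(int((result.evs == eid)[cmask].sum()) for eid in ev_ids))
        n_nuc = count_nuclei_in_cell(result.nuclei, cmask)
        rows.append({
            "time_min": float(time),
            "track_id": int(tid),
            "internal_ev_count": len(ev_ids),
            "n_nuclei": n_nuc,
            "evs_per_cell": len(ev_ids) / max(n_nuc, 1),
            "cell_area_px": cell_area,
            "internal_ev_area_px": ev_area,
            "coverage_percent": 100.0 * ev_area / cell_area if cell_area else 0.0,
        })
    return rows


def quantify_timelapse(results: list[SegmentationResult], tracks: TrackedCellSet,
                       schedule: list[float]) -> pd.DataFrame:
    """Concatenate per-frame rows over the schedule, sorted by (time, track)."""
    if len(results) != len(schedule):
        raise ValueError(f"{len(results)} results vs {len(schedule)} schedule entries")
    rows: list[dict] = []
    for f, (res, t) in enumerate(zip(results, schedule)):
        rows.extend(quantify_frame(res, tracks, t, frame_index=f))
    table = pd.DataFrame(rows, columns=UPTAKE_COLUMNS)
    return table.sort_values(["time_min", "track_id"]).reset_index(drop=True)
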