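"""Per-cell counting pipeline against construction-time ground truth."""

import numpy as np
import pytest

from evtrack import (
    SceneParams,
    SegmentationResult,
    generate_scene,
    generate_timelapse,
    select_tracked_cells,
    split_internal_external,
    count_nuclei_in_cell,
    quantify_frame,
    quantify_timelapse,
)


def gt_result(truth):
    return SegmentationResult(cells=truth.cells, nuclei=truth.nuclei,
                              evs=truth.evs, fusion_tau=0.5)


def all_cell_tracks(truth):
    res = gt_result(truth)
    return res, select_tracked_cells([res], n=int(truth.cells.max()))


# ------------------------------------------------------ internal/external


def test_empty_cell_mask_all_external(small_scene):
    _, _, truth = small_scene
    internal, external = split_internal_external(truth.evs, np.zeros_like(truth.cells, dtype=bool))
    assert internal == []
    assert len(external) == int(truth.evs.max())


def test_wholly_inside_ev_is_internal():
    evs = np.zeros((10, 10), dtype=np.uint16)
    evs[4:6, 4:6] = 1
    cell = np.zeros((10, 10), dtype=bool)
    cell[2:8, 2:8] = True
    internal, external = split_internal_external(evs, cell)
    assert internal == [1] and external == []


def test_half_overlap_boundary_case_is_internal():
    # 4-px EV with exactly 2 px inside: the >= 50 % convention decides
    evs = np.zeros((8, 8), dtype=np.uint16)
    evs[3:5, 3:5] = 1
    cell = np.zeros((8, 8), dtype=bool)
    cell[:, :4] = True           # covers columns 0-3 -> 2 of 4 EV px
    internal, _ = split_internal_external(evs, cell)
    assert internal == [1]
    # one pixel less -> external
    cell[:, 3] = False
    internal, external = split_internal_external(evs, cell)
    assert internal == [] and external == [1]


@pytest.mark.parametrize("seed", range(6))
def test_partition_exhaustive_and_disjoint(seed):
    _, truth = generate_scene(SceneParams(seed=seed))
    all_ids = list(range(1, int(truth.evs.max()) + 1))
    for cid in range(1, int(truth.cells.max()) + 1):
        internal, external = split_internal_external(truth.evs, truth.cells == cid)
        assert sorted(internal + external) == all_ids
        assert set(internal).isdisjoint(external)


# ------------------------------------------------------------ nucleus count


def test_count_nuclei_simple_cases():
    nuclei = np.zeros((12, 12), dtype=np.uint16)
    cell = np.zeros((12, 12), dtype=bool)
    cell[:, :6] = True
    assert count_nuclei_in_cell(nuclei, cell) == 0
    nuclei[2:4, 2:4] = 1
    nuclei[8:10, 1:3] = 2
    assert count_nuclei_in_cell(nuclei, cell) == 2


def test_nucleus_straddling_boundary_centroid_decides():
    nuclei = np.zeros((10, 10), dtype=np.uint16)
    nuclei[3:7, 2:8] = 1          # centroid at column 4.5 -> rounds to 4
    cell = np.zeros((10, 10), dtype=bool)
    cell[:, :4] = True            # columns 0-3: centroid outside
    assert count_nuclei_in_cell(nuclei, cell) == 0
    cell[:, 4] = True             # centroid now inside
    assert count_nuclei_in_cell(nuclei, cell) == 1


# ---------------------------------------------------------------- tracking


def test_select_largest_cells_single_frame(small_scene):
    _, _, truth = small_scene
    res = gt_result(truth)
    areas = np.bincount(truth.cells.ravel())
    tracks = select_tracked_cells([res], n=2)
    expected = list(np.argsort(areas[1:])[::-1][:2] + 1)
    assert tracks.track_ids == [int(i) for i in expected]
    assert tracks.frame_maps[0] == {tid: tid for tid in tracks.track_ids}


def test_select_zero_tracks_empty_table(small_scene):
    _, _, truth = small_scene
    res = gt_result(truth)
    tracks = select_tracked_cells([res], n=0)
    assert tracks.track_ids == []
    assert quantify_frame(res, tracks, 0.0) == []


def test_static_timelapse_tracks_map_to_same_mask():
    tl = generate_timelapse(SceneParams(seed=6, n_cells=3), lambda t: 2.0,
                            schedule=[30, 60, 90])
    results = [gt_result(t) for t in tl.truths]
    tracks = select_tracked_cells(results, n=3)
    assert len(tracks.track_ids) == 3
    for tid in tracks.track_ids:
        masks = [res.cells == tracks.frame_maps[f][tid]
                 for f, res in enumerate(results)]
        for m in masks[1:]:
            assert np.array_equal(m, masks[0])


def test_select_more_tracks_than_cells_warns_and_returns_all(small_scene, caplog):
    _, _, truth = small_scene
    res = gt_result(truth)
    with caplog.at_level("WARNING"):
        tracks = select_tracked_cells([res], n=99)
    assert len(tracks.track_ids) == int(truth.cells.max())
    assert any("matchable" in r.message for r in caplog.records)


# ------------------------------------------------------------- uptake table


def test_quantify_frame_arithmetic():
    cells = np.zeros((20, 20), dtype=np.uint16)
    cells[0:10, 0:10] = 1         # area 100
    nuclei = np.zeros_like(cells)
    nuclei[1:3, 1:3] = 1
    evs = np.zeros_like(cells)
    evs[5:7, 5:12] = 1            # 14 px, 10 inside -> internal, clipped area 10
    res = SegmentationResult(cells, nuclei, evs, 0.5)
    tracks = select_tracked_cells([res], n=1)
    (row,) = quantify_frame(res, tracks, 30.0)
    assert row["internal_ev_count"] == 1
    assert row["n_nuclei"] == 1
    assert row["evs_per_cell"] == 1.0
    assert row["cell_area_px"] == 100
    assert row["internal_ev_area_px"] == 10
    assert row["coverage_percent"] == pytest.approx(10.0)


def test_quantify_frame_anucleate_divisor():
    cells = np.zeros((12, 12), dtype=np.uint16)
    cells[2:10, 2:10] = 1
    evs = np.zeros_like(cells)
    evs[4:6, 4:6] = 1
    res = SegmentationResult(cells, np.zeros_like(cells), evs, 0.5)
    tracks = select_tracked_cells([res], n=1)
    (row,) = quantify_frame(res, tracks, 0.0)
    assert row["n_nuclei"] == 0 and row["evs_per_cell"] == 1.0


@pytest.mark.parametrize("seed", range(10))
def test_truth_masks_reproduce_per_cell_truth_exactly(seed):
    """Zero-tolerance oracle: counting on ground-truth masks equals the
    generator's per-cell truth table."""
    _, truth = generate_scene(SceneParams(
        seed=seed, n_cells=2 + seed % 3, n_evs_internal=4 + seed % 5))
    res, tracks = all_cell_tracks(truth)
    rows = quantify_frame(res, tracks, 0.0)
    assert len(rows) == len(truth.per_cell_truth)
    for row in rows:
        n_nuc, n_int, area = truth.per_cell_truth[row["track_id"]]
        assert row["n_nuclei"] == n_nuc
        assert row["internal_ev_count"] == n_int
        assert row["internal_ev_area_px"] == area
        cell_area = int((truth.cells == row["track_id"]).sum())
        assert row["cell_area_px"] == cell_area
        assert row["coverage_percent"] == pytest.approx(100.0 * area / cell_area)


def test_coverage_invariant_under_upsampling():
    _, truth = generate_scene(SceneParams(seed=14))
    res, tracks = all_cell_tracks(truth)
    rows = quantify_frame(res, tracks, 0.0)
    up = lambda a: np.kron(a, np.ones((2, 2), dtype=a.dtype))
    res2 = SegmentationResult(up(truth.cells), up(truth.nuclei), up(truth.evs), 0.5)
    tracks2 = select_tracked_cells([res2], n=int(truth.cells.max()))
    rows2 = quantify_frame(res2, tracks2, 0.0)
    cov1 = {r["track_id"]: r["coverage_percent"] for r in rows}
    cov2 = {r["track_id"]: r["coverage_percent"] for r in rows2}
    for tid in cov1:
        assert abs(cov1[tid] - cov2[tid]) < 0.5


def test_quantify_timelapse_cardinality_and_monotone_truth():
    curve = lambda t: 8.0 * (t - 30.0) / 210.0
    tl = generate_timelapse(SceneParams(seed=8, n_cells=3), curve)
    results = [gt_result(t) for t in tl.truths]
    tracks = select_tracked_cells(results, n=3)
    table = quantify_timelapse(results, tracks, tl.schedule)
    assert len(table) == 25 * 3
    assert list(table.columns) == ["time_min", "track_id", "internal_ev_count",
                                   "n_nuclei", "evs_per_cell", "cell_area_px",
                                   "internal_ev_area_px", "coverage_percent"]
    for tid in tracks.track_ids:
        traj = table[table.track_id == tid].sort_values("time_min")
        assert (np.diff(traj.evs_per_cell.values) >= -1e-12).all()


def test_quantify_timelapse_length_mismatch():
    _, truth = generate_scene(SceneParams(seed=1))
    res, tracks = all_cell_tracks(truth)
    with pytest.raises(ValueError):
        quantify_timelapse([res], tracks, [30.0, 40.0])
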