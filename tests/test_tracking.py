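"""Nearest-neighbour tracking, merge/split repair, mitosis detection."""

import numpy as np
import pandas as pd
import pytest

from rtqibc import (
    SimConfig,
    Track,
    TrackingParams,
    build_tracks,
    detect_mitosis,
    link_frames,
    repair_merge_split,
    simulate_population,
    tracks_to_table,
)
from rtqibc.pipeline import default_tracking_params


def obs(rows):
    return pd.DataFrame(rows, columns=["label", "y", "x", "area", "H2B_total"])


# ---------------------------------------------------------------- linking
def test_link_identical_frames_identity():
    frame = obs([[1, 10.0, 10.0, 100, 1000.0], [2, 50.0, 50.0, 100, 2000.0]])
    res = link_frames(frame, frame)
    assert sorted(res.matches) == [(0, 0), (1, 1)]
    assert not res.flags


def test_link_uniform_shift_perfect():
    gy, gx = np.mgrid[0:6, 0:5]
    pos = np.column_stack([20.0 + 36 * gy.ravel(), 20.0 + 36 * gx.ravel()])
    prev = obs([[i, y, x, 100, 1000.0 + i] for i, (y, x) in enumerate(pos)])
    curr = obs([[i, y + 3.0, x + 3.0, 100, 1000.0 + i] for i, (y, x) in enumerate(pos)])
    res = link_frames(prev, curr, max_dist_px=15.0)
    assert sorted(res.matches) == [(i, i) for i in range(30)]


def test_link_flags_merge_with_summed_signal():
    prev = obs([[1, 10.0, 10.0, 100, 1000.0], [2, 16.0, 10.0, 100, 1100.0]])
    curr = obs([[7, 13.0, 10.0, 200, 2100.0]])
    res = link_frames(prev, curr, max_dist_px=10.0)
    merges = [f for f in res.flags if f["type"] == "merge"]
    assert len(merges) == 1
    assert merges[0]["ratio"] == pytest.approx(1.0)


def test_link_severs_large_signal_change():
    prev = obs([[1, 10.0, 10.0, 100, 1000.0]])
    curr = obs([[1, 11.0, 10.0, 100, 500.0]])
    res = link_frames(prev, curr, signal_tolerance=0.25)
    assert not res.matches
    assert any(f["type"] == "signal" for f in res.flags)


# ---------------------------------------------------------------- repair
def _merged_frame_scene():
    """Two disk nuclei merged into one label, plus the matching image."""
    from rtqibc.types import Image2D, LabelMap
    from conftest import render_disk_nucleus

    img = render_disk_nucleus((64, 96), (32, 34), 9.0, 5.0e4)
    img2 = render_disk_nucleus((64, 96), (32, 52), 9.0, 5.2e4)
    image = Image2D(img.data + img2.data, 0.65)
    yy, xx = np.mgrid[0:64, 0:96]
    m = (((yy - 32) ** 2 + (xx - 34) ** 2 <= 81)
         | ((yy - 32) ** 2 + (xx - 52) ** 2 <= 81)).astype(np.int32)
    return image, LabelMap(m, 0.65)


def test_repair_merge_restores_two_tracks():
    image, mask = _merged_frame_scene()
    prev = obs([[1, 32.0, 34.0, 254, 5.0e4], [2, 32.0, 52.0, 254, 5.2e4]])
    curr = obs([[1, 32.0, 43.0, 500, 10.2e4]])
    res = link_frames(prev, curr, max_dist_px=12.0)
    assert any(f["type"] == "merge" for f in res.flags)
    curr2, res2 = repair_merge_split(res, prev, curr, mask, image)
    assert len(res2.matches) == 2
    assert len(curr2) == 3  # two repaired fragments appended
    matched_prev = sorted(i for i, _ in res2.matches)
    assert matched_prev == [0, 1]


def test_repair_no_flags_is_identity():
    frame = obs([[1, 10.0, 10.0, 100, 1000.0]])
    res = link_frames(frame, frame)
    curr2, res2 = repair_merge_split(res, frame, frame, None, None)
    assert curr2 is frame and res2 is res


def test_persistent_merge_terminates_track():
    """A merge that cannot be re-split (no masks available) ends both
    parent tracks with reason 'lost'."""
    frames = [
        obs([[1, 10.0, 10.0, 100, 1000.0], [2, 30.0, 10.0, 100, 1050.0]]),
        obs([[1, 20.0, 10.0, 200, 2050.0]]),
        obs([[1, 20.0, 10.0, 200, 2050.0]]),
    ]
    tracks = build_tracks(frames, TrackingParams(max_dist_px=12.0, vicinity_px=30.0))
    lost = [t for t in tracks if t.end_reason == "lost"]
    assert len(lost) == 2
    assert all(t.last_frame == 0 for t in lost)


def test_spurious_split_remerged():
    """A one-frame segmentation split is folded back into its track."""
    a = [[1, 10.0, 10.0, 200, 2000.0]]
    split_a = [[1, 8.0, 10.0, 100, 1000.0], [2, 13.0, 10.0, 100, 1000.0]]
    frames = [obs(a), obs(a), obs(split_a), obs(a), obs(a)]
    tracks = build_tracks(frames, TrackingParams(max_dist_px=12.0, vicinity_px=30.0))
    spanning = [t for t in tracks if t.n_frames == 5]
    assert len(spanning) == 1
    assert len(tracks) == 1


# ---------------------------------------------------------------- mitosis
def _track(tid, rows, **kw):
    df = pd.DataFrame(rows, columns=["frame", "label", "y", "x", "area", "H2B_total"])
    return Track(track_id=tid, observations=df, **kw)


def test_detect_mitosis_accepts_balanced_daughters():
    parent = _track(0, [[0, 1, 50.0, 50.0, 100, 100.0], [4, 1, 50.0, 50.0, 100, 100.0]])
    d1 = _track(1, [[5, 2, 45.0, 50.0, 50, 48.0]])
    d2 = _track(2, [[5, 3, 55.0, 50.0, 50, 51.0]])
    events = detect_mitosis([parent, d1, d2], vicinity_px=20.0, signal_tolerance=0.2,
                            n_frames=10)
    assert len(events) == 1
    assert parent.division_frame == 4
    assert d1.parent_track_id == 0 and d2.parent_track_id == 0
    assert d1.observations["frame"].iloc[0] == parent.division_frame + 1


def test_detect_mitosis_rejects_signal_violation():
    parent = _track(0, [[0, 1, 50.0, 50.0, 100, 100.0], [4, 1, 50.0, 50.0, 100, 100.0]])
    d1 = _track(1, [[5, 2, 45.0, 50.0, 50, 30.0]])
    d2 = _track(2, [[5, 3, 55.0, 50.0, 50, 30.0]])
    events = detect_mitosis([parent, d1, d2], vicinity_px=20.0, signal_tolerance=0.2,
                            n_frames=10)
    assert not events
    assert parent.division_frame is None


# ---------------------------------------------------------------- build_tracks
def test_empty_movie_and_single_cell():
    assert build_tracks([]) == []
    frames = [obs([[1, 10.0, 10.0, 100, 1000.0]]) for _ in range(6)]
    tracks = build_tracks(frames)
    assert len(tracks) == 1
    assert tracks[0].n_frames == 6
    assert tracks[0].end_reason == "movie_end"


@pytest.fixture(scope="module")
def truth_benchmark():
    """Ground-truth observations of the default 50-cell benchmark (several
    seeds pooled to accumulate > 40 programmed divisions)."""
    scenes = []
    for seed in (5, 6, 7, 8):
        cfg = SimConfig(seed=seed)
        cells = simulate_population(cfg)
        rng = np.random.default_rng(1000 + seed)
        frames = []
        for f in range(cfg.n_frames):
            rows = []
            for c in cells:
                idx = np.flatnonzero(c.frames == f)
                if not idx.size:
                    continue
                y, x = c.centroids[idx[0]]
                rows.append({"label": c.cell_id, "y": y, "x": x,
                             "area": np.pi * c.radius_px**2,
                             "H2B_total": c.h2b_total * rng.normal(1, 0.01),
                             "true_id": c.cell_id})
            frames.append(pd.DataFrame(rows))
        scenes.append((cfg, cells, frames))
    return scenes


def test_benchmark_link_accuracy_and_partition(truth_benchmark):
    """>= 99% correct frame-to-frame links; every observation in exactly
    one track; no track skips frames."""
    for cfg, cells, frames in truth_benchmark:
        tracks = build_tracks(frames, default_tracking_params(cfg))
        good = bad = 0
        for t in tracks:
            ids = t.observations["true_id"].to_numpy()
            good += int(np.sum(ids[1:] == ids[:-1]))
            bad += int(np.sum(ids[1:] != ids[:-1]))
            fr = t.observations["frame"].to_numpy()
            assert (np.diff(fr) == 1).all()
        assert good / (good + bad) >= 0.99
        n_obs = sum(len(f) for f in frames)
        assert sum(t.n_frames for t in tracks) == n_obs


def test_benchmark_division_detection(truth_benchmark):
    """>= 95% of programmed divisions detected within +-1 frame with zero
    false positives, across > 40 pooled divisions."""
    total = detected = fp = 0
    for cfg, cells, frames in truth_benchmark:
        tracks = build_tracks(frames, default_tracking_params(cfg))
        true_div = {}
        for c in cells:
            if c.parent_id is not None:
                true_div.setdefault(c.parent_id, []).append(c)
        true_div = {k: v for k, v in true_div.items() if len(v) == 2}
        total += len(true_div)
        by_id = {t.track_id: t for t in tracks}
        for t in tracks:
            if t.division_frame is None:
                continue
            true_id = int(t.observations["true_id"].iloc[-1])
            if true_id in true_div:
                parent_cell = next(c for c in cells if c.cell_id == true_id)
                if abs(t.division_frame - parent_cell.frames[-1]) <= 1:
                    detected += 1
                else:
                    fp += 1
            else:
                fp += 1
    assert total >= 40
    assert detected / total >= 0.95
    assert fp == 0


def test_lineage_consistency(truth_benchmark):
    cfg, cells, frames = truth_benchmark[0]
    tracks = build_tracks(frames, default_tracking_params(cfg))
    by_id = {t.track_id: t for t in tracks}
    for t in tracks:
        if t.parent_track_id is not None:
            parent = by_id[t.parent_track_id]
            assert t.first_frame == parent.division_frame + 1
    for t in tracks:
        daughters = [u for u in tracks if u.parent_track_id == t.track_id]
        assert len(daughters) in (0, 2)
    table = tracks_to_table(tracks)
    assert len(table) == sum(t.n_frames for t in tracks)
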