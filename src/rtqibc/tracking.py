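"""Frame-to-frame nuclear tracking with intensity-conservation repair.

Nuclei are linked between consecutive frames by mutual nearest
neighbours within a distance gate. The integrated nuclear H2B signal is
used as a conserved quantity: links whose signal changes by more than a
tolerance are severed and flagged; a flagged configuration where one
current object carries the summed signal of two lost tracks is a
candidate segmentation merge (repairable by locally re-splitting the
object), and the mirror case a candidate spurious split (repairable by
re-merging if the pair fuses again within a few frames). Mitoses are
detected where a track ends and two new tracks begin within a vicinity
of its last position with summed signal approximately equal to the
parent's. There is no gap closing: a nucleus missing from one frame
terminates its track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .quantification import measure_cells
from .segmentation import split_touching_nuclei
from .types import Image2D, LabelMap

__all__ = ["TrackingParams", "LinkResult", "Track", "link_frames",
           "repair_merge_split", "detect_mitosis", "build_tracks", "tracks_to_table"]


@dataclass
class TrackingParams:
    max_dist_px: float = 10.0               # NN gate; default 3x motion sigma, floor 10
    signal_tolerance: float = 0.25          # fractional H2B change allowed on a link
    division_signal_tolerance: float = 0.30 # tolerance on daughters' summed signal
    vicinity_px: float = 36.0               # daughter search radius (~4x nucleus radius)
    signal_col: str = "H2B_total"
    remerge_window_frames: int = 2          # spurious splits re-merge within this window


@dataclass
class LinkResult:
    """Assignment between two frames of observations (positional indices)."""

    matches: list[tuple[int, int]] = field(default_factory=list)
    flags: list[dict] = field(default_factory=list)
    unmatched_prev: list[int] = field(default_factory=list)
    unmatched_curr: list[int] = field(default_factory=list)


@dataclass
class Track:
    """One cell's ordered observations with lineage metadata."""

    track_id: int
    observations: pd.DataFrame          # includes a 'frame' column, strictly increasing
    parent_track_id: int | None = None
    division_frame: int | None = None
    end_reason: str = "movie_end"       # movie_end | lost | divided | left_field

    @property
    def first_frame(self) -> int:
        return int(self.observations["frame"].iloc[0])

    @property
    def last_frame(self) -> int:
        return int(self.observations["frame"].iloc[-1])

    @property
    def n_frames(self) -> int:
        return len(self.observations)


def _positions(df: pd.DataFrame) -> np.ndarray:
    return df[["y", "x"]].to_numpy(float)


def link_frames(prev: pd.DataFrame, curr: pd.DataFrame, max_dist_px: float = 10.0,
                signal_tolerance: float = 0.25, signal_col: str = "H2B_total") -> LinkResult:
    """Mutual-nearest-neighbour assignment between consecutive frames.

    Links whose total nuclear signal changes by more than
    ``signal_tolerance`` (as a fraction of the previous signal) are
    severed and flagged; merge/split candidates among the unmatched
    objects are flagged for :func:`repair_merge_split`. Unmatched
    current objects start new tracks; unmatched previous objects end.
    """
    if max_dist_px <= 0:
        raise ValueError("max_dist_px must be positive")
    res = LinkResult()
    if len(prev) == 0 or len(curr) == 0:
        res.unmatched_prev = list(range(len(prev)))
        res.unmatched_curr = list(range(len(curr)))
        return res
    ppos, cpos = _positions(prev), _positions(curr)
    ptree, ctree = cKDTree(ppos), cKDTree(cpos)
    d_pc, nn_pc = ctree.query(ppos)     # prev -> nearest curr
    _, nn_cp = ptree.query(cpos)        # curr -> nearest prev
    s_prev = prev[signal_col].to_numpy(float)
    s_curr = curr[signal_col].to_numpy(float)

    matched_prev, matched_curr = set(), set()
    candidates = []
    for i in range(len(prev)):
        j = int(nn_pc[i])
        if nn_cp[j] == i and d_pc[i] <= max_dist_px:
            candidates.append((d_pc[i], abs(s_curr[j] - s_prev[i]), i, j))
    # ties resolved by smallest distance, then smallest signal change, then index
    for _, _, i, j in sorted(candidates):
        if i in matched_prev or j in matched_curr:
            continue
        ratio = s_curr[j] / s_prev[i] if s_prev[i] > 0 else np.inf
        if abs(ratio - 1.0) > signal_tolerance:
            res.flags.append({"type": "signal", "prev": i, "curr": j, "ratio": float(ratio)})
            continue
        res.matches.append((i, j))
        matched_prev.add(i)
        matched_curr.add(j)
    res.unmatched_prev = [i for i in range(len(prev)) if i not in matched_prev]
    res.unmatched_curr = [j for j in range(len(curr)) if j not in matched_curr]

    # merge candidates: one unmatched curr whose signal ~ sum of two unmatched prev
    for j in res.unmatched_curr:
        near = [i for i in res.unmatched_prev
                if np.hypot(*(ppos[i] - cpos[j])) <= max_dist_px]
        if len(near) >= 2:
            best = None
            for a in range(len(near)):
                for b in range(a + 1, len(near)):
                    tot = s_prev[near[a]] + s_prev[near[b]]
                    err = abs(s_curr[j] / tot - 1.0) if tot > 0 else np.inf
                    if best is None or err < best[0]:
                        best = (err, near[a], near[b])
            if best is not None and best[0] <= signal_tolerance:
                res.flags.append({"type": "merge", "prev_pair": (best[1], best[2]),
                                  "curr": j, "ratio": float(s_curr[j] / (s_prev[best[1]] + s_prev[best[2]]))})
    # split candidates: one unmatched prev whose signal ~ sum of two unmatched curr
    for i in res.unmatched_prev:
        near = [j for j in res.unmatched_curr
                if np.hypot(*(ppos[i] - cpos[j])) <= max_dist_px]
        if len(near) >= 2:
            best = None
            for a in range(len(near)):
                for b in range(a + 1, len(near)):
                    tot = s_curr[near[a]] + s_curr[near[b]]
                    err = abs(tot / s_prev[i] - 1.0) if s_prev[i] > 0 else np.inf
                    if best is None or err < best[0]:
                        best = (err, near[a], near[b])
            if best is not None and best[0] <= signal_tolerance:
                res.flags.append({"type": "split", "prev": i,
                                  "curr_pair": (best[1], best[2])})
    return res


def repair_merge_split(
    result: LinkResult,
    prev: pd.DataFrame,
    curr: pd.DataFrame,
    mask: LabelMap | None = None,
    image: Image2D | np.ndarray | None = None,
    signal_col: str = "H2B_total",
):
    """Attempt to repair flagged segmentation merges on the current frame.

    For each merge flag, the merged object is re-split locally with the
    concavity-based splitter; if two fragments result they are measured
    on ``image`` and re-linked to the two lost tracks by proximity, and
    the merged observation is replaced. Irreparable flags are left as
    terminations. Returns (possibly modified) ``curr`` and an updated
    :class:`LinkResult`. Spurious-split flags are resolved later by the
    track builder, which can look ahead for the re-merge.
    """
    if mask is None or image is None:
        return curr, result
    channel = signal_col.rsplit("_", 1)[0]
    labels = mask.labels
    new_rows = []
    repaired = []
    for flag in result.flags:
        if flag["type"] != "merge":
            continue
        j = flag["curr"]
        lab = int(curr["label"].iloc[j])
        obj = labels == lab
        if not obj.any():
            continue
        sub = LabelMap((obj).astype(np.int32), pixel_size_um=mask.pixel_size_um)
        split = split_touching_nuclei(sub, reference_area_px=0.6 * obj.sum(),
                                      concavity_threshold=-0.08)
        if split.n_objects != 2:
            continue
        meas = measure_cells(image, split, background=0.0, channel=channel)
        if len(meas) != 2:
            continue
        i1, i2 = flag["prev_pair"]
        p1 = prev[["y", "x"]].iloc[i1].to_numpy(float)
        m_pos = meas[["y", "x"]].to_numpy(float)
        order = (0, 1) if np.hypot(*(m_pos[0] - p1)) <= np.hypot(*(m_pos[1] - p1)) else (1, 0)
        base = len(curr) + len(new_rows)
        for k, (prev_idx, frag) in enumerate(zip((i1, i2), order)):
            row = curr.iloc[j].copy()
            row["y"], row["x"] = meas["y"].iloc[frag], meas["x"].iloc[frag]
            row["area"] = meas["area"].iloc[frag]
            row[signal_col] = meas[f"{channel}_total"].iloc[frag]
            new_rows.append(row)
            result.matches.append((prev_idx, base + k))
        repaired.append(flag)
        result.unmatched_prev = [i for i in result.unmatched_prev if i not in (i1, i2)]
        result.unmatched_curr = [c for c in result.unmatched_curr if c != j]
    if new_rows:
        curr = pd.concat([curr, pd.DataFrame(new_rows)], ignore_index=True)
        result.flags = [f for f in result.flags if f not in repaired]
    return curr, result


def detect_mitosis(tracks: list[Track], vicinity_px: float = 36.0,
                   signal_tolerance: float = 0.30, signal_col: str = "H2B_total",
                   n_frames: int | None = None) -> list[dict]:
    """Assign parent/daughter lineage at candidate divisions.

    A division is recorded when a track ends at frame f, two tracks
    begin at frame f+1 within ``vicinity_px`` of its last centroid, and
    the daughters' summed total nuclear signal is within
    ``signal_tolerance`` of the parent's last signal. Modifies lineage
    fields in place and returns the division events.
    """
    if not 0 < signal_tolerance < 0.5:
        raise ValueError("signal_tolerance must be in (0, 0.5)")
    events = []
    starts_by_frame: dict[int, list[Track]] = {}
    for t in tracks:
        starts_by_frame.setdefault(t.first_frame, []).append(t)
    for parent in tracks:
        f = parent.last_frame
        if n_frames is not None and f >= n_frames - 1:
            continue
        if parent.division_frame is not None:
            continue
        cands = [t for t in starts_by_frame.get(f + 1, [])
                 if t.track_id != parent.track_id and t.parent_track_id is None]
        if len(cands) < 2:
            continue
        last = parent.observations.iloc[-1]
        p_pos = np.array([last["y"], last["x"]], float)
        p_sig = float(last[signal_col])
        near = [t for t in cands
                if np.hypot(t.observations["y"].iloc[0] - p_pos[0],
                            t.observations["x"].iloc[0] - p_pos[1]) <= vicinity_px]
        if len(near) < 2:
            continue
        best = None
        for a in range(len(near)):
            for b in range(a + 1, len(near)):
                tot = float(near[a].observations[signal_col].iloc[0]
                            + near[b].observations[signal_col].iloc[0])
                err = abs(tot / p_sig - 1.0) if p_sig > 0 else np.inf
                if best is None or err < best[0]:
                    best = (err, near[a], near[b])
        if best is None or best[0] > signal_tolerance:
            continue
        _, d1, d2 = best
        parent.division_frame = f
        parent.end_reason = "divided"
        d1.parent_track_id = parent.track_id
        d2.parent_track_id = parent.track_id
        events.append({"parent": parent.track_id, "frame": f,
                       "daughters": (d1.track_id, d2.track_id)})
    return events


def _remerge_spurious_splits(tracks: list[Track], params: TrackingParams) -> list[Track]:
    """Stitch tracks broken by a transient segmentation split.

    A spurious split leaves the pattern: track T ends at frame f-1; two
    sibling tracks U1, U2 exist for frames f..g (at most
    ``remerge_window_frames`` long, summed signal ~ T's); a track V
    resumes at g+1 with signal ~ T's near the same place. T, the merged
    U pair, and V are stitched into one track. Genuine daughters persist
    instead of re-merging, so divisions are untouched.
    """
    col = params.signal_col
    tol = params.signal_tolerance

    def last_pos(t: Track) -> np.ndarray:
        return t.observations[["y", "x"]].iloc[-1].to_numpy(float)

    def first_pos(t: Track) -> np.ndarray:
        return t.observations[["y", "x"]].iloc[0].to_numpy(float)

    changed = True
    while changed:
        changed = False
        by_start: dict[int, list[Track]] = {}
        for t in tracks:
            by_start.setdefault(t.first_frame, []).append(t)
        for t in tracks:
            f0 = t.last_frame + 1
            sibs = [u for u in by_start.get(f0, [])
                    if u.n_frames <= params.remerge_window_frames
                    and np.hypot(*(first_pos(u) - last_pos(t))) <= params.vicinity_px]
            if len(sibs) < 2:
                continue
            s_t = float(t.observations[col].iloc[-1])
            pair = None
            for a in range(len(sibs)):
                for b in range(a + 1, len(sibs)):
                    u1, u2 = sibs[a], sibs[b]
                    if u1.last_frame != u2.last_frame:
                        continue
                    s_sum = float(u1.observations[col].iloc[0]
                                  + u2.observations[col].iloc[0])
                    if s_t > 0 and abs(s_sum / s_t - 1.0) <= tol:
                        pair = (u1, u2)
                        break
                if pair:
                    break
            if pair is None:
                continue
            u1, u2 = pair
            g = u1.last_frame
            resume = [v for v in by_start.get(g + 1, [])
                      if v.track_id != t.track_id
                      and np.hypot(*(first_pos(v) - last_pos(u1))) <= params.vicinity_px
                      and s_t > 0
                      and abs(float(v.observations[col].iloc[0]) / s_t - 1.0) <= tol]
            if not resume:
                continue
            v = resume[0]
            merged_rows = []
            for fr in range(f0, g + 1):
                r1 = u1.observations[u1.observations["frame"] == fr]
                r2 = u2.observations[u2.observations["frame"] == fr]
                if len(r1) == 0 or len(r2) == 0:
                    break
                w1 = float(r1[col].iloc[0])
                w2 = float(r2[col].iloc[0])
                row = r1.iloc[0].to_dict()
                for c in ("y", "x"):
                    row[c] = (w1 * float(r1[c].iloc[0]) + w2 * float(r2[c].iloc[0])) / (w1 + w2)
                row[col] = w1 + w2
                if "area" in row:
                    row["area"] = r1["area"].iloc[0] + r2["area"].iloc[0]
                merged_rows.append(row)
            else:
                t.observations = pd.concat(
                    [t.observations, pd.DataFrame(merged_rows), v.observations],
                    ignore_index=True)
                t.end_reason = v.end_reason
                t.division_frame = v.division_frame
                tracks = [x for x in tracks
                          if x.track_id not in (u1.track_id, u2.track_id, v.track_id)]
                changed = True
                break
    return tracks


def build_tracks(
    frames: list[pd.DataFrame],
    params: TrackingParams | None = None,
    masks: list[LabelMap] | None = None,
    images: list[Image2D | np.ndarray] | None = None,
    border_margin_px: float = 12.0,
) -> list[Track]:
    """Link per-frame observations into lineage-resolved tracks.

    ``frames[t]`` holds the observations of frame t (columns at least
    y, x, area and the configured signal column). If ``masks`` and
    ``images`` are given, flagged segmentation merges are repaired by
    local re-splitting. Every observation ends up in exactly one track.
    """
    params = params or TrackingParams()
    n = len(frames)
    tracks: list[Track] = []
    next_id = [0]
    field_shape = None
    if masks is not None and len(masks):
        field_shape = masks[0].shape

    def start_track(frame: int, row: pd.Series) -> Track:
        t = Track(track_id=next_id[0],
                  observations=pd.DataFrame([{**row.to_dict(), "frame": frame}]))
        next_id[0] += 1
        tracks.append(t)
        return t

    active: dict[int, Track] = {}
    if n == 0:
        return []
    for _, row in frames[0].iterrows():
        t = start_track(0, row)
        active[t.track_id] = t
    for f in range(1, n):
        curr = frames[f].reset_index(drop=True)
        act_ids = sorted(active)
        prev = pd.DataFrame([active[i].observations.iloc[-1] for i in act_ids])
        res = link_frames(prev, curr, params.max_dist_px, params.signal_tolerance,
                          params.signal_col)
        if masks is not None and images is not None:
            curr, res = repair_merge_split(res, prev, curr, masks[f], images[f],
                                           params.signal_col)
        new_active: dict[int, Track] = {}
        matched_curr = set()
        for i, j in res.matches:
            tid = act_ids[i]
            tr = active[tid]
            row = curr.iloc[j].to_dict()
            row["frame"] = f
            tr.observations = pd.concat(
                [tr.observations, pd.DataFrame([row])], ignore_index=True)
            new_active[tid] = tr
            matched_curr.add(j)
        for tid in act_ids:
            if tid not in new_active:
                active[tid].end_reason = "lost"
        for j in range(len(curr)):
            if j not in matched_curr:
                t = start_track(f, curr.iloc[j])
                new_active[t.track_id] = t
        active = new_active
    for tr in active.values():
        tr.end_reason = "movie_end"

    tracks = _remerge_spurious_splits(tracks, params)
    detect_mitosis(tracks, params.vicinity_px, params.division_signal_tolerance,
                   params.signal_col, n_frames=n)
    if field_shape is not None:
        h, w = field_shape
        for tr in tracks:
            if tr.end_reason == "lost":
                last = tr.observations.iloc[-1]
                if (last["y"] < border_margin_px or last["x"] < border_margin_px
                        or last["y"] > h - border_margin_px or last["x"] > w - border_margin_px):
                    tr.end_reason = "left_field"
    return tracks


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    """Long-format table of all observations with track and lineage ids."""
    parts = []
    for t in tracks:
        df = t.observations.copy()
        df["track_id"] = t.track_id
        df["parent_track_id"] = -1 if t.parent_track_id is None else t.parent_track_id
        parts.append(df)
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)
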