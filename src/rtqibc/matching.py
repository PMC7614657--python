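"""RT-QIBC core: register fixed end-point images to the live movie, match
fixed cells to live tracks, and emit event-aligned fixed-cell records.

Fixed plates are often re-imaged at higher magnification and with a
small stage offset after plate replacement; registration recovers the
whole-field translation by 2D cross-correlation after bringing both
images to a common scale (bicubic upsampling of the live reference, or
mean-value binning of the fixed one). Each fixed cell is then assigned
to its nearest live-cell neighbour (greedy one-to-one, so a track gets
at most one fixed cell), and fixed measurements are re-indexed as time
since the track's annotated cell-cycle events, with per-site
acquisition-time offsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import block_reduce
from skimage.transform import rescale

from .events import TraceAnnotation
from .tracking import Track
from .types import Image2D

__all__ = ["AcquisitionSchedule", "register_translation", "match_fixed_to_live",
           "assign_acquisition_times", "align_staining_rounds", "assemble_records"]


def _as_array(img) -> np.ndarray:
    return img.data if isinstance(img, Image2D) else np.asarray(img, float)


def _xcorr_peak(a: np.ndarray, b: np.ndarray) -> tuple[tuple[int, int], float]:
    """Integer-pixel shift maximizing the circular cross-correlation of the
    zero-mean images, and the normalized peak coefficient."""
    a = a - a.mean()
    b = b - b.mean()
    fa = np.fft.rfft2(a)
    fb = np.fft.rfft2(b)
    corr = np.fft.irfft2(fa * np.conj(fb), s=a.shape)
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    denom = a.size * a.std() * b.std()
    coeff = float(corr[peak] / denom) if denom > 0 else 0.0
    dy, dx = peak
    if dy > a.shape[0] // 2:
        dy -= a.shape[0]
    if dx > a.shape[1] // 2:
        dx -= a.shape[1]
    return (int(dy), int(dx)), coeff


def register_translation(
    fixed_ref: Image2D | np.ndarray,
    live_ref: Image2D | np.ndarray,
    magnification_ratio: float = 1.0,
    strategy: str = "upsample_live",
    min_correlation: float = 0.1,
) -> tuple[int, int]:
    """Whole-field translation of the fixed image relative to the live one.

    Returns (dy, dx) in fixed-frame pixels such that fixed-frame
    coordinates are ``ratio * live + (dy, dx)``. ``strategy`` selects
    how the scales are reconciled: bicubic upsampling of the live image
    (``upsample_live``) or mean-value binning of the fixed image
    (``bin_fixed``, integer ratios only). Raises if the normalized
    correlation peak is below ``min_correlation`` (no overlap).
    """
    if magnification_ratio < 1:
        raise ValueError("magnification ratio must be >= 1")
    fixed = _as_array(fixed_ref)
    live = _as_array(live_ref)
    ratio = float(magnification_ratio)
    if strategy == "upsample_live":
        if ratio != 1.0:
            live = rescale(live, ratio, order=3, anti_aliasing=False, mode="edge")
        scale_back = 1.0
    elif strategy == "bin_fixed":
        k = int(round(ratio))
        if abs(ratio - k) > 1e-9:
            raise ValueError("bin_fixed requires an integer magnification ratio")
        if k > 1:
            fixed = block_reduce(fixed, (k, k), np.mean)
        scale_back = ratio
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    h = min(fixed.shape[0], live.shape[0])
    w = min(fixed.shape[1], live.shape[1])
    (dy, dx), coeff = _xcorr_peak(fixed[:h, :w], live[:h, :w])
    if coeff < min_correlation:
        raise ValueError(f"registration failed: peak correlation {coeff:.3f} below "
                         f"{min_correlation} (no overlap?)")
    return int(round(dy * scale_back)), int(round(dx * scale_back))


def match_fixed_to_live(
    fixed_centroids,
    live_centroids,
    offset: tuple[float, float] = (0.0, 0.0),
    magnification_ratio: float = 1.0,
    max_dist_px: float = 10.0,
) -> pd.DataFrame:
    """Greedy one-to-one nearest-neighbour assignment of fixed cells to live cells.

    Fixed centroids are mapped into live coordinates as
    ``(c - offset) / ratio``; pairs are accepted by ascending distance,
    each live cell receiving at most one fixed cell. Unmatched fixed
    cells are dropped; the count is in ``DataFrame.attrs['n_dropped']``.
    Distances (``match_distance_px``) are in live-frame pixels.
    """
    fixed = np.asarray(fixed_centroids, float).reshape(-1, 2)
    live = np.asarray(live_centroids, float).reshape(-1, 2)
    cols = ["fixed_index", "live_index", "match_distance_px"]
    if fixed.shape[0] == 0 or live.shape[0] == 0:
        out = pd.DataFrame(columns=cols)
        out.attrs["n_dropped"] = int(fixed.shape[0])
        return out
    mapped = (fixed - np.asarray(offset, float)) / float(magnification_ratio)
    from scipy.spatial import cKDTree

    tree = cKDTree(live)
    k = min(4, live.shape[0])
    dists, idxs = tree.query(mapped, k=k)
    dists = np.atleast_2d(dists.reshape(mapped.shape[0], -1))
    idxs = np.atleast_2d(idxs.reshape(mapped.shape[0], -1))
    cand = [(dists[i, j], i, int(idxs[i, j]))
            for i in range(mapped.shape[0]) for j in range(dists.shape[1])
            if dists[i, j] <= max_dist_px]
    cand.sort()
    taken_fixed: set[int] = set()
    taken_live: set[int] = set()
    rows = []
    for d, fi, li in cand:
        if fi in taken_fixed or li in taken_live:
            continue
        taken_fixed.add(fi)
        taken_live.add(li)
        rows.append({"fixed_index": fi, "live_index": li, "match_distance_px": float(d)})
    out = pd.DataFrame(rows, columns=cols)
    out.attrs["n_dropped"] = int(fixed.shape[0] - len(rows))
    return out


@dataclass
class AcquisitionSchedule:
    """Acquisition order of (well, site) positions within one frame cycle."""

    order: list[tuple[str, str]]
    frame_interval_min: float
    fixation_delay_min: float = 0.0

    def __post_init__(self) -> None:
        if not self.order:
            raise ValueError("schedule must list at least one position")
        if len(set(self.order)) != len(self.order):
            raise ValueError("duplicate positions in schedule")


def assign_acquisition_times(site_id: str, well_id: str,
                             schedule: AcquisitionSchedule) -> float:
    """Minutes offset of a site within the acquisition cycle.

    offset = (ordinal position of the site) / (total positions) x frame
    interval; the first position has offset 0.
    """
    key = (well_id, site_id)
    try:
        pos = schedule.order.index(key)
    except ValueError:
        raise KeyError(f"unknown acquisition position {key}") from None
    return pos / len(schedule.order) * schedule.frame_interval_min


def align_staining_rounds(round_dna_images, magnification_ratio: float = 1.0,
                          strategy: str = "upsample_live"):
    """Register each staining round's DNA image to round 1.

    Returns a list of per-round (dy, dx) offsets (round 1 is (0, 0));
    a round that fails to register yields None and its channels should
    be treated as null. The round-1 segmentation is the primary mask:
    quantify every round under it, shifted by the round's offset.
    """
    if len(round_dna_images) < 2:
        raise ValueError("need at least 2 rounds")
    ref = round_dna_images[0]
    offsets: list[tuple[int, int] | None] = [(0, 0)]
    for img in round_dna_images[1:]:
        try:
            offsets.append(register_translation(img, ref, magnification_ratio, strategy))
        except ValueError:
            offsets.append(None)
    return offsets


def assemble_records(
    fixed_table: pd.DataFrame,
    tracks: list[Track],
    annotations: dict[int, TraceAnnotation],
    assignment: pd.DataFrame,
    frame_interval_min: float,
    movie_end_min: float,
    site_id: str = "s1",
    well_id: str = "A1",
    schedule: AcquisitionSchedule | None = None,
) -> pd.DataFrame:
    """Join matched fixed cells with live tracks into event-aligned records.

    ``assignment`` maps ``fixed_index`` (positional row of
    ``fixed_table``) to ``live_index`` (positional index into
    ``tracks``). Derived times are (movie end + site offset + fixation
    delay) - event time; cells whose event was not annotated keep their
    measurements with null times. Output is sorted by
    (well, site, track_id) and each track appears at most once.
    """
    track_by_pos = {i: t for i, t in enumerate(tracks)}
    offset_min = 0.0
    delay = 0.0
    if schedule is not None:
        offset_min = assign_acquisition_times(site_id, well_id, schedule)
        delay = schedule.fixation_delay_min
    fix_time = movie_end_min + offset_min + delay
    rows = []
    for _, m in assignment.iterrows():
        li = int(m["live_index"])
        fi = int(m["fixed_index"])
        if li not in track_by_pos:
            raise KeyError(f"assignment references unknown live index {li}")
        if fi < 0 or fi >= len(fixed_table):
            raise KeyError(f"assignment references unknown fixed row {fi}")
        track = track_by_pos[li]
        ann = annotations.get(track.track_id)
        row = {"well_id": well_id, "site_id": site_id,
               "track_id": track.track_id, "fixed_cell_id": fi,
               "match_distance_px": float(m["match_distance_px"])}
        row.update(fixed_table.iloc[fi].to_dict())

        def ev_time(frame):
            return None if frame is None else frame * frame_interval_min

        events = {
            "anaphase": ev_time(ann.anaphase_frame) if ann else None,
            "s_entry": ev_time(ann.s_entry_frame) if ann else None,
            "apcc_inactivation": ev_time(ann.apcc_inactivation_frame) if ann else None,
        }
        for name, t_ev in events.items():
            row[f"{name}_min"] = np.nan if t_ev is None else t_ev
            row[f"time_since_{name}_min"] = np.nan if t_ev is None else fix_time - t_ev
        row["s_entry_source"] = ann.s_entry_source if ann else None
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        if out["track_id"].duplicated().any():
            raise ValueError("a live track received more than one fixed cell")
        out = out.sort_values(["well_id", "site_id", "track_id"]).reset_index(drop=True)
    return out
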