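"""End-to-end RT-QIBC orchestration on synthetic (or pre-loaded) data.

The full chain for one imaging site: simulate a population, render live
and fixed images, pass them through the camera model, flat-field
correct, segment and quantify every live frame, track nuclei, annotate
cell-cycle events, register and match the fixed snapshot to the final
live frame, and assemble event-aligned RT-QIBC records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correction import IlluminationProfile, ProfileSource, flatfield_correct
from .events import EventParams, TraceAnnotation, annotate_track
from .matching import (AcquisitionSchedule, assemble_records, match_fixed_to_live,
                       register_translation)
from .quantification import estimate_background, measure_cells, measure_puncta_area
from .segmentation import detect_nuclei_log, segment_fixed
from .synth import (SimConfig, apply_camera_model, illumination_profile_field,
                    render_fixed_snapshot, render_movie, simulate_population)
from .tracking import Track, TrackingParams, build_tracks
from .types import Image2D, LabelMap

__all__ = ["SiteResult", "default_tracking_params", "acquire_site", "analyze_live",
           "analyze_fixed", "run_rtqibc_site"]

LIVE_CHANNELS = ("H2B", "CRL4", "APCC", "PCNAFOCI")
FIXED_CHANNELS = ("DNA", "CDT1IF", "GMNNIF", "EDU", "NDCDT1IF")

#: puncta-area threshold series (top-hat counts) and the stringency index
#: used for the foci trace
FOCI_THRESHOLDS = (10.0, 20.0, 40.0)
FOCI_THRESHOLD_INDEX = 0
FOCI_INTERIOR_EROSION_PX = 2


@dataclass
class SiteResult:
    """Everything produced for one imaging site."""

    records: pd.DataFrame
    tracks: list[Track]
    annotations: dict[int, TraceAnnotation]
    truth: pd.DataFrame
    fixed_truth: pd.DataFrame
    registration_offset: tuple[int, int]
    config: SimConfig
    masks: list[LabelMap] = field(default_factory=list)
    fixed_mask: LabelMap | None = None


def default_tracking_params(config: SimConfig) -> TrackingParams:
    """Tracking defaults derived from the simulation config: NN gate of
    3x the motion sigma (floor 10 px), daughter vicinity of 4x the mean
    nucleus radius."""
    return TrackingParams(
        max_dist_px=max(3.0 * config.motion_sigma_px_per_frame, 10.0),
        vicinity_px=4.0 * config.mean_radius_px,
    )


def acquire_site(config: SimConfig, noise: bool = True,
                 magnification_ratio: float = 1.0,
                 fixed_offset_px: tuple[float, float] = (0.0, 0.0)):
    """Simulate, render, and pass through the camera model.

    Returns (cells, truth, raw_live, raw_fixed, fixed_truth) where the
    raw stacks are camera counts (offset + gain x signal + noise).
    """
    cells = simulate_population(config)
    stacks, truth = render_movie(cells, config)
    rng = np.random.default_rng((config.seed * 1_000_003 + 17) % (2**31))
    raw_live: dict[str, np.ndarray] = {}
    for ch in LIVE_CHANNELS:
        frames = []
        for f in range(config.n_frames):
            sources = {other: stacks[other][f] for other in LIVE_CHANNELS if other != ch}
            img = apply_camera_model(stacks[ch][f], config, channel=ch,
                                     sources=sources, noise=noise, rng=rng)
            frames.append(img.data)
        raw_live[ch] = np.stack(frames)
    fixed_imgs, fixed_truth = render_fixed_snapshot(cells, config, magnification_ratio,
                                                    fixed_offset_px)
    raw_fixed = {}
    for ch, img in fixed_imgs.items():
        sources = {other: fixed_imgs[other].data for other in FIXED_CHANNELS if other != ch}
        raw_fixed[ch] = apply_camera_model(img, config, channel=ch, sources=sources,
                                           noise=noise, rng=rng)
    return cells, truth, raw_live, raw_fixed, fixed_truth


def _profile_for(config: SimConfig, shape) -> IlluminationProfile:
    return IlluminationProfile(illumination_profile_field(config, shape),
                               camera_offset=config.camera.offset,
                               source=ProfileSource.PROVIDED)


def correct_live(raw_live: dict[str, np.ndarray], config: SimConfig) -> dict[str, np.ndarray]:
    """Flat-field correct all live channels with the acquisition profile."""
    shape = next(iter(raw_live.values())).shape[1:]
    profile = _profile_for(config, shape)
    out = {}
    for ch, stack in raw_live.items():
        out[ch] = np.stack([flatfield_correct(stack[f], profile).data
                            for f in range(stack.shape[0])])
    return out


def analyze_live(
    live: dict[str, np.ndarray],
    config: SimConfig,
    tracking_params: TrackingParams | None = None,
    event_params: EventParams | None = None,
):
    """Segment, quantify, track, and annotate a corrected live movie."""
    tracking_params = tracking_params or default_tracking_params(config)
    n_frames = live["H2B"].shape[0]
    px = config.pixel_size_um
    d_range = (2 * config.nucleus_radius_um[0] * 0.8, 2 * config.nucleus_radius_um[1] * 1.2)
    frames = []
    masks = []
    for f in range(n_frames):
        h2b = Image2D(live["H2B"][f], pixel_size_um=px, channel="H2B")
        mask = detect_nuclei_log(h2b, diameter_range_um=d_range)
        masks.append(mask)
        obs = measure_cells(h2b, mask, background=_safe_background(h2b, mask),
                            channel="H2B")
        for ch in ("CRL4", "APCC"):
            img = Image2D(live[ch][f], pixel_size_um=px, channel=ch)
            bg = _safe_background(img, mask)
            m = measure_cells(img, mask, background=bg, channel=ch)
            obs[f"{ch}_total"] = m[f"{ch}_total"].to_numpy()
        foci = measure_puncta_area(live["PCNAFOCI"][f], mask,
                                   tophat_radius_px=2, thresholds=FOCI_THRESHOLDS,
                                   interior_erosion_px=FOCI_INTERIOR_EROSION_PX)
        col = foci[f"area_thr{FOCI_THRESHOLD_INDEX}"]
        obs["PCNAFOCI_area"] = obs["label"].map(col).fillna(0).to_numpy()
        frames.append(obs)
    tracks = build_tracks(frames, tracking_params, masks=masks,
                          images=[live["H2B"][f] for f in range(n_frames)])
    annotations = {t.track_id: annotate_track(t, params=event_params) for t in tracks}
    return tracks, annotations, masks, frames


def _safe_background(img: Image2D, mask: LabelMap, dilation_um: float = 7.8) -> float:
    try:
        return estimate_background(img, mask, dilation_um)
    except ValueError:
        return 0.0


def analyze_fixed(fixed: dict[str, Image2D], config: SimConfig, min_area_px: int = 50):
    """Segment the DNA stain and quantify all fixed channels under it."""
    mask = segment_fixed(fixed["DNA"], min_area_px=min_area_px)
    table = None
    for ch in FIXED_CHANNELS:
        if ch not in fixed:
            continue
        bg = _safe_background(fixed[ch], mask)
        m = measure_cells(fixed[ch], mask, background=bg, channel=ch)
        if table is None:
            table = m
        else:
            for col in (f"{ch}_total", f"{ch}_mean", f"{ch}_median"):
                table[col] = m[col].to_numpy()
    return mask, table


def run_rtqibc_site(
    config: SimConfig,
    noise: bool = True,
    magnification_ratio: float = 1.0,
    fixed_offset_px: tuple[float, float] = (0.0, 0.0),
    site_id: str = "s1",
    well_id: str = "A1",
    schedule: AcquisitionSchedule | None = None,
    tracking_params: TrackingParams | None = None,
    event_params: EventParams | None = None,
    match_max_dist_px: float | None = None,
) -> SiteResult:
    """Run the full RT-QIBC chain on one synthetic site."""
    cells, truth, raw_live, raw_fixed, fixed_truth = acquire_site(
        config, noise=noise, magnification_ratio=magnification_ratio,
        fixed_offset_px=fixed_offset_px)
    live = correct_live(raw_live, config)
    fixed_profile = IlluminationProfile(
        illumination_profile_field(config, raw_fixed["DNA"].shape),
        camera_offset=config.camera.offset, source=ProfileSource.PROVIDED)
    fixed = {ch: flatfield_correct(img, fixed_profile) for ch, img in raw_fixed.items()}

    tracks, annotations, masks, _ = analyze_live(live, config, tracking_params,
                                                 event_params)
    fixed_mask, fixed_table = analyze_fixed(fixed, config)

    live_ref = live["H2B"][-1]
    offset = register_translation(fixed["DNA"], live_ref, magnification_ratio,
                                  strategy="upsample_live")
    end_tracks = [t for t in tracks if t.last_frame == config.n_frames - 1]
    live_cents = np.array([[t.observations["y"].iloc[-1], t.observations["x"].iloc[-1]]
                           for t in end_tracks]).reshape(-1, 2)
    fixed_cents = fixed_table[["y", "x"]].to_numpy(float)
    max_dist = match_max_dist_px if match_max_dist_px is not None else config.mean_radius_px
    assignment = match_fixed_to_live(fixed_cents, live_cents, offset=offset,
                                     magnification_ratio=magnification_ratio,
                                     max_dist_px=max_dist)
    records = assemble_records(fixed_table, end_tracks, annotations, assignment,
                               frame_interval_min=config.frame_interval_min,
                               movie_end_min=config.movie_length_min,
                               site_id=site_id, well_id=well_id, schedule=schedule)
    return SiteResult(records=records, tracks=tracks, annotations=annotations,
                      truth=truth, fixed_truth=fixed_truth,
                      registration_offset=offset, config=config, masks=masks,
                      fixed_mask=fixed_mask)
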