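"""Cell-cycle event detection on per-track reporter traces.

Three detectors operate on per-cell time series of integrated nuclear
reporter intensity (or PCNA foci area):

* drop onset — the start of CRL4^Cdt2-mediated reporter degradation
  (S-phase entry) found where the normalized trace has a sufficiently
  negative slope, a convex kink, and a minimum fractional drop over a
  *fixed* look-ahead window. Using a fixed window keeps the detection
  latency independent of how long before fixation the drop happened, so
  cells that entered S just before fixation are not under-called.
* rise onset — APC/C^Cdh1 inactivation, the first point where the
  forward slope exceeds a threshold from a low level and the trace
  subsequently rises persistently.
* dual-threshold foci onset — S entry from the PCNA foci-area trace:
  the first frame whose area exceeds a high threshold (50 px) and all
  of the previous 4 frames, backtracked to the last preceding frame
  below a low threshold (3 px).

Default slope/curvature thresholds were calibrated on the synthetic
benchmark; they are configuration, not constants of nature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracking import Track

__all__ = ["EventParams", "TraceAnnotation", "detect_drop_onset", "detect_rise_onset",
           "detect_s_entry_foci", "annotate_track"]


@dataclass
class EventParams:
    window_frames: int = 3
    slope_max: float = -0.03            # /frame, on the normalized trace
    curvature_min: float = 0.01         # /frame^2, second central difference
    min_drop_frac: float = 0.10
    rise_slope_min: float = 0.01        # /frame, normalized
    rise_low_level_max: float = 0.10
    rise_persist_level: float = 0.25
    foci_high_px: float = 50.0
    foci_low_px: float = 3.0
    foci_lookback: int = 4
    # use the rise detector when the dual-threshold rule finds nothing
    # (e.g. wide-field data where foci never cross the high threshold);
    # off by default: an S entry too recent to cross the high threshold
    # is not identifiable, and a late-movie rise call would be biased
    foci_fallback_rise: bool = False


@dataclass
class TraceAnnotation:
    """Per-track event frames (and minutes, once converted by the matcher)."""

    track_id: int
    anaphase_frame: int | None = None
    crl4_activation_frame: int | None = None
    apcc_inactivation_frame: int | None = None
    s_entry_frame: int | None = None
    s_entry_source: str | None = None   # 'crl4_reporter' | 'pcna_foci'
    times_min: dict = field(default_factory=dict)


def _window_slope(v: np.ndarray, t: int, w: int) -> float:
    """Least-squares slope of v over frames [t, t+w]."""
    y = v[t : t + w + 1]
    x = np.arange(y.size, dtype=float)
    x -= x.mean()
    return float(np.dot(x, y - y.mean()) / np.dot(x, x))


def detect_drop_onset(
    trace,
    search_start: int = 0,
    window_frames: int = 3,
    slope_max: float = -0.03,
    curvature_min: float = 0.01,
    min_drop_frac: float = 0.10,
) -> int | None:
    """Earliest degradation-onset frame on a reporter trace, or None.

    The trace is normalized per cell to its peak after ``search_start``
    (the reporter expression level) so thresholds are independent of
    expression. A frame t qualifies when, over the fixed window
    [t, t + window_frames]: the fitted slope is at most ``slope_max``,
    the second central difference at t is at least ``curvature_min``
    (convex kink into the decay), and the normalized decrease across the
    window is at least ``min_drop_frac``.
    """
    trace = np.asarray(trace, float)
    n = trace.size
    if n < search_start + window_frames + 1:
        return None
    # normalize to reporter expression (the trace peak); a rising trace's
    # small early values then cannot trigger spurious relative drops
    peak = float(np.max(trace[search_start:]))
    if peak <= 0:
        return None
    v = trace / peak
    for t in range(max(search_start, 1), n - window_frames):
        if _window_slope(v, t, window_frames) > slope_max:
            continue
        curvature = v[t + 1] - 2.0 * v[t] + v[t - 1]
        if curvature < curvature_min:
            continue
        if v[t] - v[t + window_frames] < min_drop_frac:
            continue
        return t
    return None


def detect_rise_onset(
    trace,
    search_start: int = 0,
    window_frames: int = 3,
    slope_min: float = 0.01,
    low_level_max: float = 0.10,
    persist_level: float = 0.25,
) -> int | None:
    """Earliest accumulation-onset frame (APC/C inactivation), or None.

    The trace is normalized to its maximum after ``search_start``. A
    frame qualifies when the forward fitted slope reaches ``slope_min``
    from a level at most ``low_level_max``, and the trace afterwards
    reaches ``persist_level`` without first returning below
    ``low_level_max`` (rejects transient blips).
    """
    trace = np.asarray(trace, float)
    n = trace.size
    if n < search_start + window_frames + 1:
        return None
    mx = np.max(trace[search_start:])
    if mx <= 0:
        return None
    v = trace / mx

    def qualifies(t: int) -> bool:
        return (v[t] <= low_level_max
                and _window_slope(v, t, window_frames) >= slope_min)

    for t in range(search_start, n - window_frames):
        if not qualifies(t):
            continue
        persistent = False
        for u in range(t + 1, n):
            if v[u] >= persist_level:
                persistent = True
                break
            if v[u] < low_level_max and u > t + window_frames:
                break
        if not persistent:
            continue
        # the forward window makes the first qualifying frame precede the
        # actual kink; advance through the remaining flat frames (stop as
        # soon as the per-frame increment shows the rise has begun)
        while (t + 1 < n - window_frames and qualifies(t + 1)
               and v[t + 1] - v[t] < slope_min):
            t += 1
        return t
    return None


def detect_s_entry_foci(
    foci_area,
    high_thresh_px: float = 50.0,
    low_thresh_px: float = 3.0,
    lookback_frames: int = 4,
) -> int | None:
    """S-entry frame from a PCNA foci-area trace via the dual-threshold rule.

    Finds the first frame h with area above ``high_thresh_px`` that also
    exceeds each of the previous ``lookback_frames`` values, then
    returns the last frame before h whose area is below
    ``low_thresh_px``; None if no frame qualifies.
    """
    if low_thresh_px >= high_thresh_px:
        raise ValueError("low threshold must be below high threshold")
    a = np.asarray(foci_area, float)
    for h in range(a.size):
        if a[h] <= high_thresh_px:
            continue
        lo = max(h - lookback_frames, 0)
        if h > 0 and not np.all(a[h] > a[lo:h]):
            continue
        below = np.flatnonzero(a[:h] < low_thresh_px)
        if below.size:
            return int(below[-1])
        return None
    return None


def annotate_track(
    track: Track,
    channel_map: dict[str, str] | None = None,
    params: EventParams | None = None,
) -> TraceAnnotation:
    """Annotate one track's cell-cycle events from its reporter traces.

    ``channel_map`` maps roles to observation columns, e.g.
    ``{"crl4": "CRL4_total", "apcc": "APCC_total", "foci": "PCNAFOCI_area"}``.
    Integrated (total) nuclear intensity is used for the CRL4 and APC/C
    reporters. S entry comes from the foci trace when available (falling
    back to the rise detector if the dual-threshold rule finds nothing),
    otherwise from the CRL4 drop. Anaphase is the track's first frame
    when a parent track is linked. Missing channels yield None for the
    corresponding events.
    """
    params = params or EventParams()
    channel_map = channel_map or {"crl4": "CRL4_total", "apcc": "APCC_total",
                                  "foci": "PCNAFOCI_area"}
    obs = track.observations
    frames = obs["frame"].to_numpy(int)
    ann = TraceAnnotation(track_id=track.track_id)
    if track.parent_track_id is not None:
        ann.anaphase_frame = int(frames[0])

    def col(role):
        name = channel_map.get(role)
        return obs[name].to_numpy(float) if name and name in obs.columns else None

    crl4 = col("crl4")
    if crl4 is not None:
        # skip the immediate post-mitotic frames where the reporter is still low
        idx = detect_drop_onset(crl4, search_start=1,
                                window_frames=params.window_frames,
                                slope_max=params.slope_max,
                                curvature_min=params.curvature_min,
                                min_drop_frac=params.min_drop_frac)
        if idx is not None:
            ann.crl4_activation_frame = int(frames[idx])
    apcc = col("apcc")
    if apcc is not None:
        idx = detect_rise_onset(apcc, search_start=0,
                                window_frames=params.window_frames,
                                slope_min=params.rise_slope_min,
                                low_level_max=params.rise_low_level_max,
                                persist_level=params.rise_persist_level)
        if idx is not None:
            ann.apcc_inactivation_frame = int(frames[idx])
    foci = col("foci")
    s_idx = None
    if foci is not None:
        s_idx = detect_s_entry_foci(foci, params.foci_high_px, params.foci_low_px,
                                    params.foci_lookback)
        if s_idx is None and params.foci_fallback_rise:
            # foci-area rises like the APC/C reporter; reuse the rise detector
            s_idx = detect_rise_onset(foci, search_start=0,
                                      window_frames=params.window_frames,
                                      slope_min=params.rise_slope_min,
                                      low_level_max=params.rise_low_level_max,
                                      persist_level=params.rise_persist_level)
        if s_idx is not None:
            ann.s_entry_frame = int(frames[s_idx])
            ann.s_entry_source = "pcna_foci"
    if ann.s_entry_frame is None and ann.crl4_activation_frame is not None:
        ann.s_entry_frame = ann.crl4_activation_frame
        ann.s_entry_source = "crl4_reporter"
    return ann
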