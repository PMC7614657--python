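"""Per-cell signal extraction.

Background is the 25th percentile of pixels outside the nuclear mask
dilated by 7.8 um (nuclear signals) or 15.6 um (signals with a
cytoplasmic component). Per nucleus, the mean/median/total
background-subtracted intensity is measured; for cytoplasmic signals a
ring median 0.65-3.25 um outside the nuclear edge gives the
cytoplasm-to-nucleus ratio used as the cyclin E/A-CDK activity readout.
Puncta area (e.g. PCNA foci) is the count of top-hat-filtered pixels
above a chosen threshold. Staining-round utilities remove incompletely
extracted cells, subtract residual signal from a previous staining
round, and normalize by a co-expressed marker.

Cell observations are returned as a :class:`pandas.DataFrame` with one
row per nucleus (columns: label, y, x, area plus per-channel
statistics); frames of observations are the tracking module's input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk, white_tophat

from .types import Image2D, LabelMap

__all__ = [
    "estimate_background",
    "measure_cells",
    "measure_puncta_area",
    "filter_extraction_artifacts",
    "correct_round_residual",
    "normalize_by_coexpressed_marker",
]


def _as_array(img) -> np.ndarray:
    return img.data if isinstance(img, Image2D) else np.asarray(img, float)


def estimate_background(image: Image2D | np.ndarray, mask: LabelMap,
                        dilation_um: float = 7.8) -> float:
    """25th percentile of pixels outside the dilated nuclear mask.

    By convention ``dilation_um`` is 7.8 um for predominantly nuclear
    signals and 15.6 um for signals with cytoplasmic components.
    """
    arr = _as_array(image)
    if arr.shape != mask.shape:
        raise ValueError("image/mask shape mismatch")
    r = int(round(dilation_um / mask.pixel_size_um))
    fg = mask.labels > 0
    if r > 0 and fg.any():
        fg = ndimage.binary_dilation(fg, structure=disk(r))
    outside = arr[~fg]
    if outside.size == 0:
        raise ValueError("no pixels outside the dilated mask; cannot estimate background")
    return float(np.percentile(outside, 25))


def measure_cells(
    image: Image2D | np.ndarray,
    mask: LabelMap,
    background: float = 0.0,
    ring_um: tuple[float, float] | None = None,
    channel: str = "signal",
) -> pd.DataFrame:
    """Per-nucleus intensity statistics, optionally with a cytoplasmic ring.

    Returns a DataFrame indexed by row with columns ``label, y, x, area,
    {channel}_total, {channel}_mean, {channel}_median`` and, if
    ``ring_um`` is given, ``{channel}_ring_median`` and ``cdk_activity``
    (ring median / nuclear median). Ring pixels lie between dilations of
    the nucleus by the inner and outer radii, excluding pixels within
    the inner dilation of *any* nucleus; contested pixels go to the
    nearest nucleus, so no ring pixel is shared between cells.
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    arr = _as_array(image) - background
    labels = mask.labels
    if arr.shape != labels.shape:
        raise ValueError("image/mask shape mismatch")
    ids = mask.ids
    if ids.size == 0:
        return pd.DataFrame(columns=["label", "y", "x", "area",
                                     f"{channel}_total", f"{channel}_mean",
                                     f"{channel}_median"])
    idx = ids
    count = ndimage.sum_labels(np.ones_like(arr), labels, index=idx)
    total = ndimage.sum_labels(arr, labels, index=idx)
    mean = total / count
    median = ndimage.labeled_comprehension(arr, labels, idx, np.median, float, np.nan)
    cy = ndimage.sum_labels(np.indices(arr.shape)[0], labels, index=idx) / count
    cx = ndimage.sum_labels(np.indices(arr.shape)[1], labels, index=idx) / count
    out = pd.DataFrame({
        "label": idx.astype(int), "y": cy, "x": cx, "area": count.astype(int),
        f"{channel}_total": total, f"{channel}_mean": mean, f"{channel}_median": median,
    })

    if ring_um is not None:
        inner_um, outer_um = ring_um
        if not 0 < inner_um < outer_um:
            raise ValueError("ring bounds must satisfy 0 < inner < outer")
        inner = max(int(round(inner_um / mask.pixel_size_um)), 1)
        outer = max(int(round(outer_um / mask.pixel_size_um)), inner + 1)
        bg_zone = labels == 0
        dist, (iy, ix) = ndimage.distance_transform_edt(bg_zone, return_indices=True)
        owner = labels[iy, ix]  # nearest nucleus for every background pixel
        ring_zone = (dist > inner) & (dist <= outer)
        ring_med = np.full(idx.size, np.nan)
        if ring_zone.any():
            ring_owner = owner[ring_zone]
            ring_vals = arr[ring_zone]
            order = np.argsort(ring_owner, kind="stable")
            ring_owner, ring_vals = ring_owner[order], ring_vals[order]
            bounds = np.searchsorted(ring_owner, np.concatenate([idx, [idx[-1] + 1]]))
            for k in range(idx.size):
                seg = ring_vals[bounds[k]:bounds[k + 1]]
                if seg.size:
                    ring_med[k] = np.median(seg)
        out[f"{channel}_ring_median"] = ring_med
        nuc_med = out[f"{channel}_median"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            cdk = np.where(nuc_med > 0, ring_med / nuc_med, np.nan)
        out["cdk_activity"] = cdk
    return out


def measure_puncta_area(
    image: Image2D | np.ndarray,
    mask: LabelMap,
    tophat_radius_px: int = 2,
    thresholds: tuple[float, ...] = (10.0, 20.0, 40.0),
    interior_erosion_px: int = 0,
) -> pd.DataFrame:
    """Per-nucleus puncta area at a series of threshold stringencies.

    A morphological white top-hat (radius 2 px for wide-field, 3 px for
    confocal) isolates punctate structure inside each nucleus; puncta
    area is the count of top-hat pixels above each threshold. With
    ``interior_erosion_px`` > 0 pixels within that distance of the
    nuclear boundary are excluded, which suppresses spillover from foci
    of a touching neighbour. Returns a DataFrame indexed by ``label``
    with one ``area_thr{i}`` column per threshold; areas are monotone
    non-increasing in threshold.
    """
    if tophat_radius_px < 1:
        raise ValueError("tophat radius must be >= 1 px")
    thresholds = tuple(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    arr = _as_array(image)
    labels = mask.labels
    if interior_erosion_px > 0:
        foot = disk(interior_erosion_px)
        lo = ndimage.grey_erosion(labels, footprint=foot)
        hi = ndimage.grey_dilation(labels, footprint=foot)
        labels = np.where((lo == labels) & (hi == labels), labels, 0)
    filtered = white_tophat(arr, footprint=disk(tophat_radius_px))
    filtered = np.where(labels > 0, filtered, 0.0)
    ids = mask.ids
    data = {"label": ids.astype(int)}
    for i, thr in enumerate(thresholds):
        above = (filtered > thr).astype(float)
        data[f"area_thr{i}"] = ndimage.sum_labels(above, labels, index=ids).astype(int)
    return pd.DataFrame(data).set_index("label")


def filter_extraction_artifacts(records: pd.DataFrame, soluble_signal,
                                gate: float) -> pd.DataFrame:
    """Remove incompletely pre-extracted cells.

    Cells whose residual soluble-reporter signal exceeds ``gate``
    (derived from control cells) are dropped; the removal count is
    attached as ``DataFrame.attrs['n_removed_extraction']``.
    """
    soluble = np.asarray(soluble_signal, float)
    if soluble.shape[0] != len(records):
        raise ValueError("soluble_signal length mismatch")
    keep = ~(soluble > gate)
    out = records.loc[keep].copy()
    out.attrs["n_removed_extraction"] = int((~keep).sum())
    return out


def correct_round_residual(round2, round1, scale: float) -> np.ndarray:
    """Subtract residual first-round staining: round2 - scale * round1, floored at 0."""
    if scale < 0:
        raise ValueError("scale must be >= 0")
    a = np.asarray(round2, float)
    b = np.asarray(round1, float)
    if a.shape != b.shape:
        raise ValueError("length mismatch between rounds")
    return np.maximum(a - scale * b, 0.0)


def normalize_by_coexpressed_marker(values, marker_values) -> np.ndarray:
    """Element-wise ratio to a co-expressed marker (e.g. H2B from a P2A
    construct); cells with non-positive marker get NaN."""
    v = np.asarray(values, float)
    m = np.asarray(marker_values, float)
    if v.shape != m.shape:
        raise ValueError("length mismatch")
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(m > 0, v / m, np.nan)
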