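"""Rendering of simulated populations into images.

Nuclei are drawn as isotropic Gaussian blobs truncated at 2.5 sigma
(sigma = radius / 2.5), normalized so that the integrated blob intensity
equals the cell's trace value for that channel and frame — integrated
H2B intensity is therefore conserved across frames and split ~equally at
division. The PCNA-foci channel adds punctate spots (fixed per-cell
positions) inside S-phase nuclei on top of a dim nuclear haze. The
camera model is *not* applied here; see :mod:`rtqibc.synth.camera`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..types import Image2D
from .config import SimConfig
from .population import GroundTruthCell, population_table

__all__ = ["render_movie", "render_fixed_snapshot", "FOCI_SPOT_SIGMA_PX",
           "FOCI_SPOT_AMPLITUDE", "FOCI_PX_PER_SPOT"]

LIVE_CHANNELS = ("H2B", "CRL4", "APCC", "PCNAFOCI")
FIXED_CHANNELS = ("DNA", "CDT1IF", "GMNNIF", "EDU", "NDCDT1IF")

FOCI_SPOT_SIGMA_PX = 1.0
FOCI_SPOT_AMPLITUDE = 100.0
#: approximate rendered above-threshold footprint of one focus, px
FOCI_PX_PER_SPOT = 7.0


def _add_blob(img: np.ndarray, y: float, x: float, radius_px: float, total: float) -> None:
    """Add a truncated-Gaussian nucleus of integrated intensity ``total``."""
    if total <= 0:
        return
    sigma = radius_px / 2.5
    r = int(np.ceil(radius_px))
    h, w = img.shape
    y0, y1 = max(int(np.floor(y)) - r, 0), min(int(np.floor(y)) + r + 2, h)
    x0, x1 = max(int(np.floor(x)) - r, 0), min(int(np.floor(x)) + r + 2, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - y) ** 2 + (xx - x) ** 2
    kern = np.exp(-d2 / (2.0 * sigma**2))
    kern[d2 > radius_px**2] = 0.0
    # normalize over the full (untruncated-by-border) kernel so intensity is
    # conserved for nuclei away from the field edge
    norm = 2.0 * np.pi * sigma**2 * (1.0 - np.exp(-radius_px**2 / (2.0 * sigma**2)))
    img[y0:y1, x0:x1] += total * kern / norm


def _add_spot(img: np.ndarray, y: float, x: float, sigma: float, amplitude: float) -> None:
    r = int(np.ceil(3 * sigma))
    h, w = img.shape
    y0, y1 = max(int(np.floor(y)) - r, 0), min(int(np.floor(y)) + r + 2, h)
    x0, x1 = max(int(np.floor(x)) - r, 0), min(int(np.floor(x)) + r + 2, w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))


def render_movie(cells: list[GroundTruthCell], config: SimConfig):
    """Render per-channel live frame stacks plus the ground-truth table.

    Returns
    -------
    (stacks, truth) where ``stacks`` maps channel name (H2B, CRL4, APCC,
    PCNAFOCI) to a float array of shape (n_frames, H, W) and ``truth``
    is the per-cell ground-truth DataFrame.
    """
    h, w = config.field_size_px
    stacks = {ch: np.zeros((config.n_frames, h, w)) for ch in LIVE_CHANNELS}
    for cell in cells:
        for i, f in enumerate(cell.frames):
            y, x = cell.centroids[i]
            for ch in ("H2B", "CRL4", "APCC"):
                _add_blob(stacks[ch][f], y, x, cell.radius_px, cell.traces[ch][i])
            area = cell.traces["PCNAFOCI"][i]
            # dim nuclear haze so the nucleus is visible in the PCNA channel
            _add_blob(stacks["PCNAFOCI"][f], y, x, cell.radius_px, 0.01 * cell.h2b_total)
            if area > 0 and cell.foci_offsets is not None:
                n_active = min(int(round(area / FOCI_PX_PER_SPOT)), len(cell.foci_offsets))
                for dy, dx in cell.foci_offsets[:n_active]:
                    _add_spot(stacks["PCNAFOCI"][f], y + dy, x + dx,
                              FOCI_SPOT_SIGMA_PX, FOCI_SPOT_AMPLITUDE)
    return stacks, population_table(cells)


def render_true_labelmap(cells: list[GroundTruthCell], config: SimConfig,
                         frame: int) -> np.ndarray:
    """Ground-truth label map at one live frame: each nucleus is the disk of
    its true radius at its true centroid, labelled by cell_id + 1 (ties at
    overlaps go to the nearer centroid)."""
    h, w = config.field_size_px
    labels = np.zeros((h, w), np.int32)
    dist = np.full((h, w), np.inf)
    for cell in cells:
        idx = np.flatnonzero(cell.frames == frame)
        if not idx.size:
            continue
        y, x = cell.centroids[idx[0]]
        r = cell.radius_px
        ri = int(np.ceil(r))
        y0, y1 = max(int(y) - ri, 0), min(int(y) + ri + 2, h)
        x0, x1 = max(int(x) - ri, 0), min(int(x) + ri + 2, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (yy - y) ** 2 + (xx - x) ** 2
        inside = (d2 <= r**2) & (d2 < dist[y0:y1, x0:x1])
        labels[y0:y1, x0:x1][inside] = cell.cell_id + 1
        dist[y0:y1, x0:x1][inside] = d2[inside]
    return labels


def render_fixed_snapshot(
    cells: list[GroundTruthCell],
    config: SimConfig,
    magnification_ratio: float = 1.0,
    offset_px: tuple[float, float] = (0.0, 0.0),
):
    """Render the end-point fixed-cell snapshot at the final movie time.

    The fixed plate may be imaged at higher magnification (e.g. 20x fixed
    vs 10x live, ``magnification_ratio = 2``) and with a whole-field
    translation from replacing the plate on the microscope: fixed-frame
    coordinates are ``ratio * live + offset_px`` (offset in fixed px).

    Returns
    -------
    (images, truth) where ``images`` maps channel name (DNA, CDT1IF,
    GMNNIF, EDU, NDCDT1IF) to :class:`Image2D` at pixel size
    ``config.pixel_size_um / ratio`` and ``truth`` is a per-cell table
    including fixed-frame centroids.
    """
    if magnification_ratio < 1:
        raise ValueError("magnification ratio must be >= 1")
    ratio = float(magnification_ratio)
    dy, dx = offset_px
    h, w = config.field_size_px
    fh, fw = int(round(h * ratio)), int(round(w * ratio))
    px_um = config.pixel_size_um / ratio
    imgs = {ch: np.zeros((fh, fw)) for ch in FIXED_CHANNELS}
    rows = []
    last_frame = config.n_frames - 1
    for cell in cells:
        if cell.frames[-1] != last_frame:
            continue  # divided or left before fixation
        y, x = cell.centroids[-1]
        fy, fx = ratio * y + dy, ratio * x + dx
        r_fixed = cell.radius_px * ratio
        for ch in FIXED_CHANNELS:
            _add_blob(imgs[ch], fy, fx, r_fixed, cell.traces[ch][-1])
        rows.append({
            "cell_id": cell.cell_id,
            "live_y": y, "live_x": x,
            "fixed_y": fy, "fixed_x": fx,
            "radius_px_fixed": r_fixed,
            "anaphase_time": cell.anaphase_time,
            "apcc_inactivation_time": cell.apcc_inactivation_time,
            "s_entry_time": cell.s_entry_time,
            "cdt1_fully_degraded_time": cell.cdt1_fully_degraded_time,
            "in_s_at_movie_end": cell.in_s_at_movie_end,
            "ndcdt1": cell.ndcdt1,
            "edu": cell.edu,
            **{f"true_{ch}": cell.traces[ch][-1] for ch in FIXED_CHANNELS},
        })
    images = {ch: Image2D(arr, pixel_size_um=px_um, channel=ch) for ch, arr in imgs.items()}
    return images, pd.DataFrame(rows)
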