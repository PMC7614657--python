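"""Flat-field (shading) and spectral bleedthrough correction.

Raw camera frames are ``offset + gain * signal``; correction subtracts
the camera offset and divides by an empirically determined illumination
profile. The profile is estimated either from background
autofluorescence in cell-free areas aggregated over many sites
(``background_aggregate``) or from sample-free blank wells
(``blank_well``). Confocal acquisitions, which have no appreciable
shading, can skip flat-field correction via a per-channel flag in the
pipeline configuration.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import Image2D, LabelMap

__all__ = [
    "ProfileSource",
    "IlluminationProfile",
    "estimate_illumination",
    "flatfield_correct",
    "correct_bleedthrough",
]


class ProfileSource(enum.Enum):
    BACKGROUND_AGGREGATE = "background_aggregate"
    BLANK_WELL = "blank_well"
    PROVIDED = "provided"


@dataclass
class IlluminationProfile:
    """Unitless illumination gain field (mean ~1) plus the camera offset."""

    profile: np.ndarray
    camera_offset: float
    source: ProfileSource = ProfileSource.PROVIDED

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, float)
        if np.any(self.profile <= 0):
            raise ValueError("illumination profile must be strictly positive")

    def save(self, tiff_path, json_path) -> None:
        import tifffile

        tifffile.imwrite(tiff_path, self.profile.astype(np.float32))
        with open(json_path, "w") as fh:
            json.dump({"camera_offset": self.camera_offset, "source": self.source.value}, fh)

    @classmethod
    def load(cls, tiff_path, json_path) -> "IlluminationProfile":
        import tifffile

        with open(json_path) as fh:
            meta = json.load(fh)
        return cls(tifffile.imread(tiff_path), meta["camera_offset"],
                   ProfileSource(meta["source"]))


def _as_array(img) -> np.ndarray:
    return img.data if isinstance(img, Image2D) else np.asarray(img, float)


def estimate_illumination(
    images,
    foreground_masks=None,
    method: ProfileSource = ProfileSource.BACKGROUND_AGGREGATE,
    camera_offset: float | None = None,
    smoothing_sigma_frac: float = 0.05,
    mask_dilation_px: int = 5,
    min_images: int = 10,
    min_coverage: float = 0.5,
) -> IlluminationProfile:
    """Estimate the illumination profile from a stack of raw images.

    For ``background_aggregate``, pixels under any (dilated) foreground
    mask are excluded and the per-pixel median of the remaining
    background observations is taken; pixels with fewer than 3
    observations are filled from their nearest covered neighbour. The
    aggregate is offset-subtracted, low-pass smoothed with a Gaussian of
    sigma = ``smoothing_sigma_frac`` of the image width, and normalized
    to mean 1. If ``camera_offset`` is not given it is estimated as the
    0.5th percentile of the aggregate (a biased fallback; prefer the
    known offset).
    """
    arrays = [_as_array(im) for im in images]
    if method is ProfileSource.BACKGROUND_AGGREGATE:
        if foreground_masks is None:
            raise ValueError("background_aggregate requires foreground masks")
        if len(arrays) < min_images:
            raise ValueError(f"need >= {min_images} images, got {len(arrays)}")
        stack = np.stack(arrays)
        excl = np.stack([
            ndimage.binary_dilation(
                (m.labels if isinstance(m, LabelMap) else np.asarray(m)) > 0,
                iterations=mask_dilation_px)
            for m in foreground_masks
        ])
        counts = (~excl).sum(axis=0)
        if np.mean(counts >= 3) < min_coverage:
            raise ValueError("insufficient background coverage: fewer than 50% of "
                             "pixels have >= 3 cell-free observations")
        masked = np.where(excl, np.nan, stack)
        with np.errstate(invalid="ignore"):
            agg = np.nanmedian(masked, axis=0)
        missing = counts < 3
        agg[missing] = np.nan
    elif method is ProfileSource.BLANK_WELL:
        agg = np.median(np.stack(arrays), axis=0)
        missing = np.zeros(agg.shape, bool)
    else:
        raise ValueError("estimate_illumination supports background_aggregate or blank_well")

    if camera_offset is None:
        camera_offset = float(np.nanpercentile(agg, 0.5))
    signal = agg - camera_offset
    if np.isnan(signal).any():
        # fill uncovered pixels from the nearest covered pixel
        nan = np.isnan(signal)
        _, (iy, ix) = ndimage.distance_transform_edt(nan, return_indices=True)
        signal = signal[iy, ix]
    mean_sig = float(signal.mean())
    if mean_sig <= 0 or mean_sig < 1e-6 * max(camera_offset, 1.0):
        raise ValueError("no background signal above the camera offset; "
                         "profile undefined")
    sigma = smoothing_sigma_frac * signal.shape[1]
    smooth = ndimage.gaussian_filter(signal, sigma=sigma, mode="nearest")
    profile = smooth / smooth.mean()
    if np.any(profile <= 0):
        raise ValueError("estimated profile is not strictly positive")
    return IlluminationProfile(profile, float(camera_offset), method)


def flatfield_correct(image: Image2D | np.ndarray, profile: IlluminationProfile) -> Image2D:
    """(image - camera_offset) / profile, clipped at 0."""
    arr = _as_array(image)
    if arr.shape != profile.profile.shape:
        raise ValueError(f"shape mismatch: image {arr.shape} vs profile {profile.profile.shape}")
    out = np.clip((arr - profile.camera_offset) / profile.profile, 0.0, None)
    px = image.pixel_size_um if isinstance(image, Image2D) else 1.0
    ch = image.channel if isinstance(image, Image2D) else None
    return Image2D(out, pixel_size_um=px, channel=ch)


def correct_bleedthrough(target: Image2D | np.ndarray, source: Image2D | np.ndarray,
                         coefficient: float) -> Image2D:
    """target - coefficient * source, clipped at 0 (both flat-field corrected)."""
    if not 0 <= coefficient < 1:
        raise ValueError("bleedthrough coefficient must be in [0, 1)")
    t = _as_array(target)
    s = _as_array(source)
    if t.shape != s.shape:
        raise ValueError("shape mismatch between target and source")
    out = np.clip(t - coefficient * s, 0.0, None)
    px = target.pixel_size_um if isinstance(target, Image2D) else 1.0
    ch = target.channel if isinstance(target, Image2D) else None
    return Image2D(out, pixel_size_um=px, channel=ch)
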