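"""Shared fixtures: small synthetic scenes generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from rtqibc import SimConfig, render_movie, simulate_population
from rtqibc.types import Image2D, LabelMap


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact movie config used by most imaging tests."""
    return SimConfig(field_size_px=(256, 256), n_cells_initial=20, n_frames=40, seed=11)


@pytest.fixture(scope="session")
def small_scene(small_config):
    """(cells, stacks, truth) for the compact movie, rendered once."""
    cells = simulate_population(small_config)
    stacks, truth = render_movie(cells, small_config)
    return cells, stacks, truth


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    """The default 50-cell benchmark config (400x400 px, 120 frames)."""
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_scene(default_config):
    cells = simulate_population(default_config)
    stacks, truth = render_movie(cells, default_config)
    return cells, stacks, truth


def render_disk_nucleus(shape=(64, 64), center=(32.0, 32.0), radius_px=9.0,
                        total=5.0e4, pixel_size_um=0.65) -> Image2D:
    """One truncated-Gaussian nucleus, as the movie renderer draws them."""
    from rtqibc.synth.render import _add_blob

    img = np.zeros(shape)
    _add_blob(img, center[0], center[1], radius_px, total)
    return Image2D(img, pixel_size_um=pixel_size_um)


def disk_mask(shape, center, radius, label=1, base=None) -> LabelMap:
    arr = np.zeros(shape, np.int32) if base is None else base
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    arr[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2] = label
    return LabelMap(arr, pixel_size_um=0.65)


def iou_match_scores(pred: np.ndarray, true: np.ndarray, iou_min: float = 0.5):
    """(recall, precision) of predicted vs true labels at an IoU threshold."""
    ids_p = np.unique(pred[pred > 0])
    ids_t = np.unique(true[true > 0])
    matched = 0
    for t in ids_t:
        tm = true == t
        labs, cnt = np.unique(pred[tm], return_counts=True)
        labs, cnt = labs[labs > 0], cnt[labs > 0]
        if not len(labs):
            continue
        p = labs[np.argmax(cnt)]
        pm = pred == p
        if (tm & pm).sum() / (tm | pm).sum() >= iou_min:
            matched += 1
    recall = matched / len(ids_t) if len(ids_t) else 1.0
    precision = matched / len(ids_p) if len(ids_p) else 1.0
    return recall, precision
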