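"""Disk I/O: multipage TIFF stacks, ground-truth tables, and configs.

One multipage TIFF per channel per site; ground truth and configs are
written as CSV + YAML so a simulated dataset is fully reproducible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .synth import SimConfig, render_fixed_snapshot, render_movie, simulate_population
from .synth.population import population_table

__all__ = ["write_stack", "read_stack", "simulate_to_dir"]


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (n_frames, H, W) stack as a multipage float32 TIFF."""
    tifffile.imwrite(path, np.asarray(stack, np.float32),
                     photometric="minisblack")


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def simulate_to_dir(config: SimConfig, out_dir, site_id: str = "s1") -> Path:
    """Simulate one site and write movie stacks, fixed snapshot, ground
    truth, and the config under ``out_dir``; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = simulate_population(config)
    stacks, truth = render_movie(cells, config)
    for ch, stack in stacks.items():
        write_stack(out / f"{site_id}_{ch}.tif", stack)
    fixed, fixed_truth = render_fixed_snapshot(cells, config)
    for ch, img in fixed.items():
        write_stack(out / f"{site_id}_fixed_{ch}.tif", img.data[None])
    truth.to_csv(out / f"{site_id}_truth.csv", index=False)
    fixed_truth.to_csv(out / f"{site_id}_fixed_truth.csv", index=False)
    population_table(cells).to_csv(out / f"{site_id}_cells.csv", index=False)
    config.to_yaml(out / f"{site_id}_config.yaml")
    return out
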