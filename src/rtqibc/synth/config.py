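"""Simulation configuration for the synthetic RT-QIBC benchmark.

Defaults emulate asynchronously cycling MCF10A-like epithelial cells
imaged at 10x (0.65 um/px) every 3 minutes: a ~16 h cell cycle, nuclei
~9-13 um in diameter, modest nuclear motility, a CRL4^Cdt2 reporter
degraded with a ~6 min half-time from S entry, endogenous-CDT1-like
immunofluorescence degraded with a ~9 min half-time (reaching the
"fully degraded" gate of 10% of the G1 level ~30 min after S entry), and
an sCMOS-like camera (constant offset, smooth vignetting gain, Gaussian
read noise plus intensity-proportional shot-like noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from ..stats import DoseResponseFit

__all__ = ["CellCycleParams", "ReporterKinetics", "CameraConfig", "SimConfig", "CHANNELS"]

#: Fixed channel naming used across rendered outputs and ground-truth tables.
CHANNELS = ("H2B", "CRL4", "APCC", "PCNAFOCI", "DNA", "CDT1IF", "GMNNIF", "EDU", "NDCDT1IF")


@dataclass
class CellCycleParams:
    """Lognormal per-phase duration distributions (median minutes, CV)."""

    g1_median_min: float = 300.0
    g1_cv: float = 0.25
    s_median_min: float = 480.0
    s_cv: float = 0.15
    g2m_median_min: float = 240.0
    g2m_cv: float = 0.20

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"cell cycle parameter {name} must be > 0")

    @property
    def mean_cycle_min(self) -> float:
        total = 0.0
        for med, cv in ((self.g1_median_min, self.g1_cv),
                        (self.s_median_min, self.s_cv),
                        (self.g2m_median_min, self.g2m_cv)):
            total += med * np.exp(np.log1p(cv**2) / 2.0)
        return total


@dataclass
class ReporterKinetics:
    """Reporter accumulation/degradation kinetics (functional forms are a
    modelling choice: linear rise, exponential decay)."""

    crl4_rise_time_min: float = 240.0       # time from anaphase to reporter plateau
    crl4_decay_half_min: float = 6.0        # reporter degradation half-time after S entry
    cdt1_if_decay_half_min: float = 9.0     # endogenous-CDT1-like IF half-time after S entry
    cdt1_degraded_fraction: float = 0.1     # gate: "fully degraded" = 10% of pre-S level
    apcc_rise_time_min: float = 180.0       # APC/C reporter: 0 -> plateau after inactivation
    apcc_basal_fraction: float = 0.02       # residual reporter level while APC/C is active
    apcc_offset_mean_min: float = 6.0       # APC/C inactivation precedes S entry by ~6 min
    apcc_offset_sd_min: float = 5.0         # ... with cell-to-cell spread (can land after S)
    gmnn_rise_time_min: float = 240.0       # geminin/cyclin-A-like IF ramp after inactivation
    foci_area_px: float = 80.0              # plateau PCNA foci area in S phase
    foci_rise_min: float = 6.0              # time for foci area to ramp up at S entry

    def validate(self) -> None:
        for name in ("crl4_rise_time_min", "crl4_decay_half_min", "cdt1_if_decay_half_min",
                     "apcc_rise_time_min", "gmnn_rise_time_min", "foci_area_px",
                     "foci_rise_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"kinetic parameter {name} must be > 0")
        if not 0 < self.cdt1_degraded_fraction < 1:
            raise ValueError("cdt1_degraded_fraction must be in (0, 1)")

    @property
    def cdt1_time_to_degraded_min(self) -> float:
        """Minutes from S entry until CDT1-IF crosses the degraded gate."""
        return self.cdt1_if_decay_half_min * np.log2(1.0 / self.cdt1_degraded_fraction)


@dataclass
class CameraConfig:
    """sCMOS-like acquisition model."""

    offset: float = 100.0                   # constant camera offset, counts
    vignette_amplitude: float = 0.15        # peak-to-edge amplitude of the gain field
    vignette_sigma_frac: float = 0.6        # Gaussian vignette scale as fraction of width
    read_noise_sd: float = 2.0              # Gaussian read noise, counts
    shot_noise_scale: float = 0.05          # variance per unit signal (shot-like)
    bleedthrough: dict = field(default_factory=dict)  # {(src, dst): coefficient}

    def validate(self) -> None:
        if self.offset < 0:
            raise ValueError("camera offset must be >= 0")
        if self.read_noise_sd < 0 or self.shot_noise_scale < 0:
            raise ValueError("noise parameters must be >= 0")
        if not 0 <= self.vignette_amplitude < 1:
            raise ValueError("vignette amplitude must be in [0, 1)")
        for pair, c in self.bleedthrough.items():
            if not 0 <= c < 1:
                raise ValueError(f"bleedthrough coefficient {pair} must be in [0, 1)")


@dataclass
class SimConfig:
    """Top-level synthetic-movie configuration."""

    field_size_px: tuple[int, int] = (400, 400)
    pixel_size_um: float = 0.65
    frame_interval_min: float = 3.0
    n_frames: int = 120
    n_cells_initial: int = 50
    motion_sigma_px_per_frame: float = 1.5
    nucleus_radius_um: tuple[float, float] = (4.5, 6.5)
    cell_cycle: CellCycleParams = field(default_factory=CellCycleParams)
    kinetics: ReporterKinetics = field(default_factory=ReporterKinetics)
    hill: DoseResponseFit = field(
        default_factory=lambda: DoseResponseFit(22.0, 1.0, 10.2, 4.2)
    )
    ndcdt1_range: tuple[float, float] = (0.5, 40.0)
    edu_noise_cv: float = 0.3
    h2b_total_mean: float = 5.0e4           # per-cell integrated H2B intensity, a.u.
    h2b_total_cv: float = 0.2
    reporter_total_mean: float = 2.0e3      # plateau integrated reporter intensity
    reporter_total_cv: float = 0.3
    if_intensity_per_au: float = 400.0      # fixed-cell IF counts per a.u. of analyte
    dna_total_2n: float = 4.0e4             # integrated DNA-stain intensity of a 2N nucleus
    camera: CameraConfig = field(default_factory=CameraConfig)
    seed: int = 0

    # --- validation -----------------------------------------------------
    def validate(self) -> None:
        h, w = self.field_size_px
        if h < 64 or w < 64:
            raise ValueError("field size must be at least 64 px per side")
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ValueError("pixel size and frame interval must be > 0")
        if self.n_frames < 2 or self.n_cells_initial < 1:
            raise ValueError("need at least 2 frames and 1 cell")
        rlo, rhi = self.nucleus_radius_um
        if not 0 < rlo <= rhi:
            raise ValueError("nucleus_radius_um must be a positive increasing range")
        if self.motion_sigma_px_per_frame >= rlo / self.pixel_size_um:
            raise ValueError("motion sigma must be smaller than the nucleus radius in px")
        self.cell_cycle.validate()
        self.kinetics.validate()
        self.camera.validate()
        self._check_density()

    @property
    def mean_radius_px(self) -> float:
        return 0.5 * (self.nucleus_radius_um[0] + self.nucleus_radius_um[1]) / self.pixel_size_um

    @property
    def movie_length_min(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_min

    def _check_density(self) -> None:
        """Reject configs whose expected end-of-movie population would make
        more than ~20% of nuclei overlap a neighbour (centers closer than
        1.2x the mean radius, Poisson placement approximation)."""
        growth = 2.0 ** (self.movie_length_min / self.cell_cycle.mean_cycle_min)
        n_final = self.n_cells_initial * growth
        h, w = self.field_size_px
        lam = n_final * np.pi * (1.2 * self.mean_radius_px) ** 2 / (h * w)
        overlap_frac = 1.0 - np.exp(-lam)
        if overlap_frac > 0.20:
            raise ValueError(
                f"expected overlapping-nuclei fraction {overlap_frac:.2f} exceeds the "
                "20% density bound; enlarge the field or reduce n_cells_initial"
            )

    # --- (de)serialization ----------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["hill"] = {"edu_max": self.hill.edu_max, "edu_min": self.hill.edu_min,
                     "ic50": self.hill.ic50, "n_hill": self.hill.n_hill}
        d["camera"]["bleedthrough"] = {f"{a}->{b}": c
                                       for (a, b), c in self.camera.bleedthrough.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        hill = d.pop("hill", None)
        cam = d.pop("camera", None)
        cfg = cls(
            field_size_px=tuple(d.pop("field_size_px")),
            nucleus_radius_um=tuple(d.pop("nucleus_radius_um")),
            ndcdt1_range=tuple(d.pop("ndcdt1_range")),
            cell_cycle=CellCycleParams(**d.pop("cell_cycle")),
            kinetics=ReporterKinetics(**d.pop("kinetics")),
            **d,
        )
        if hill:
            cfg.hill = DoseResponseFit(hill["edu_max"], hill["edu_min"],
                                       hill["ic50"], hill["n_hill"])
        if cam:
            bt = {tuple(k.split("->")): v for k, v in cam.pop("bleedthrough", {}).items()}
            cfg.camera = CameraConfig(bleedthrough=bt, **cam)
        return cfg
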