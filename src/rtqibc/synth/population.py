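"""Ground-truth cell population simulator.

Each cell draws lognormal G1/S/G2M durations, moves by an isotropic
Gaussian random walk with a soft-core exclusion (nuclei may touch but
not interpenetrate; a density bound on the config guards against
crowding), and divides at the end of G2M into two daughters placed
adjacent to the parent. Reporter traces are evaluated
analytically at frame times from the cell's event schedule:

* CRL4^Cdt2 reporter — rises linearly from anaphase to a plateau, then
  decays exponentially from S entry (half-time ``crl4_decay_half_min``).
* APC/C^Cdh1 reporter — near-basal from anaphase until APC/C
  inactivation (drawn around ``apcc_offset_mean_min`` before S entry),
  then a linear rise.
* CDT1-like immunofluorescence — constant through G1, exponential decay
  from S entry; with default kinetics it crosses the "fully degraded"
  gate (10% of the G1 level) ~30 min after S entry.
* PCNA foci area — ~0 outside S phase, ramping to a plateau within
  minutes of S entry.
* EdU — the Hill-model prediction at the cell's ND-CDT1 expression for
  cells in S phase at the end of the movie (times lognormal cell-to-cell
  noise), ~0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig

__all__ = ["GroundTruthCell", "simulate_population", "programmed_cell", "population_table"]


@dataclass
class GroundTruthCell:
    """One simulated cell with its full event schedule and per-frame truth."""

    cell_id: int
    parent_id: int | None
    radius_px: float
    frames: np.ndarray                  # frame indices where the cell exists
    centroids: np.ndarray               # (n_frames_present, 2) as (y, x), px
    traces: dict = field(default_factory=dict)  # channel -> per-frame values
    # raw schedule, minutes from movie start (may lie outside the movie)
    birth_time_min: float = 0.0
    s_entry_time_min: float = np.inf
    apcc_inactivation_time_min: float = np.inf
    division_time_min: float = np.inf
    cdt1_fully_degraded_time_min: float = np.inf
    s_exit_time_min: float = np.inf
    movie_end_min: float = 0.0
    # per-cell scalars
    h2b_total: float = 0.0
    ndcdt1: float = 0.0                 # true ND-CDT1 expression, a.u.
    edu: float = 0.0                    # true EdU incorporation, a.u.
    foci_offsets: np.ndarray | None = None  # (k, 2) foci positions rel. to centroid

    def _in_movie(self, t: float) -> float | None:
        return float(t) if 0.0 <= t <= self.movie_end_min else None

    @property
    def anaphase_time(self) -> float | None:
        return self._in_movie(self.birth_time_min)

    @property
    def s_entry_time(self) -> float | None:
        return self._in_movie(self.s_entry_time_min)

    @property
    def apcc_inactivation_time(self) -> float | None:
        return self._in_movie(self.apcc_inactivation_time_min)

    @property
    def cdt1_fully_degraded_time(self) -> float | None:
        return self._in_movie(self.cdt1_fully_degraded_time_min)

    @property
    def in_s_at_movie_end(self) -> bool:
        return self.s_entry_time_min <= self.movie_end_min < self.s_exit_time_min


def _lognormal(rng: np.random.Generator, median: float, cv: float) -> float:
    sigma = np.sqrt(np.log1p(cv**2))
    return float(median * np.exp(rng.normal(0.0, sigma)))


def _lognormal_mean1(rng: np.random.Generator, cv: float, size=None):
    if cv <= 0:
        return np.ones(size) if size else 1.0
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=size)


def _evaluate_traces(cell: GroundTruthCell, cfg: SimConfig, t: np.ndarray,
                     e_rep: float, cdt1_level: float, gmnn_level: float) -> None:
    """Fill per-frame analytic trace values for frame times ``t`` (minutes)."""
    kin = cfg.kinetics
    birth = cell.birth_time_min
    s_in = cell.s_entry_time_min
    s_out = cell.s_exit_time_min
    t_apcc = cell.apcc_inactivation_time_min

    # CRL4^Cdt2 reporter: linear rise from anaphase, exponential decay from S entry
    rise = np.clip((t - birth) / kin.crl4_rise_time_min, 0.0, 1.0)
    crl4 = e_rep * rise
    after = t >= s_in
    if np.any(after):
        level_at_s = e_rep * np.clip((s_in - birth) / kin.crl4_rise_time_min, 0.0, 1.0)
        crl4[after] = level_at_s * 2.0 ** (-(t[after] - s_in) / kin.crl4_decay_half_min)

    # APC/C^Cdh1 reporter: basal until inactivation, then linear rise
    apcc = np.full_like(t, kin.apcc_basal_fraction * e_rep)
    on = t >= t_apcc
    apcc[on] += e_rep * np.clip((t[on] - t_apcc) / kin.apcc_rise_time_min, 0.0, 1.0)

    # PCNA foci area (px): ramp at S entry, plateau through S, gone after
    foci = np.zeros_like(t)
    in_s = (t >= s_in) & (t < s_out)
    foci[in_s] = kin.foci_area_px * np.clip((t[in_s] - s_in) / kin.foci_rise_min, 0.0, 1.0)

    # CDT1-like IF: constant through G1, exponential decay from S entry
    cdt1 = np.full_like(t, cdt1_level)
    cdt1[after] = cdt1_level * 2.0 ** (-(t[after] - s_in) / kin.cdt1_if_decay_half_min)

    # geminin/cyclin-A-like IF: basal, linear ramp after APC/C inactivation
    gmn = np.full_like(t, 0.05 * gmnn_level)
    gmn[on] += gmnn_level * np.clip((t[on] - t_apcc) / kin.gmnn_rise_time_min, 0.0, 1.0)

    # DNA content (a.u. of 2N): doubles linearly through S phase
    s_dur = max(s_out - s_in, 1e-9)
    progress = np.clip((t - s_in) / s_dur, 0.0, 1.0)
    dna = cfg.dna_total_2n * (1.0 + progress)

    scale = cfg.if_intensity_per_au
    cell.traces = {
        "H2B": np.full_like(t, cell.h2b_total),
        "CRL4": np.maximum(crl4, 0.0),
        "APCC": np.maximum(apcc, 0.0),
        "PCNAFOCI": foci,
        "CDT1IF": np.maximum(cdt1 * scale, 0.0),
        "GMNNIF": np.maximum(gmn * scale, 0.0),
        "DNA": dna,
        "NDCDT1IF": np.full_like(t, cell.ndcdt1 * scale),
        "EDU": np.full_like(t, cell.edu * scale),
    }


def _walk(rng: np.random.Generator, start: np.ndarray, n_steps: int,
          sigma: float, shape: tuple[int, int], margin: float) -> np.ndarray:
    """Gaussian random walk reflected at the field border."""
    pos = np.empty((n_steps, 2))
    p = start.astype(float).copy()
    h, w = shape
    for k in range(n_steps):
        pos[k] = p
        p = p + rng.normal(0.0, sigma, size=2)
        for ax, lim in ((0, h), (1, w)):
            if p[ax] < margin:
                p[ax] = 2 * margin - p[ax]
            if p[ax] > lim - margin:
                p[ax] = 2 * (lim - margin) - p[ax]
            p[ax] = float(np.clip(p[ax], margin, lim - margin))
    return pos


def _draw_foci_offsets(rng: np.random.Generator, radius_px: float, n_spots: int) -> np.ndarray:
    """Uniform spot positions within 70% of the nuclear radius."""
    r = 0.70 * radius_px * np.sqrt(rng.uniform(0, 1, n_spots))
    theta = rng.uniform(0, 2 * np.pi, n_spots)
    return np.column_stack([r * np.sin(theta), r * np.cos(theta)])


def _finalize_cell(cell: GroundTruthCell, cfg: SimConfig, rng: np.random.Generator,
                   e_rep: float, cdt1_level: float, gmnn_level: float) -> None:
    t = cell.frames * cfg.frame_interval_min
    # EdU: Hill-model incorporation for cells in S at fixation, ~0 otherwise
    base = cfg.hill.predict(cell.ndcdt1) if cell.in_s_at_movie_end else 0.05
    cell.edu = float(base * _lognormal_mean1(rng, cfg.edu_noise_cv))
    _evaluate_traces(cell, cfg, t, e_rep, cdt1_level, gmnn_level)
    n_spots = max(int(round(cfg.kinetics.foci_area_px / 7.0)), 1)
    cell.foci_offsets = _draw_foci_offsets(rng, cell.radius_px, n_spots)


def simulate_population(config: SimConfig) -> list[GroundTruthCell]:
    """Simulate a ground-truthed population for one imaging site.

    Deterministic given ``config.seed``. Initial cells start at uniform
    random positions (at least ~2.2 mean radii apart where space allows)
    and a uniform random age within their own cycle; divisions spawn two
    daughters adjacent to the parent, splitting the parent's integrated
    H2B intensity ~equally. Motion is a per-frame isotropic Gaussian
    random walk with a soft-core exclusion: nuclei whose centers come
    closer than 75% of the sum of their radii are pushed apart, so
    nuclei may touch (and are then separated by the splitter during
    segmentation) but never interpenetrate, as in a real monolayer.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cc = config.cell_cycle
    h, w = config.field_size_px
    t_end = config.movie_length_min
    dt = config.frame_interval_min
    rlo, rhi = (r / config.pixel_size_um for r in config.nucleus_radius_um)

    def new_schedule():
        return (_lognormal(rng, cc.g1_median_min, cc.g1_cv),
                _lognormal(rng, cc.s_median_min, cc.s_cv),
                _lognormal(rng, cc.g2m_median_min, cc.g2m_cv))

    # ---- phase A: lineage tree with schedules and per-cell levels --------
    protos: list[dict] = []
    next_id = [0]
    queue: list[dict] = []
    min_sep = 2.2 * config.mean_radius_px
    placed: list[np.ndarray] = []
    for _ in range(config.n_cells_initial):
        g1, s, g2m = new_schedule()
        age = rng.uniform(0.0, g1 + s + g2m)
        cand = np.array([rng.uniform(rhi, h - rhi), rng.uniform(rhi, w - rhi)])
        for _attempt in range(200):
            if all(np.hypot(*(cand - p)) >= min_sep for p in placed):
                break
            cand = np.array([rng.uniform(rhi, h - rhi), rng.uniform(rhi, w - rhi)])
        placed.append(cand)
        h2b = config.h2b_total_mean * _lognormal_mean1(rng, config.h2b_total_cv)
        queue.append({"birth": -age, "parent": None, "pos0": cand, "h2b": float(h2b),
                      "sign": 1.0, "schedule": (g1, s, g2m)})
    while queue:
        q = queue.pop(0)
        g1, s, g2m = q["schedule"]
        birth = q["birth"]
        div = birth + g1 + s + g2m
        first = max(int(np.ceil(birth / dt)), 0) if birth > 0 else 0
        last = min(int(np.floor((div - 1e-9) / dt)), config.n_frames - 1)
        if first > config.n_frames - 1 or last < first:
            continue  # never visible
        cid = next_id[0]
        next_id[0] += 1
        proto = dict(q)
        proto.update({
            "cell_id": cid,
            "radius": float(rng.uniform(rlo, rhi)),
            "first": first, "last": last, "div": div,
            "apcc_offset": float(rng.normal(config.kinetics.apcc_offset_mean_min,
                                            config.kinetics.apcc_offset_sd_min)),
            "ndcdt1": float(np.exp(rng.uniform(np.log(config.ndcdt1_range[0]),
                                               np.log(config.ndcdt1_range[1])))),
            "e_rep": float(config.reporter_total_mean
                           * _lognormal_mean1(rng, config.reporter_total_cv)),
            "cdt1_level": float(5.0 * _lognormal_mean1(rng, 0.25)),
            "gmnn_level": float(8.0 * _lognormal_mean1(rng, 0.25)),
            "div_theta": float(rng.uniform(0, 2 * np.pi)),
            "split_frac": float(np.clip(rng.normal(0.5, 0.02), 0.4, 0.6)),
        })
        protos.append(proto)
        if div < t_end:
            for sign in (1.0, -1.0):
                frac = proto["split_frac"] if sign > 0 else 1.0 - proto["split_frac"]
                queue.append({"birth": div, "parent": cid, "pos0": None,
                              "h2b": proto["h2b"] * frac, "sign": sign,
                              "schedule": new_schedule()})

    # ---- phase B: frame-synchronous motion with soft-core exclusion ------
    by_id = {p["cell_id"]: p for p in protos}
    positions: dict[int, list[np.ndarray]] = {p["cell_id"]: [] for p in protos}
    current: dict[int, np.ndarray] = {}

    def clip_to_field(pos, radius):
        return np.clip(pos, radius, [h - radius, w - radius])

    sigma = config.motion_sigma_px_per_frame
    for f in range(config.n_frames):
        for cid in [c for c in current if by_id[c]["last"] < f]:
            del current[cid]
        for p in sorted((p for p in protos if p["first"] == f), key=lambda p: p["cell_id"]):
            if p["parent"] is None:
                pos = np.asarray(p["pos0"], float)
            else:
                parent = by_id[p["parent"]]
                ppos = positions[parent["cell_id"]][-1]
                direction = np.array([np.sin(parent["div_theta"]),
                                      np.cos(parent["div_theta"])])
                # daughters placed adjacent to the parent, on opposite sides
                pos = ppos + p["sign"] * 1.1 * parent["radius"] * direction
            current[p["cell_id"]] = clip_to_field(pos, p["radius"])
        ids = sorted(current)
        for cid in ids:
            if positions[cid]:  # cells present before this frame take a step
                r = by_id[cid]["radius"]
                pnew = current[cid] + rng.normal(0.0, sigma, size=2)
                for ax, lim in ((0, h), (1, w)):
                    if pnew[ax] < r:
                        pnew[ax] = 2 * r - pnew[ax]
                    if pnew[ax] > lim - r:
                        pnew[ax] = 2 * (lim - r) - pnew[ax]
                    pnew[ax] = float(np.clip(pnew[ax], r, lim - r))
                current[cid] = pnew
        for _iteration in range(3):
            moved = False
            for a in range(len(ids)):
                for b in range(a + 1, len(ids)):
                    ca, cb = ids[a], ids[b]
                    dmin = 0.75 * (by_id[ca]["radius"] + by_id[cb]["radius"])
                    delta = current[cb] - current[ca]
                    d = float(np.hypot(*delta))
                    if d < dmin:
                        direction = delta / d if d > 1e-6 else np.array([1.0, 0.0])
                        push = 0.5 * (dmin - d)
                        current[ca] = clip_to_field(current[ca] - push * direction,
                                                    by_id[ca]["radius"])
                        current[cb] = clip_to_field(current[cb] + push * direction,
                                                    by_id[cb]["radius"])
                        moved = True
            if not moved:
                break
        for cid in ids:
            positions[cid].append(current[cid].copy())

    # ---- phase C: assemble cells and evaluate traces ---------------------
    cells: list[GroundTruthCell] = []
    for p in protos:
        g1, s, g2m = p["schedule"]
        birth = p["birth"]
        s_in = birth + g1
        frames = np.arange(p["first"], p["last"] + 1)
        cents = np.asarray(positions[p["cell_id"]], float)
        cell = GroundTruthCell(
            cell_id=p["cell_id"], parent_id=p["parent"], radius_px=p["radius"],
            frames=frames, centroids=cents,
            birth_time_min=birth,
            s_entry_time_min=s_in,
            apcc_inactivation_time_min=max(s_in - p["apcc_offset"], birth + 0.05 * g1),
            division_time_min=p["div"],
            cdt1_fully_degraded_time_min=s_in + config.kinetics.cdt1_time_to_degraded_min,
            s_exit_time_min=s_in + s,
            movie_end_min=t_end,
            h2b_total=p["h2b"],
            ndcdt1=p["ndcdt1"],
        )
        _finalize_cell(cell, config, rng, p["e_rep"], p["cdt1_level"], p["gmnn_level"])
        cells.append(cell)
    return cells


def programmed_cell(
    config: SimConfig,
    cell_id: int = 0,
    birth_time_min: float = 0.0,
    g1_min: float = 120.0,
    s_min: float = 480.0,
    g2m_min: float = 240.0,
    position: tuple[float, float] | None = None,
    apcc_offset_min: float = 6.0,
    ndcdt1: float | None = None,
    motion: bool = False,
    seed: int = 0,
) -> GroundTruthCell:
    """Construct a single cell with an explicitly programmed schedule.

    Useful for tests and examples that need an event (e.g. S entry) at a
    known frame without searching a random population.
    """
    rng = np.random.default_rng(seed)
    h, w = config.field_size_px
    pos = np.array(position if position is not None else (h / 2.0, w / 2.0), float)
    dt = config.frame_interval_min
    div = birth_time_min + g1_min + s_min + g2m_min
    first = max(int(np.ceil(birth_time_min / dt)), 0) if birth_time_min > 0 else 0
    last = min(int(np.floor((div - 1e-9) / dt)), config.n_frames - 1)
    frames = np.arange(first, last + 1)
    radius = config.mean_radius_px
    if motion:
        cents = _walk(rng, pos, frames.size, config.motion_sigma_px_per_frame,
                      (h, w), margin=radius)
    else:
        cents = np.tile(pos, (frames.size, 1))
    s_in = birth_time_min + g1_min
    cell = GroundTruthCell(
        cell_id=cell_id, parent_id=None, radius_px=radius,
        frames=frames, centroids=cents,
        birth_time_min=birth_time_min,
        s_entry_time_min=s_in,
        apcc_inactivation_time_min=s_in - apcc_offset_min,
        division_time_min=div,
        cdt1_fully_degraded_time_min=s_in + config.kinetics.cdt1_time_to_degraded_min,
        s_exit_time_min=s_in + s_min,
        movie_end_min=config.movie_length_min,
        h2b_total=config.h2b_total_mean,
        ndcdt1=float(ndcdt1 if ndcdt1 is not None else
                     np.sqrt(config.ndcdt1_range[0] * config.ndcdt1_range[1])),
    )
    _finalize_cell(cell, config, rng, config.reporter_total_mean, 5.0, 8.0)
    return cell


def population_table(cells: list[GroundTruthCell]) -> pd.DataFrame:
    """Per-cell ground-truth summary (one row per cell)."""
    rows = []
    for c in cells:
        rows.append({
            "cell_id": c.cell_id,
            "parent_id": -1 if c.parent_id is None else c.parent_id,
            "radius_px": c.radius_px,
            "first_frame": int(c.frames[0]),
            "last_frame": int(c.frames[-1]),
            "final_y": c.centroids[-1, 0],
            "final_x": c.centroids[-1, 1],
            "anaphase_time": c.anaphase_time,
            "apcc_inactivation_time": c.apcc_inactivation_time,
            "s_entry_time": c.s_entry_time,
            "cdt1_fully_degraded_time": c.cdt1_fully_degraded_time,
            "in_s_at_movie_end": c.in_s_at_movie_end,
            "h2b_total": c.h2b_total,
            "ndcdt1": c.ndcdt1,
            "edu": c.edu,
        })
    return pd.DataFrame(rows)
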