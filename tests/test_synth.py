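"""Synthetic generator: populations, rendering, camera model."""

import numpy as np
import pytest

from rtqibc import SimConfig, apply_camera_model, render_fixed_snapshot, render_movie, simulate_population
from rtqibc.correction import IlluminationProfile, ProfileSource, correct_bleedthrough, flatfield_correct
from rtqibc.synth import CameraConfig, illumination_profile_field
from rtqibc.synth.population import population_table, programmed_cell
from rtqibc.synth.render import render_true_labelmap
from rtqibc.types import Image2D


# ---------------------------------------------------------------- population
def test_population_seeded_determinism(small_config, small_scene):
    cells, _, truth = small_scene
    again = population_table(simulate_population(small_config))
    assert truth.equals(again)


def test_population_event_ordering(default_scene):
    cells, _, _ = default_scene
    for c in cells:
        if c.anaphase_time is not None and c.s_entry_time is not None:
            assert c.anaphase_time < c.s_entry_time
        if c.anaphase_time is not None and c.apcc_inactivation_time is not None:
            assert c.anaphase_time < c.apcc_inactivation_time
        assert c.cdt1_fully_degraded_time_min >= c.s_entry_time_min
        for trace in c.traces.values():
            assert (np.asarray(trace) >= 0).all()


def test_population_density_bound_rejected():
    cfg = SimConfig(field_size_px=(128, 128), n_cells_initial=200)
    with pytest.raises(ValueError, match="density"):
        simulate_population(cfg)


def test_config_invariant_validation():
    with pytest.raises(ValueError):
        SimConfig(field_size_px=(32, 400)).validate()
    with pytest.raises(ValueError):
        SimConfig(motion_sigma_px_per_frame=20.0).validate()
    cam = CameraConfig(bleedthrough={("A", "B"): 1.5})
    with pytest.raises(ValueError):
        cam.validate()


def test_programmed_cell_crl4_peaks_at_s_entry():
    """A cell with S entry at frame 40 has its CRL4 trace maximal there and
    strictly decreasing for the following 10 frames."""
    cfg = SimConfig(seed=0)
    cell = programmed_cell(cfg, birth_time_min=0.0, g1_min=40 * 3.0)
    trace = cell.traces["CRL4"]
    assert np.argmax(trace) == 40
    assert (np.diff(trace[40:51]) < 0).all()


def test_cdt1_degraded_gate_reached_by_33_min(default_config, default_scene):
    """With default kinetics, the analytic exponential decay brings CDT1-IF
    below the degraded gate (10% of the G1 level) by 33 min after S entry
    for >= 90% of cells (deterministically: for all of them)."""
    kin = default_config.kinetics
    t_gate = kin.cdt1_time_to_degraded_min
    assert t_gate == pytest.approx(kin.cdt1_if_decay_half_min * np.log2(10), rel=1e-12)
    assert t_gate <= 33.0
    cells, _, _ = default_scene
    frac = np.mean([c.cdt1_fully_degraded_time_min - c.s_entry_time_min <= 33.0
                    for c in cells])
    assert frac >= 0.9


# ---------------------------------------------------------------- rendering
def test_render_static_cell_conserves_intensity():
    cfg = SimConfig(field_size_px=(96, 96), n_cells_initial=1, n_frames=10, seed=2)
    cell = programmed_cell(cfg, g1_min=1000.0)
    stacks, _ = render_movie([cell], cfg)
    totals = stacks["H2B"].sum(axis=(1, 2))
    assert np.ptp(totals) / totals.mean() < 1e-3


def test_render_division_two_components_summing_to_parent(default_config, default_scene):
    from scipy import ndimage

    cells, stacks, _ = default_scene
    daughters = {}
    for c in cells:
        if c.parent_id is not None:
            daughters.setdefault(c.parent_id, []).append(c)
    pid, ds = next((k, v) for k, v in daughters.items() if len(v) == 2)
    parent = next(c for c in cells if c.cell_id == pid)
    k = parent.frames[-1]
    assert ds[0].frames[0] == k + 1
    # isolate the two daughters in a window around the parent's last position
    y, x = parent.centroids[-1].astype(int)
    h2b = stacks["H2B"][k + 1]
    win = np.zeros_like(h2b)
    true = render_true_labelmap(cells, default_config, k + 1)
    m = np.isin(true, [ds[0].cell_id + 1, ds[1].cell_id + 1])
    lab, n = ndimage.label(m)
    assert n == 2
    assert np.hypot(*(np.array(ndimage.center_of_mass(m)) - [y, x])) < 3 * parent.radius_px
    total = h2b[m].sum()
    assert total == pytest.approx(parent.h2b_total, rel=0.05)


def test_render_foci_only_inside_s_phase_nuclei(default_config, default_scene):
    cells, stacks, _ = default_scene
    f = default_config.n_frames - 1
    foci = stacks["PCNAFOCI"][f]
    true = render_true_labelmap(cells, default_config, f)
    in_s = [c.cell_id + 1 for c in cells if f in set(c.frames)
            and c.traces["PCNAFOCI"][np.flatnonzero(c.frames == f)[0]] > 0]
    bright = foci > 30.0  # well above the nuclear haze
    outside = bright & ~np.isin(true, in_s)
    assert outside.sum() / max(bright.sum(), 1) < 0.01


# ---------------------------------------------------------------- camera
def test_camera_offset_and_profile_arithmetic():
    cfg = SimConfig(seed=0)
    cfg.camera.vignette_amplitude = 0.0  # profile identically 1
    sig = np.full((64, 64), 40.0)
    out = apply_camera_model(sig, cfg, noise=False)
    assert np.allclose(out.data, 140.0)
    profile = illumination_profile_field(cfg, (64, 64))
    assert np.allclose(profile, 1.0)
    # non-flat profile: output = offset + profile * signal at each pixel
    cfg2 = SimConfig(seed=0)
    p2 = illumination_profile_field(cfg2, (64, 64))
    out2 = apply_camera_model(sig, cfg2, noise=False)
    assert np.allclose(out2.data, 100.0 + p2 * 40.0)
    assert p2.mean() == pytest.approx(1.0)
    assert (p2 > 0).all()


def test_camera_bleedthrough_arithmetic():
    cfg = SimConfig(seed=0)
    cfg.camera.vignette_amplitude = 0.0
    cfg.camera.bleedthrough = {("A", "B"): 0.1}
    a = np.full((32, 32), 200.0)
    b = np.zeros((32, 32))
    out = apply_camera_model(b, cfg, channel="B", sources={"A": a}, noise=False)
    assert np.allclose(out.data, 100.0 + 20.0)


def test_camera_model_exactly_invertible_without_noise():
    cfg = SimConfig(seed=3)
    cfg.camera.bleedthrough = {("CRL4", "APCC"): 0.08}
    rng = np.random.default_rng(0)
    sig = rng.uniform(0, 500, (80, 80))
    src = rng.uniform(0, 300, (80, 80))
    raw = apply_camera_model(sig, cfg, channel="APCC", sources={"CRL4": src}, noise=False)
    raw_src = apply_camera_model(src, cfg, channel="CRL4", noise=False)
    profile = IlluminationProfile(illumination_profile_field(cfg, (80, 80)),
                                  camera_offset=cfg.camera.offset,
                                  source=ProfileSource.PROVIDED)
    corr = flatfield_correct(raw, profile)
    corr_src = flatfield_correct(raw_src, profile)
    recovered = correct_bleedthrough(corr, corr_src, 0.08)
    assert np.allclose(recovered.data, sig, atol=1e-9)
    assert np.allclose(corr_src.data, src, atol=1e-9)


def test_camera_rejects_invalid():
    cfg = SimConfig(seed=0)
    cfg.camera.offset = -5.0
    with pytest.raises(ValueError):
        apply_camera_model(np.zeros((16, 16)), cfg, noise=False)


# ---------------------------------------------------------------- fixed plate
def test_fixed_snapshot_coordinates_ratio_and_offset(small_config, small_scene):
    cells, _, _ = small_scene
    imgs, truth = render_fixed_snapshot(cells, small_config, 1.0, (0.0, 0.0))
    assert np.allclose(truth.fixed_y, truth.live_y, atol=1e-9)
    _, t2 = render_fixed_snapshot(cells, small_config, 1.0, (17.0, -9.0))
    assert np.allclose(t2.fixed_y - truth.fixed_y, 17.0)
    assert np.allclose(t2.fixed_x - truth.fixed_x, -9.0)
    _, t3 = render_fixed_snapshot(cells, small_config, 2.0, (5.0, 3.0))
    assert np.allclose(t3.fixed_y, 2.0 * truth.live_y + 5.0)
    assert np.allclose(t3.fixed_x, 2.0 * truth.live_x + 3.0)
    with pytest.raises(ValueError):
        render_fixed_snapshot(cells, small_config, 0.5)


def test_fixed_snapshot_centroid_measurement_matches_truth(small_config, small_scene):
    from scipy import ndimage

    cells, _, _ = small_scene
    imgs, truth = render_fixed_snapshot(cells, small_config, 1.0, (0.0, 0.0))
    dna = imgs["DNA"].data
    # intensity-weighted centroid near each true centroid (isolated cells,
    # so the window contains no neighbour signal)
    pos = truth[["fixed_y", "fixed_x"]].to_numpy()
    d = np.hypot(*(pos[:, None, :] - pos[None, :, :]).transpose(2, 0, 1))
    np.fill_diagonal(d, np.inf)
    isolated = truth[d.min(axis=1) > 35]
    assert len(isolated) >= 3
    for _, row in isolated.head(5).iterrows():
        y, x = int(round(row.fixed_y)), int(round(row.fixed_x))
        win = dna[max(y - 12, 0):y + 13, max(x - 12, 0):x + 13]
        cy, cx = ndimage.center_of_mass(win)
        assert abs(cy - (row.fixed_y - max(y - 12, 0))) < 0.5
        assert abs(cx - (row.fixed_x - max(x - 12, 0))) < 0.5
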