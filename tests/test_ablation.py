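"""Virtual ablation planning, lesion clamping and outcome classification."""

import numpy as np
import pytest

from rotormap import ablation as abl, ionic, maps, rotors, tissue
from rotormap.fixtures import SpiralFixture, make_spiral_movie


def _df_map(ny=120, nx=120, seed=0):
    vals = np.random.default_rng(seed).uniform(3.0, 11.0, (ny, nx))
    return maps.ScalarMap(vals, "DF", 6000.0)


def test_map_ablation_fraction_and_order_statistic():
    smap = _df_map()
    plan = abl.plan_map_ablation(smap, "DF", 0.05)
    assert plan.lesion_mask.sum() == int(round(0.05 * 120 * 120))
    assert smap.values[plan.lesion_mask].min() >= smap.values[~plan.lesion_mask].max() - 1e-12


def test_cfae_ablation_targets_lowest_and_skips_undefined():
    vals = np.random.default_rng(2).uniform(50.0, 400.0, (80, 80))
    vals[:10] = np.nan
    smap = maps.ScalarMap(vals, "CFAE", 6000.0)
    plan = abl.plan_map_ablation(smap, "CFAE", 0.05)
    assert not plan.lesion_mask[:10].any()
    sel = vals[plan.lesion_mask]
    unsel = vals[10:][~plan.lesion_mask[10:]]
    assert np.nanmax(sel) <= np.nanmin(unsel) + 1e-12


def test_map_ablation_fraction_bounds():
    with pytest.raises(ValueError):
        abl.plan_map_ablation(_df_map(), "DF", 0.0)
    with pytest.raises(ValueError):
        abl.plan_map_ablation(_df_map(), "DF", 0.7)


def test_ps_ablation_single_point_one_disk():
    tr = rotors.PSTrajectory(np.array([0.0, 1.0]), np.array([40.0, 40.0]),
                             np.array([40.0, 40.0]), 1, 0.25)
    plan = abl.plan_ps_ablation([tr], (120, 120), 0.25, fraction=0.05)
    # oracle: brute-force count of nodes within 1 mm of the point
    rr, cc = np.meshgrid(np.arange(120), np.arange(120), indexing="ij")
    disk = np.hypot(rr - 40, cc - 40) * 0.25 <= 1.0
    assert plan.lesion_mask.sum() == disk.sum()
    assert plan.flagged                       # stream exhausted below 5%
    assert plan.achieved_fraction == pytest.approx(disk.sum() / 120 ** 2)


def test_ps_ablation_line_of_points_disjoint_disks():
    xs = np.arange(10.0, 110.0, 10.0)         # 2.5 mm apart at dx 0.25
    t = np.arange(xs.size, dtype=float)
    tr = rotors.PSTrajectory(t, xs, np.full(xs.size, 60.0), 1, 0.25)
    plan = abl.plan_ps_ablation([tr], (120, 120), 0.25, fraction=0.05)
    single = abl.disk_mask((120, 120), (60.0, 10.0), 1.0, 0.25).sum()
    n_disks = round(plan.lesion_mask.sum() / single)
    assert plan.lesion_mask.sum() == n_disks * single   # disks don't overlap


def test_ps_ablation_tiny_fraction_overruns_by_one_disk():
    tr = rotors.PSTrajectory(np.array([0.0, 1.0]), np.array([40.0, 41.0]),
                             np.array([40.0, 40.0]), 1, 0.25)
    plan = abl.plan_ps_ablation([tr], (120, 120), 0.25, fraction=1e-5)
    single = abl.disk_mask((120, 120), (40.0, 40.0), 1.0, 0.25).sum()
    assert plan.lesion_mask.sum() == single


def test_apply_ablation_idempotent_and_monotone():
    grid = tissue.TissueGrid(nx=32, ny=32, dx=0.25, deff=0.1)
    m1 = np.zeros((32, 32), bool)
    m1[5:10, 5:10] = True
    m2 = np.zeros((32, 32), bool)
    m2[20:25, 20:25] = True
    p1 = abl.AblationPlan(m1, "DF", 0.02)
    p2 = abl.AblationPlan(m2, "DF", 0.02)
    g1 = abl.apply_ablation(grid, p1)
    g11 = abl.apply_ablation(g1, p1)
    assert np.array_equal(g1.lesion_mask, g11.lesion_mask)
    g12 = abl.apply_ablation(g1, p2)
    assert g12.lesion_mask.sum() == m1.sum() + m2.sum()
    assert (g12.lesion_mask & g1.lesion_mask).sum() == m1.sum()   # only grows


def test_empty_plan_leaves_grid_unchanged():
    grid = tissue.TissueGrid(nx=24, ny=24, dx=0.25, deff=0.1)
    plan = abl.AblationPlan(np.zeros((24, 24), bool), "DF", 0.0)
    g = abl.apply_ablation(grid, plan)
    assert not g.lesion_mask.any()


def test_lesion_clamped_to_rest_in_every_later_frame():
    grid = tissue.TissueGrid(nx=32, ny=48, dx=0.25, deff=0.1)
    sim = tissue.TissueSim(grid, ionic.CONTROL_PARAMS)
    sim.run_recorded(30.0, 5.0, [(0.0, 2.0, sim.line_stim_indices(3), -20.0)])
    mask = np.zeros((48, 32), bool)
    mask[20:26, 8:24] = True
    abl.apply_ablation(sim, abl.AblationPlan(mask, "DF", 0.0125))
    movie = sim.run_recorded(150.0, 2.0)
    assert np.abs(movie.frames[:, mask] - sim.v_rest).max() < 1e-9


def test_full_width_lesion_strip_blocks_conduction():
    grid = tissue.TissueGrid(nx=24, ny=80, dx=0.25, deff=0.1)
    sim = tissue.TissueSim(grid, ionic.CONTROL_PARAMS)
    mask = np.zeros((80, 24), bool)
    mask[40:44, :] = True                     # strip spans the sheet
    sim.set_lesion(mask)
    movie = sim.run_recorded(300.0, 2.0,
                             [(0.0, 2.0, sim.line_stim_indices(3), -20.0)])
    # wave reaches the strip but never crosses it
    assert (movie.frames[:, 20:40, :] > -40).any()
    assert not (movie.frames[:, 45:, :] > -40).any()


# ---------------------------------------------------------------------------
# outcome classification
# ---------------------------------------------------------------------------

def test_quiescent_movie_classified_terminated():
    frames = np.full((4000, 24, 24), -81.0, np.float32)
    frames[:200] += 60.0 * np.random.default_rng(0).random((200, 24, 24)).astype(np.float32)
    movie = tissue.VoltageMovie(frames, 1.0, 0.0, 0.25)
    rep = abl.classify_outcome(movie, ablation_time=0.0)
    assert rep.outcome == "AF-terminated"
    assert rep.event_time == pytest.approx(200.0, abs=5.0)


def test_periodic_macro_reentry_classified_at_with_measured_cl():
    f = SpiralFixture(ny=32, nx=32, duration_ms=4000.0, dt_sample=2.0,
                      angular_frequency=2 * np.pi / 180.0)   # CL 180 ms
    movie, _, _ = make_spiral_movie(f)
    rep = abl.classify_outcome(movie, ablation_time=0.0)
    assert rep.outcome == "AT-converted"
    assert rep.post_cycle_length == pytest.approx(180.0, abs=4.0)


def test_irregular_activity_classified_sustained():
    rng = np.random.default_rng(4)
    frames = np.full((6000, 16, 16), -80.0, np.float32)
    # irregular activation: upstroke intervals drawn from a wide range
    for r in range(16):
        for c in range(16):
            t_up = np.cumsum(rng.uniform(80.0, 260.0, 60)).astype(int)
            for tu in t_up[t_up < 5950]:
                frames[tu:tu + 40, r, c] = 10.0
    movie = tissue.VoltageMovie(frames, 1.0, 0.0, 0.25)
    rep = abl.classify_outcome(movie, ablation_time=0.0)
    assert rep.outcome == "AF-sustained"


def test_short_follow_up_flagged_indeterminate():
    frames = np.full((300, 16, 16), -81.0, np.float32)
    movie = tissue.VoltageMovie(frames, 1.0, 0.0, 0.25)
    rep = abl.classify_outcome(movie, ablation_time=0.0)
    assert rep.outcome == "indeterminate"


def test_wave_dynamics_timecourse_structure():
    """Sliding-window areas of PS count, fast-DF, high-ShEn and short-CFAE
    are finite fractions with one row per window position."""
    t = np.arange(4000)
    sig = 100.0 * ((t % 250) < 90) - 80.0       # 4 Hz activation
    frames = np.tile(sig[:, None, None].astype(np.float32), (1, 32, 32))
    movie = tissue.VoltageMovie(frames, 1.0, 0.0, 0.25)
    tc = abl.wave_dynamics_timecourse(movie, window_ms=2500.0, hop_ms=1000.0,
                                      spacing_mm=2.0)
    n = tc["t"].size
    assert n == 2                                # windows at 0 and 1000 ms
    for key in ("ps_count", "df_area", "shen_area", "cfae_area"):
        assert tc[key].size == n
    assert np.all(tc["df_area"] >= 0) and np.all(tc["df_area"] <= 1)
    assert np.all(tc["shen_area"] >= 0) and np.all(tc["shen_area"] <= 1)
    assert np.all(tc["ps_count"] == 0)           # uniform field: no PS
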