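"""Phase mapping, PS detection/tracking, smallest circle, rotor classifier."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rotormap import fixtures as fx, rotors, tissue


def _vortex_phase(ny, nx, r0, c0, mirror=False):
    rr, cc = np.meshgrid(np.arange(ny, dtype=float),
                         np.arange(nx, dtype=float), indexing="ij")
    th = np.arctan2(rr - r0, cc - c0)
    return rotors.wrap_phase(-th if mirror else th)


def test_detect_ps_on_analytic_vortex():
    ph = _vortex_phase(40, 40, 20.2, 17.8)
    pts = rotors.detect_ps_frame(ph)
    assert len(pts) == 1
    p = pts[0]
    assert abs(p.x - 17.8) <= 1.0 and abs(p.y - 20.2) <= 1.0
    assert p.charge == 1

    mirrored = rotors.detect_ps_frame(_vortex_phase(40, 40, 20.2, 17.8,
                                                    mirror=True))
    assert len(mirrored) == 1 and mirrored[0].charge == -1


def test_detect_ps_uniform_phase_empty():
    assert rotors.detect_ps_frame(np.full((30, 30), 0.7)) == []


def test_net_topological_charge_conserved_across_pair_creation():
    """A frame with a +/- vortex pair has net charge 0; adding the pair to
    a gradient background changes total charge only by the +/-1 pair."""
    base = np.linspace(-np.pi, np.pi, 40)[None, :] * np.ones((40, 1))
    before = rotors.detect_ps_frame(rotors.wrap_phase(base))
    # fractional core positions: a singularity exactly on a node is
    # degenerate for the plaquette winding sum
    pair = (_vortex_phase(40, 40, 20.3, 12.4)
            + _vortex_phase(40, 40, 19.7, 27.6, mirror=True))
    after = rotors.detect_ps_frame(rotors.wrap_phase(pair))
    net_before = sum(p.charge for p in before)
    net_after = sum(p.charge for p in after)
    assert net_before == 0
    assert net_after == 0                       # charges only in +/- pairs
    charges = {p.charge for p in after}
    assert {1, -1} <= charges


def test_phase_of_sinusoidal_node_wraps_once_per_period():
    t = np.arange(3000)
    sig = 30 * np.sin(2 * np.pi * t / 250.0)
    frames = np.tile(sig[:, None, None].astype(np.float32), (1, 4, 4))
    movie = tissue.VoltageMovie(frames, 1.0, 0.0, 0.25)
    pm = rotors.phase_movie(movie)
    ph = pm.frames[:, 2, 2].astype(float)
    wraps = np.sum(np.abs(np.diff(ph)) > np.pi)
    assert wraps == pytest.approx(3000 / 250.0, abs=1)


def test_phase_of_constant_node_flagged_undefined():
    frames = np.zeros((2500, 4, 4), np.float32)
    frames[:, :2, :] = 30 * np.sin(np.arange(2500) / 40.0)[:, None, None]
    movie = tissue.VoltageMovie(frames, 1.0, 0.0, 0.25)
    pm = rotors.phase_movie(movie)
    assert np.isnan(pm.frames[:, 3, 3]).all()
    assert np.isfinite(pm.frames[100:-100, 0, 0]).all()


def test_phase_reconstruction_matches_constructed_spiral():
    f = fx.SpiralFixture(ny=48, nx=48, duration_ms=2000, dt_sample=5.0,
                         waveform="sinusoid")
    movie, pm_truth, truth = fx.make_spiral_movie(f)
    pm = rotors.phase_movie(movie)
    rr, cc = np.meshgrid(np.arange(48), np.arange(48), indexing="ij")
    far = np.hypot(rr - truth[0, 1], cc - truth[0, 2]) > 8
    errs = [np.sqrt(np.nanmean(rotors.wrap_phase(
        pm.frames[k] - pm_truth.frames[k])[far] ** 2))
        for k in range(80, 320)]
    assert np.mean(errs) < 0.2


def test_detect_ps_tracks_constructed_core():
    f = fx.SpiralFixture(ny=48, nx=48, duration_ms=2000, dt_sample=5.0,
                         core_track="linear", drift_mm_per_s=2.0)
    movie, pm_truth, truth = fx.make_spiral_movie(f)
    per_frame = rotors.detect_ps(pm_truth)
    hits = 0
    err2 = []
    for k, pts in enumerate(per_frame):
        if len(pts) == 1:
            hits += 1
            err2.append((pts[0].x - truth[k, 2]) ** 2
                        + (pts[0].y - truth[k, 1]) ** 2)
    assert hits / len(per_frame) >= 0.99
    assert np.sqrt(np.mean(err2)) <= 1.0


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

def test_track_single_stationary_ps():
    frames = fx.make_ps_stream([{"birth": 0, "death": 99, "x0": 10.0,
                                 "y0": 12.0, "charge": 1}], dt_sample=2.0)
    trajs = rotors.track_ps(frames, 2.0, 0.25)
    assert len(trajs) == 1
    assert trajs[0].duration == pytest.approx(99 * 2.0)


def test_crossing_paths_beyond_gate_stay_unbroken():
    # two same-charge paths crossing at > gate distance per frame
    frames = fx.make_ps_stream([
        {"birth": 0, "death": 60, "x0": 0.0, "y0": 0.0, "vx": 1.0, "vy": 0.0},
        {"birth": 0, "death": 60, "x0": 60.0, "y0": 3.0, "vx": -1.0, "vy": 0.0},
    ], dt_sample=1.0)
    trajs = rotors.track_ps(frames, 1.0, 0.25, gate_mm=0.3)
    assert len(trajs) == 2
    assert all(len(tr) == 61 for tr in trajs)


def test_gap_beyond_gate_splits_trajectory():
    frames = fx.make_ps_stream([
        {"birth": 0, "death": 30, "x0": 5.0, "y0": 5.0},
        {"birth": 32, "death": 60, "x0": 40.0, "y0": 40.0},
    ], dt_sample=1.0)
    trajs = rotors.track_ps(frames, 1.0, 0.25, gate_mm=1.0)
    assert len(trajs) == 2


def test_opposite_charge_never_linked():
    frames = fx.make_ps_stream([
        {"birth": 0, "death": 20, "x0": 5.0, "y0": 5.0, "charge": 1},
        {"birth": 21, "death": 40, "x0": 5.0, "y0": 5.0, "charge": -1},
    ], dt_sample=1.0)
    trajs = rotors.track_ps(frames, 1.0, 0.25)
    assert len(trajs) == 2
    assert {tr.charge for tr in trajs} == {1, -1}


# ---------------------------------------------------------------------------
# smallest enclosing circle
# ---------------------------------------------------------------------------

def _brute_force_sec(pts):
    """Exhaustive smallest circle over all pairs and triples (n <= 12)."""
    from itertools import combinations
    from rotormap.rotors import _circle_three, _circle_two, _in_circle

    best = None
    cands = [_circle_two(p, q) for p, q in combinations(pts, 2)]
    for tri in combinations(pts, 3):
        c = _circle_three(*tri)
        if c is not None:
            cands.append(c)
    for c in cands:
        if all(_in_circle(c, p, eps=1e-9) for p in pts):
            if best is None or c[2] < best[2]:
                best = c
    return best


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.integers(2, 12))
def test_smallest_circle_matches_brute_force(seed, n):
    pts = np.random.default_rng(seed).uniform(-10, 10, (n, 2))
    cx, cy, r = rotors.smallest_enclosing_circle(pts)
    brute = _brute_force_sec([tuple(p) for p in pts])
    assert r == pytest.approx(brute[2], rel=1e-6, abs=1e-9)
    # encloses everything
    assert np.all(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) <= r * (1 + 1e-9) + 1e-9)


# ---------------------------------------------------------------------------
# mother-rotor classification
# ---------------------------------------------------------------------------

def _traj(duration_ms, radius_mm=0.0, dx=0.25, n=200, t0=0.0):
    t = np.linspace(t0, t0 + duration_ms, n)
    ang = np.linspace(0, 6 * np.pi, n)
    x = (20.0 + radius_mm * np.cos(ang)) / dx
    y = (20.0 + radius_mm * np.sin(ang)) / dx
    return rotors.PSTrajectory(t, x, y, 1, dx)


def _external_birth(t_birth, x_mm=2.0, y_mm=2.0, dx=0.25):
    t = np.array([t_birth, t_birth + 10.0])
    return rotors.PSTrajectory(t, np.full(2, x_mm / dx), np.full(2, y_mm / dx),
                               1, dx)


def test_stationary_long_rotor_with_breakup_qualifies():
    tr = _traj(6000.0)
    others = [tr, _external_birth(3000.0)]
    m = rotors.classify_mother_rotor(tr, wavelength_mm=40.0,
                                     all_trajectories=others)
    assert m.qualifies and m.breakup_observed


def test_duration_just_below_threshold_fails():
    tr = _traj(4900.0)
    others = [tr, _external_birth(3000.0)]
    m = rotors.classify_mother_rotor(tr, 40.0, others)
    assert not m.qualifies and m.breakup_observed


def test_meander_beyond_half_wavelength_fails_confinement():
    lam = 40.0
    tr = _traj(6000.0, radius_mm=0.3 * lam)   # tip circle diameter 0.6 * lam
    others = [tr, _external_birth(3000.0)]
    m = rotors.classify_mother_rotor(tr, lam, others)
    assert not m.qualifies
    assert 2 * m.confinement_radius > lam / 2


def test_stable_reentry_without_breakup_not_a_mother_rotor():
    tr = _traj(8000.0)
    m = rotors.classify_mother_rotor(tr, 40.0, [tr])
    assert m.duration > 5000.0 and not m.breakup_observed and not m.qualifies


def test_classifier_monotone_in_confinement_and_duration():
    lam = 30.0
    others = lambda tr: [tr, _external_birth(tr.birth + tr.duration / 2)]
    prev_ok = None
    for radius in (12.0, 7.0, 3.0, 0.5):      # shrinking tip circle
        tr = _traj(6000.0, radius_mm=radius)
        ok = rotors.classify_mother_rotor(tr, lam, others(tr)).qualifies
        if prev_ok is not None:
            assert ok >= prev_ok              # never true -> false
        prev_ok = ok
    assert prev_ok                             # tightest case qualifies
    prev_ok = None
    for dur in (3000.0, 5200.0, 9000.0):      # lengthening duration
        tr = _traj(dur, radius_mm=1.0)
        ok = rotors.classify_mother_rotor(tr, lam, others(tr)).qualifies
        if prev_ok is not None:
            assert ok >= prev_ok
        prev_ok = ok


def test_invalid_wavelength_rejected():
    with pytest.raises(ValueError):
        rotors.classify_mother_rotor(_traj(6000.0), 0.0, [])
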