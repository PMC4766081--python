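"""Phase mapping, phase-singularity detection and the mother-rotor classifier.

The activation phase is the analytic-signal (Hilbert-quadrature) phase of
each node's de-meaned action potential.  A phase singularity (PS) is a
point where the phase is undefined and winds by +/-2*pi around it; it is
detected by summing wrapped phase differences around every 2x2 node
plaquette (the discrete form of the Iyer-Gray line integral).  PS points
are linked into trajectories by greedy nearest-neighbour tracking, and a
trajectory qualifies as a *mother rotor* when

* its tip stays within a circle of diameter half the pacing wavelength
  (smallest enclosing circle of the tip points),
* it lasts longer than 5 s, and
* at least one wave breakup occurs at its periphery (a PS birth outside
  the rotor area) — stable stationary reentry without peripheral breakup
  does not count.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .tissue import VoltageMovie

TWO_PI = 2.0 * np.pi
WINDING_TOL = 0.1            # |plaquette sum| within this of 2*pi
MIN_RANGE_MV = 5.0           # AP dynamic range needed for a defined phase
DEFAULT_GATE_MM_PER_MS = 2.0  # tracking gate per ms of frame spacing
MOTHER_ROTOR_MIN_MS = 5000.0  # "longer than 5 s"


@dataclass
class PhaseMovie:
    """Per-node phase in (-pi, pi]; undefined nodes are NaN."""

    frames: np.ndarray
    dt_sample: float
    t0: float = 0.0
    dx: float = 0.25

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) * self.dt_sample

    def frame_index(self, t_ms: float) -> int:
        k = int(round((t_ms - self.t0) / self.dt_sample))
        if not 0 <= k < self.n_frames:
            raise IndexError(f"no phase frame at t = {t_ms} ms")
        return k


@dataclass
class PSPoint:
    t: float        # ms
    x: float        # column, node units
    y: float        # row, node units
    charge: int     # +/-1


@dataclass
class PSTrajectory:
    """Time-ordered points of one tracked singularity."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    charge: int
    dx: float = 0.25

    @property
    def birth(self) -> float:
        return float(self.t[0])

    @property
    def death(self) -> float:
        return float(self.t[-1])

    @property
    def duration(self) -> float:
        return self.death - self.birth

    @property
    def points_mm(self) -> np.ndarray:
        return np.column_stack([self.x, self.y]) * self.dx

    def __len__(self) -> int:
        return self.t.size


@dataclass
class MotherRotor:
    """Classification of one PS trajectory against the rotor definition."""

    trajectory: PSTrajectory
    center: tuple[float, float]        # rotor-area center, mm
    radius: float                      # rotor-area radius, mm (max tip distance)
    confinement_center: tuple[float, float]  # smallest-circle center, mm
    confinement_radius: float          # smallest-circle radius, mm
    duration: float                    # ms
    wavelength: float                  # mm
    breakup_observed: bool
    qualifies: bool

    @property
    def area_mask_args(self):
        return self.center, self.radius


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.mod(np.asarray(x) + np.pi, TWO_PI) - np.pi


# ---------------------------------------------------------------------------
# Phase construction
# ---------------------------------------------------------------------------

def phase_movie(movie: VoltageMovie, min_range_mv: float = MIN_RANGE_MV,
                method: str = "hilbert", delay_ms: float = 5.0,
                block_rows: int = 16) -> PhaseMovie:
    """Analytic-signal phase of each node's de-meaned AP.

    `method` 'hilbert' (default) uses the Hilbert-transform quadrature;
    'delay' uses time-delay embedding with lag `delay_ms`
    (atan2(V(t - tau) - Vbar, V(t) - Vbar)).  Nodes with dynamic range
    below `min_range_mv` are flagged undefined (NaN).
    """
    if movie.duration < 2000.0:
        raise ValueError("phase mapping needs at least 2 s of signal")
    nt = movie.n_frames
    ny, nx = movie.shape
    out = np.empty((nt, ny, nx), dtype=np.float32)
    lag = max(int(round(delay_ms / movie.dt_sample)), 1)
    for r0 in range(0, ny, block_rows):
        block = np.asarray(movie.frames[:, r0:r0 + block_rows, :], dtype=np.float64)
        x = block - block.mean(axis=0)
        if method == "hilbert":
            ph = np.angle(hilbert(x, axis=0))
        elif method == "delay":
            xd = np.empty_like(x)
            xd[lag:] = x[:-lag]
            xd[:lag] = x[0]
            ph = np.arctan2(xd, x)
        else:
            raise ValueError(f"unknown phase method {method!r}")
        rng = block.max(axis=0) - block.min(axis=0)
        ph[:, rng < min_range_mv] = np.nan
        out[:, r0:r0 + block.shape[1], :] = ph.astype(np.float32)
    return PhaseMovie(out, movie.dt_sample, movie.t0, movie.dx)


# ---------------------------------------------------------------------------
# PS detection (plaquette winding number)
# ---------------------------------------------------------------------------

def detect_ps_frame(phase_frame: np.ndarray, t: float = 0.0,
                    tol: float = WINDING_TOL) -> list[PSPoint]:
    """PS points of one phase frame via 2x2 plaquette winding sums."""
    p = np.asarray(phase_frame, dtype=float)
    a = p[:-1, :-1]
    b = p[:-1, 1:]
    c = p[1:, 1:]
    d = p[1:, :-1]
    s = (wrap_phase(b - a) + wrap_phase(c - b)
         + wrap_phase(d - c) + wrap_phase(a - d))
    hit = np.abs(np.abs(s) - TWO_PI) < TWO_PI * tol
    hit &= np.isfinite(s)
    rr, cc = np.nonzero(hit)
    return [PSPoint(t, float(cj) + 0.5, float(ri) + 0.5,
                    int(np.sign(s[ri, cj])))
            for ri, cj in zip(rr, cc)]


def detect_ps(phase: PhaseMovie, t_ms: float | None = None,
              tol: float = WINDING_TOL):
    """PS points at one instant, or per-frame lists for the whole movie."""
    if t_ms is not None:
        k = phase.frame_index(t_ms)
        return detect_ps_frame(phase.frames[k], phase.times[k], tol)
    return [detect_ps_frame(phase.frames[k], phase.times[k], tol)
            for k in range(phase.n_frames)]


# ---------------------------------------------------------------------------
# Trajectory tracking
# ---------------------------------------------------------------------------

def track_ps(per_frame: list[list[PSPoint]], dt_sample: float,
             dx: float = 0.25, gate_mm: float | None = None,
             min_points: int = 2, max_gap_frames: int = 1) -> list[PSTrajectory]:
    """Greedy nearest-neighbour linkage of same-charge PS points.

    Candidate (trajectory, point) pairs in consecutive frames are matched
    in ascending-distance order within the gate; unmatched points open new
    trajectories.  A trajectory may coast unmatched for up to
    `max_gap_frames` frames (covering single-frame detector dropouts)
    before it closes; reappearance beyond the gate always starts a new
    trajectory.  Ties at equal distance resolve to the older trajectory
    (then lower point index).
    """
    if gate_mm is None:
        gate_mm = DEFAULT_GATE_MM_PER_MS * max(dt_sample, 1.0)
    gate_nodes = gate_mm / dx

    done: list[dict] = []
    active: list[dict] = []
    for k, pts in enumerate(per_frame):
        pairs = []
        for ti, tr in enumerate(active):
            lx, ly = tr["x"][-1], tr["y"][-1]
            for pi, p in enumerate(pts):
                if p.charge != tr["charge"]:
                    continue
                dist = np.hypot(p.x - lx, p.y - ly)
                if dist <= gate_nodes:
                    pairs.append((dist, ti, pi))
        pairs.sort(key=lambda z: (z[0], z[1], z[2]))
        used_t, used_p = set(), set()
        for dist, ti, pi in pairs:
            if ti in used_t or pi in used_p:
                continue
            used_t.add(ti)
            used_p.add(pi)
            tr = active[ti]
            p = pts[pi]
            tr["t"].append(p.t)
            tr["x"].append(p.x)
            tr["y"].append(p.y)
            tr["miss"] = 0
        still = []
        for ti, tr in enumerate(active):
            if ti in used_t:
                still.append(tr)
            else:
                tr["miss"] = tr.get("miss", 0) + 1
                if tr["miss"] <= max_gap_frames:
                    still.append(tr)
                else:
                    done.append(tr)
        active = still
        for pi, p in enumerate(pts):
            if pi not in used_p:
                active.append({"t": [p.t], "x": [p.x], "y": [p.y],
                               "charge": p.charge, "miss": 0})
    done.extend(active)

    # repair identity fragmentation: when a transient spurious pair near a
    # tip splits a chain, the fragments line up end-to-start within the
    # gate and a <= (max_gap_frames + 1)-frame time gap; merge them
    max_dt = (max_gap_frames + 1) * dt_sample + 1e-9
    done.sort(key=lambda tr: (tr["t"][0], tr["x"][0], tr["y"][0]))
    merged = True
    while merged:
        merged = False
        for i, a in enumerate(done):
            best = None
            for j, b in enumerate(done):
                if j == i or b["charge"] != a["charge"]:
                    continue
                # the split fragment may share one frame with the chain end
                gap = b["t"][0] - a["t"][-1]
                if not (-1.001 * dt_sample <= gap <= max_dt):
                    continue
                k0 = next((k for k, tb in enumerate(b["t"])
                           if tb > a["t"][-1]), None)
                if k0 is None:
                    continue
                dist = np.hypot(b["x"][k0] - a["x"][-1],
                                b["y"][k0] - a["y"][-1])
                if dist <= gate_nodes and (best is None
                                           or (dist, b["t"][0]) < best[:2]):
                    best = (dist, b["t"][0], j, k0)
            if best is not None:
                j, k0 = best[2], best[3]
                b = done[j]
                a["t"] += b["t"][k0:]
                a["x"] += b["x"][k0:]
                a["y"] += b["y"][k0:]
                del done[j]
                merged = True
                break

    out = [PSTrajectory(np.array(tr["t"]), np.array(tr["x"]),
                        np.array(tr["y"]), tr["charge"], dx)
           for tr in done if len(tr["t"]) >= min_points]
    out.sort(key=lambda tr: (tr.birth, tr.x[0], tr.y[0]))
    return out


# ---------------------------------------------------------------------------
# Smallest enclosing circle (Welzl, randomized incremental)
# ---------------------------------------------------------------------------

def _circle_two(p, q):
    cx = (p[0] + q[0]) / 2.0
    cy = (p[1] + q[1]) / 2.0
    r = np.hypot(p[0] - q[0], p[1] - q[1]) / 2.0
    return (cx, cy, r)


def _circle_three(p, q, r):
    ax, ay = p
    bx, by = q
    cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax ** 2 + ay ** 2) * (by - cy) + (bx ** 2 + by ** 2) * (cy - ay)
          + (cx ** 2 + cy ** 2) * (ay - by)) / d
    uy = ((ax ** 2 + ay ** 2) * (cx - bx) + (bx ** 2 + by ** 2) * (ax - cx)
          + (cx ** 2 + cy ** 2) * (bx - ax)) / d
    return (ux, uy, np.hypot(ax - ux, ay - uy))


def _in_circle(c, p, eps=1e-9):
    return np.hypot(p[0] - c[0], p[1] - c[1]) <= c[2] * (1 + eps) + eps


def smallest_enclosing_circle(points, seed: int = 0):
    """Exact smallest circle (cx, cy, r) containing all 2D points."""
    pts = [tuple(map(float, p)) for p in np.asarray(points, dtype=float)]
    if not pts:
        raise ValueError("no points")
    rng = random.Random(seed)
    rng.shuffle(pts)
    c = (pts[0][0], pts[0][1], 0.0)
    for i, p in enumerate(pts[1:], 1):
        if _in_circle(c, p):
            continue
        c = (p[0], p[1], 0.0)
        for j, q in enumerate(pts[:i]):
            if _in_circle(c, q):
                continue
            c = _circle_two(p, q)
            for k, s in enumerate(pts[:j]):
                if _in_circle(c, s):
                    continue
                cc = _circle_three(p, q, s)
                if cc is not None:
                    c = cc
    return c


# ---------------------------------------------------------------------------
# Mother-rotor classification
# ---------------------------------------------------------------------------

def classify_mother_rotor(traj: PSTrajectory, wavelength_mm: float,
                          all_trajectories: list[PSTrajectory] | None = None,
                          min_duration_ms: float = MOTHER_ROTOR_MIN_MS
                          ) -> MotherRotor:
    """Test one tip trajectory against the quantitative rotor definition.

    confinement: the smallest circle enclosing all tip points must have a
    diameter no larger than half the wavelength; duration must exceed
    `min_duration_ms`; and at least one other PS trajectory must be born
    outside the rotor area (mean-center, max-radius circle) while this
    rotor lives — the peripheral wave-breakup requirement.
    """
    if wavelength_mm <= 0:
        raise ValueError("wavelength must be positive")
    pts = traj.points_mm
    cx, cy = pts.mean(axis=0)
    radius = float(np.hypot(pts[:, 0] - cx, pts[:, 1] - cy).max())
    scx, scy, sr = smallest_enclosing_circle(pts)

    breakup = False
    for other in (all_trajectories or []):
        if other is traj:
            continue
        if not (traj.birth <= other.birth <= traj.death):
            continue
        bx, by = other.x[0] * other.dx, other.y[0] * other.dx
        if np.hypot(bx - cx, by - cy) > radius:
            breakup = True
            break

    confined = 2.0 * sr <= wavelength_mm / 2.0
    long_enough = traj.duration > min_duration_ms
    return MotherRotor(
        trajectory=traj,
        center=(float(cx), float(cy)),
        radius=radius,
        confinement_center=(float(scx), float(scy)),
        confinement_radius=float(sr),
        duration=traj.duration,
        wavelength=float(wavelength_mm),
        breakup_observed=breakup,
        qualifies=bool(confined and long_enough and breakup),
    )


def rotor_area_mask(rotor: MotherRotor, shape: tuple[int, int],
                    dx: float) -> np.ndarray:
    """Nodes inside the rotor-area circle (mean center, max tip distance)."""
    ny, nx = shape
    cx, cy = rotor.center
    rr, cc = np.meshgrid(np.arange(ny) * dx, np.arange(nx) * dx, indexing="ij")
    return np.hypot(cc - cx, rr - cy) <= rotor.radius


def trajectory_mask(trajs: list[PSTrajectory], shape: tuple[int, int],
                    dx: float, radius_mm: float = 0.5) -> np.ndarray:
    """Nodes within `radius_mm` of any tip point (tip-trajectory footprint)."""
    ny, nx = shape
    mask = np.zeros(shape, dtype=bool)
    r_nodes = radius_mm / dx
    ri = int(np.ceil(r_nodes))
    for tr in trajs:
        for x, y in zip(tr.x, tr.y):
            r0 = max(int(y) - ri, 0)
            r1 = min(int(y) + ri + 1, ny)
            c0 = max(int(x) - ri, 0)
            c1 = min(int(x) + ri + 1, nx)
            sub_r, sub_c = np.ogrid[r0:r1, c0:c1]
            mask[r0:r1, c0:c1] |= (np.hypot(sub_c - x, sub_r - y) <= r_nodes)
    return mask
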