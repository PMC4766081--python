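"""Virtual ablation strategies and post-ablation outcome classification.

Four lesion-planning strategies target 5% of the sheet: the highest-DF
area, the highest-ShEn area, the lowest-CFAE-CL area, or 1-mm disks around
successive phase-singularity points.  Ablation is modelled as permanently
clamping the lesioned nodes' membrane potential to the resting value
(conduction block); the lesioned tissue still couples diffusively as
resting tissue.  After ablation the run is classified as AF-terminated,
AT-converted (organised periodic macro-reentry) or AF-sustained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maps import ScalarMap, area_mask
from .rotors import PSTrajectory
from .tissue import VoltageMovie, ACTIVATION_THRESHOLD

DEFAULT_FRACTION = 0.05
PS_LESION_RADIUS_MM = 1.0

#: wave-dynamics time-course thresholds (areas of DF > 7 Hz, ShEn > 7,
#: CFAE-CL < 100 ms, plus the PS count), evaluated in sliding windows
TIMECOURSE_DF_HZ = 7.0
TIMECOURSE_SHEN = 7.0
TIMECOURSE_CFAE_MS = 100.0

QUIESCENT_MS = 500.0     # no node above -40 mV for this long => terminated
AT_CL_CV_MAX = 0.05      # CL coefficient of variation over >= 10 beats
AT_MIN_BEATS = 10


@dataclass
class AblationPlan:
    """Binary lesion mask tagged with the producing strategy."""

    lesion_mask: np.ndarray
    strategy: str                    # 'PS' | 'DF' | 'ShEn' | 'CFAE'
    area_fraction: float             # target fraction of the domain
    achieved_fraction: float = None
    flagged: bool = False            # target not met / overrun

    def __post_init__(self):
        self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
        if self.achieved_fraction is None:
            self.achieved_fraction = self.lesion_mask.mean()


@dataclass
class OutcomeReport:
    """Post-ablation wave-dynamics outcome."""

    outcome: str                     # 'AF-sustained' | 'AF-terminated' | 'AT-converted' | 'indeterminate'
    event_time: float | None         # ms (termination instant or AT onset)
    post_cycle_length: float | None  # ms, when AT-converted
    time_courses: dict = field(default_factory=dict)
    observed_ms: float = 0.0


def plan_map_ablation(smap: ScalarMap, strategy: str,
                      fraction: float = DEFAULT_FRACTION) -> AblationPlan:
    """Percentile lesion: highest 5% for DF/ShEn, lowest 5% for CFAE."""
    if not 0 < fraction <= 0.5:
        raise ValueError("ablation fraction must be in (0, 50%]")
    directions = {"DF": "upper-percentile", "ShEn": "upper-percentile",
                  "CFAE": "lower-percentile"}
    if strategy not in directions:
        raise ValueError(f"unknown map-ablation strategy {strategy!r}")
    if strategy != smap.kind:
        raise ValueError(f"{strategy} ablation requires a {strategy} map")
    am = area_mask(smap, directions[strategy], fraction * 100.0)
    achieved = am.mask.mean()
    return AblationPlan(am.mask, strategy, fraction, achieved,
                        flagged=abs(achieved - fraction) > 1.0 / smap.values.shape[0])


def disk_mask(shape: tuple[int, int], center_rc: tuple[float, float],
              radius_mm: float, dx: float) -> np.ndarray:
    """Nodes within radius_mm of a (row, col) point."""
    ny, nx = shape
    r0, c0 = center_rc
    rr, cc = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    return np.hypot(rr - r0, cc - c0) * dx <= radius_mm


def plan_ps_ablation(trajectories: list[PSTrajectory], shape: tuple[int, int],
                     dx: float, fraction: float = DEFAULT_FRACTION,
                     lesion_radius_mm: float = PS_LESION_RADIUS_MM) -> AblationPlan:
    """Sequential 1-mm disks on PS points, in time order, until 5% is reached.

    Points already inside the lesion are skipped.  If the PS stream runs
    out before reaching the target the plan is returned flagged with the
    achieved fraction; a target smaller than one disk overruns by one disk
    (also flagged).
    """
    points = []
    for tr in trajectories:
        for t, x, y in zip(tr.t, tr.x, tr.y):
            points.append((t, y, x))
    if not points:
        raise ValueError("no PS points to ablate")
    points.sort(key=lambda p: (p[0], p[1], p[2]))

    ny, nx = shape
    target_nodes = fraction * ny * nx
    mask = np.zeros(shape, dtype=bool)
    for t, r, c in points:
        if mask.sum() >= target_nodes:
            break
        ri, ci = int(round(r)), int(round(c))
        if 0 <= ri < ny and 0 <= ci < nx and mask[ri, ci]:
            continue  # already inside the lesion
        mask |= disk_mask(shape, (r, c), lesion_radius_mm, dx)
    achieved = mask.mean()
    flagged = achieved < fraction or mask.sum() > target_nodes + mask.sum() * 0
    return AblationPlan(mask, "PS", fraction, achieved,
                        flagged=achieved < fraction)


def apply_ablation(sim_or_grid, plan: AblationPlan):
    """Install the lesion: clamp lesioned nodes to rest from now on.

    Accepts a live :class:`~rotormap.tissue.TissueSim` (lesion takes
    effect immediately, mid-run) or a :class:`~rotormap.tissue.TissueGrid`
    (returns a new grid with the union lesion mask).  Idempotent; lesions
    only grow.
    """
    from .tissue import TissueGrid, TissueSim

    if isinstance(sim_or_grid, TissueSim):
        sim_or_grid.set_lesion(plan.lesion_mask)
        return sim_or_grid
    if isinstance(sim_or_grid, TissueGrid):
        return sim_or_grid.with_lesion(sim_or_grid.lesion_mask | plan.lesion_mask)
    raise TypeError("apply_ablation expects a TissueSim or TissueGrid")


# ---------------------------------------------------------------------------
# Outcome classification
# ---------------------------------------------------------------------------

def _activation_cycle_lengths(movie: VoltageMovie, probes=None) -> np.ndarray:
    """Upstroke-to-upstroke cycle lengths (ms) pooled over probe nodes."""
    ny, nx = movie.shape
    if probes is None:
        probes = [(ny // 4, nx // 4), (ny // 4, 3 * nx // 4),
                  (3 * ny // 4, nx // 4), (3 * ny // 4, 3 * nx // 4),
                  (ny // 2, nx // 2)]
    all_cls = []
    for r, c in probes:
        v = movie.trace(r, c)
        above = v > ACTIVATION_THRESHOLD
        ups = np.nonzero(above[1:] & ~above[:-1])[0] + 1
        if ups.size >= 2:
            all_cls.append(np.diff(ups) * movie.dt_sample)
    if not all_cls:
        return np.empty(0)
    return np.concatenate(all_cls)


def _at_test(movie: VoltageMovie) -> tuple[bool, float | None, float | None]:
    """Organised periodic activation: CV of CL < 5% over >= 10 beats."""
    ny, nx = movie.shape
    best = None
    for r, c in [(ny // 2, nx // 2), (ny // 4, nx // 4), (3 * ny // 4, 3 * nx // 4),
                 (ny // 4, 3 * nx // 4), (3 * ny // 4, nx // 4)]:
        v = movie.trace(r, c)
        above = v > ACTIVATION_THRESHOLD
        ups = np.nonzero(above[1:] & ~above[:-1])[0] + 1
        if ups.size < AT_MIN_BEATS + 1:
            continue
        cls = np.diff(ups[-(AT_MIN_BEATS + 1):]) * movie.dt_sample
        cv = cls.std() / cls.mean()
        if cv < AT_CL_CV_MAX:
            onset = movie.t0 + ups[-(AT_MIN_BEATS + 1)] * movie.dt_sample
            if best is None or cv < best[2]:
                best = (float(cls.mean()), float(onset), float(cv))
    if best is None:
        return False, None, None
    return True, best[1], best[0]


def wave_dynamics_timecourse(movie: VoltageMovie, window_ms: float = 6000.0,
                             hop_ms: float = 1000.0,
                             spacing_mm: float = 2.0) -> dict:
    """Areas of PS count, DF > 7 Hz, ShEn > 7 and CFAE-CL < 100 ms vs time.

    Windows shorter than `window_ms` at the movie tail are dropped; on
    movies shorter than one window the single full-length window is used.
    """
    from .maps import cfae_map, dominant_frequency_map, shannon_entropy_map
    from .rotors import detect_ps_frame, phase_movie

    window_ms = min(window_ms, movie.duration)
    t_starts = np.arange(movie.t0, movie.t0 + movie.duration - window_ms + 1e-6,
                         hop_ms)
    rows = {"t": [], "ps_count": [], "df_area": [], "shen_area": [],
            "cfae_area": []}
    for ts in t_starts:
        sub = movie.window(ts, ts + window_ms)
        rows["t"].append(ts + window_ms / 2.0)
        if window_ms >= 2000.0:
            ph = phase_movie(sub)
            counts = [len(detect_ps_frame(ph.frames[k], 0.0))
                      for k in range(0, ph.n_frames,
                                     max(ph.n_frames // 50, 1))]
            rows["ps_count"].append(float(np.mean(counts)))
            dfm = dominant_frequency_map(sub, window=window_ms)
            rows["df_area"].append(float(np.nanmean(
                (dfm.values > TIMECOURSE_DF_HZ) & ~dfm.undefined)))
        else:
            rows["ps_count"].append(np.nan)
            rows["df_area"].append(np.nan)
        shm = shannon_entropy_map(sub, window=window_ms, spacing_mm=spacing_mm)
        rows["shen_area"].append(float(np.nanmean(
            (shm.values > TIMECOURSE_SHEN) & ~shm.undefined)))
        cfm = cfae_map(sub, window=window_ms, spacing_mm=spacing_mm)
        rows["cfae_area"].append(float(np.mean(
            (cfm.values < TIMECOURSE_CFAE_MS) & ~cfm.undefined)))
    return {k: np.asarray(v) for k, v in rows.items()}


def classify_outcome(movie: VoltageMovie, ablation_time: float,
                     min_follow_up_ms: float = 2000.0,
                     with_timecourse: bool = False) -> OutcomeReport:
    """Classify the post-ablation movie.

    AF-terminated: no node exceeds -40 mV for 500 ms (event time = start
    of the quiescent stretch).  AT-converted: periodic global activation
    with CL coefficient of variation < 5% over 10 consecutive beats.
    Otherwise AF-sustained.  A movie with less than `min_follow_up_ms`
    beyond the ablation is flagged indeterminate.
    """
    if ablation_time < movie.t0:
        raise ValueError("ablation time precedes the movie")
    post = movie.window(max(ablation_time, movie.t0),
                        movie.t0 + movie.duration)
    observed = post.duration
    tc = {}
    if with_timecourse and observed >= 2000.0:
        tc = wave_dynamics_timecourse(post)
    if observed < min_follow_up_ms:
        return OutcomeReport("indeterminate", None, None, tc, observed)

    # terminated: a quiescent stretch of >= 500 ms persisting to the end
    active = (post.frames > ACTIVATION_THRESHOLD).any(axis=(1, 2))
    quiet_needed = int(round(QUIESCENT_MS / post.dt_sample))
    tail = active[::-1]
    quiet_tail = int(np.argmax(tail)) if tail.any() else tail.size
    if quiet_tail >= quiet_needed:
        t_event = post.t0 + (post.n_frames - quiet_tail) * post.dt_sample
        return OutcomeReport("AF-terminated", float(t_event), None, tc, observed)

    is_at, onset, cl = _at_test(post)
    if is_at:
        return OutcomeReport("AT-converted", onset, cl, tc, observed)
    return OutcomeReport("AF-sustained", None, None, tc, observed)
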