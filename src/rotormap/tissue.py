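"""2D monodomain tissue: grid, stimulation protocols and the PDE driver.

The tissue is a homogeneous isotropic sheet discretised on a regular grid
(default 600 x 600 nodes at 250 um; the test/analysis configurations use
smaller sheets).  The monodomain equation

    dVm/dt = Deff * Laplacian(Vm) - (Iion + Is)

is integrated with a 5-point finite-difference Laplacian, no-flux
boundaries, and the Rush-Larsen ionic kernel.  Conventions: node (row,
col) with row 0 at the line-stimulus edge, paced waves travel along
increasing row; the cross-field reset half-sheet is columns >= nx/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import ionic, kernels
from .ionic import IonicParams

#: default effective diffusivity (mm^2/ms), calibrated so the control-tissue
#: planar conduction velocity at 600-ms line pacing sits in the physiological
#: atrial range 0.4-0.6 mm/ms at dx = 0.25 mm (see calibrate_diffusivity).
DEFAULT_DEFF = 0.1

DEFAULT_DX_MM = 0.25
DEFAULT_DT_MS = 0.05

#: line-stimulus current, pA/pF (about twice diastolic threshold, 2-ms pulse)
DEFAULT_STIM_AMP = -20.0
DEFAULT_STIM_MS = 2.0

ACTIVATION_THRESHOLD = -40.0   # mV, upstroke crossing for activation times
EXCITED_THRESHOLD = -60.0      # mV, wavefront-to-waveback band for wavelength


class ConfigurationError(ValueError):
    """Invalid grid / protocol / solver configuration."""


class IntegrationError(RuntimeError):
    """The PDE integration produced a non-finite field."""

    def __init__(self, msg, t_ms=None):
        super().__init__(msg)
        self.t_ms = t_ms


class MeasurementError(RuntimeError):
    """A wave-property measurement found no usable signal."""


@dataclass
class TissueGrid:
    """Regular isotropic sheet; dx in mm, Deff in mm^2/ms."""

    nx: int = 600
    ny: int = 600
    dx: float = DEFAULT_DX_MM
    deff: float = DEFAULT_DEFF
    lesion_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.nx < 16 or self.ny < 16:
            raise ConfigurationError("grid must be at least 16 x 16 nodes")
        if self.dx <= 0 or self.deff <= 0:
            raise ConfigurationError("dx and Deff must be positive")
        if self.lesion_mask is None:
            self.lesion_mask = np.zeros((self.ny, self.nx), dtype=bool)
        else:
            self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
            if self.lesion_mask.shape != (self.ny, self.nx):
                raise ConfigurationError("lesion mask shape mismatch")

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (self.nx * self.dx, self.ny * self.dx)

    def with_lesion(self, mask: np.ndarray) -> "TissueGrid":
        return TissueGrid(self.nx, self.ny, self.dx, self.deff,
                          np.asarray(mask, dtype=bool).copy())


@dataclass
class StimulusProtocol:
    """Pacing / reentry-initiation protocol.

    kind 'line-pace': `count` line stimuli at the row-0 edge every
    `cycle_length` ms.  kind 'cross-field-reset': line pacing followed by
    resetting V to `reset_value` on columns >= nx/2 when the last paced
    wave reaches `reset_at_row_fraction` of the sheet — either its
    wavefront (reset_mode 'front') or its repolarisation tail
    (reset_mode 'tail', i.e. against the repolarising wave).  kind
    'none': no stimulation.
    """

    kind: str = "line-pace"
    cycle_length: float = 600.0
    count: int = 2
    amplitude: float = DEFAULT_STIM_AMP
    pulse_ms: float = DEFAULT_STIM_MS
    line_rows: int = 3
    reset_value: float = 0.0
    reset_at_row_fraction: float = 0.5
    reset_mode: str = "front"

    def __post_init__(self):
        if self.kind not in ("line-pace", "cross-field-reset", "none"):
            raise ConfigurationError(f"unknown protocol kind {self.kind!r}")
        if self.reset_mode not in ("front", "tail"):
            raise ConfigurationError(f"unknown reset mode {self.reset_mode!r}")
        if self.kind != "none" and self.cycle_length <= 0:
            raise ConfigurationError("cycle length must be positive")


@dataclass
class VoltageMovie:
    """Uniformly sampled membrane-potential field, frames (nt, ny, nx) in mV."""

    frames: np.ndarray
    dt_sample: float
    t0: float = 0.0
    dx: float = DEFAULT_DX_MM
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ConfigurationError("movie frames must be (nt, ny, nx)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.dt_sample

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) * self.dt_sample

    def frame_at(self, t_ms: float) -> np.ndarray:
        k = int(round((t_ms - self.t0) / self.dt_sample))
        if not 0 <= k < self.n_frames:
            raise IndexError(f"no frame at t = {t_ms} ms")
        return self.frames[k]

    def trace(self, row: int, col: int) -> np.ndarray:
        return np.asarray(self.frames[:, row, col], dtype=float)

    def window(self, t_start: float, t_stop: float) -> "VoltageMovie":
        i0 = int(round((t_start - self.t0) / self.dt_sample))
        i1 = int(round((t_stop - self.t0) / self.dt_sample)) + 1
        i0 = max(i0, 0)
        if i1 <= i0:
            raise ConfigurationError("empty movie window")
        return VoltageMovie(self.frames[i0:i1], self.dt_sample,
                            self.t0 + i0 * self.dt_sample, self.dx, dict(self.meta))

    def save(self, path) -> None:
        from . import io
        io.save_movie(self, path)

    @classmethod
    def load(cls, path) -> "VoltageMovie":
        from . import io
        return io.load_movie(path)


class TissueSim:
    """Stateful monodomain integrator over a :class:`TissueGrid`.

    Supports mid-run interventions (cross-field reset, ablation) and
    incremental recording, which the higher-level :func:`simulate` and the
    ablation workflow drive.
    """

    def __init__(self, grid: TissueGrid, params: IonicParams,
                 dt: float = DEFAULT_DT_MS, y0: np.ndarray | None = None,
                 nernst_every: int = 10):
        cfl = grid.dx ** 2 / (4.0 * grid.deff)
        if dt > 0.8 * cfl:
            raise ConfigurationError(
                f"explicit diffusion unstable: dt={dt} > 0.8*dx^2/(4*Deff)={0.8 * cfl:.4f}")
        self.grid = grid
        self.params = params
        self.dt = float(dt)
        self.t = 0.0
        self.nernst_every = int(nernst_every)
        y0 = ionic.RESTING_STATE if y0 is None else y0
        self.v_rest = float(y0[0])
        self.V, self.G = kernels.initial_grid_state(grid.ny, grid.nx, y0)
        n = grid.ny * grid.nx
        self.EN = np.zeros((n, 4))
        self._lap = np.zeros((grid.ny, grid.nx))
        self._lesion = np.ascontiguousarray(
            grid.lesion_mask.reshape(n).astype(np.uint8))
        self._tab, self._prm, self._fntab = kernels.build_tables(params, self.dt)
        self._cdiff = grid.deff / grid.dx ** 2
        self._no_stim = np.empty(0, dtype=np.int64)
        # clamp any pre-existing lesion immediately
        self.V.reshape(n)[self._lesion.astype(bool)] = self.v_rest

    def snapshot(self) -> dict:
        """Copy of the full dynamic state, for branching continuation runs."""
        return {"V": self.V.copy(), "G": self.G.copy(), "EN": self.EN.copy(),
                "t": self.t, "lesion": self.grid.lesion_mask.copy()}

    def restore(self, snap: dict) -> None:
        self.V[...] = snap["V"]
        self.G[...] = snap["G"]
        self.EN[...] = snap["EN"]
        self.t = snap["t"]
        self.grid.lesion_mask = snap["lesion"].copy()
        self._lesion = np.ascontiguousarray(
            self.grid.lesion_mask.reshape(self.grid.ny * self.grid.nx
                                          ).astype(np.uint8))

    # -- interventions ----------------------------------------------------

    def set_lesion(self, mask: np.ndarray) -> None:
        """Union the lesion with `mask` and clamp those nodes to rest."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.V.shape:
            raise ConfigurationError("lesion mask shape mismatch")
        self.grid.lesion_mask |= mask
        n = mask.size
        self._lesion = np.ascontiguousarray(
            self.grid.lesion_mask.reshape(n).astype(np.uint8))
        self.V[self.grid.lesion_mask] = self.v_rest

    def line_stim_indices(self, rows: int = 3) -> np.ndarray:
        nx = self.grid.nx
        idx = np.concatenate([np.arange(nx) + r * nx for r in range(rows)])
        return np.ascontiguousarray(idx.astype(np.int64))

    def cross_field_reset(self, value: float = 0.0) -> int:
        """Set V to `value` on the half-sheet columns >= nx/2.

        Requires a wave in flight (some node above the activation
        threshold); returns the number of nodes modified.
        """
        if not np.any(self.V > ACTIVATION_THRESHOLD):
            raise ConfigurationError(
                "cross-field reset requires a propagating wave "
                "(no node above -40 mV)")
        half = self.grid.nx // 2
        self.V[:, half:] = value
        self.V[self.grid.lesion_mask] = self.v_rest
        return self.grid.ny * (self.grid.nx - half)

    # -- integration ------------------------------------------------------

    def advance(self, duration_ms: float, stim_idx: np.ndarray | None = None,
                stim_amp: float = 0.0) -> None:
        """Advance without recording; stimulus applied for the whole span."""
        nsteps = int(round(duration_ms / self.dt))
        idx = self._no_stim if stim_idx is None or stim_amp == 0.0 else stim_idx
        bad = kernels.advance(self.V, self.G, self.EN, self._lesion, self._tab,
                              self._fntab, self._prm, self.dt, nsteps,
                              self._cdiff, idx, stim_amp, self.v_rest,
                              self.nernst_every, self._lap)
        if bad >= 0:
            t_fail = self.t + bad * self.dt
            raise IntegrationError(
                f"non-finite membrane potential at t = {t_fail:.2f} ms", t_fail)
        self.t += nsteps * self.dt

    def run_recorded(self, duration_ms: float, sampling_ms: float = 1.0,
                     stim_schedule=None) -> VoltageMovie:
        """Advance `duration_ms`, recording every `sampling_ms`.

        `stim_schedule` is a list of (t_on, t_off, indices, amplitude)
        relative to the current time.
        """
        n_rec = int(round(duration_ms / sampling_ms))
        frames = np.empty((n_rec + 1, self.grid.ny, self.grid.nx),
                          dtype=np.float32)
        frames[0] = self.V
        t0 = self.t
        schedule = stim_schedule or []
        for k in range(n_rec):
            seg_a = k * sampling_ms
            seg_b = (k + 1) * sampling_ms
            # split the segment at stimulus boundaries
            cuts = {seg_a, seg_b}
            for (on, off, _, _) in schedule:
                for c in (on, off):
                    if seg_a < c < seg_b:
                        cuts.add(c)
            cuts = sorted(cuts)
            for a, b in zip(cuts[:-1], cuts[1:]):
                idx, amp = None, 0.0
                for (on, off, sidx, samp) in schedule:
                    if on <= a < off:
                        idx, amp = sidx, samp
                        break
                self.advance(b - a, idx, amp)
            frames[k + 1] = self.V
        return VoltageMovie(frames, sampling_ms, t0, self.grid.dx,
                            {"preset": self.params.name,
                             "deff": self.grid.deff})

    def front_row(self, col: int | None = None) -> int:
        """Largest row index whose node (at `col`) is above threshold, or -1."""
        col = self.grid.nx // 4 if col is None else col
        above = np.nonzero(self.V[:, col] > ACTIVATION_THRESHOLD)[0]
        return int(above.max()) if above.size else -1

    def tail_row(self, col: int | None = None) -> int:
        """Smallest row index whose node (at `col`) is above threshold, or -1.

        Once the paced band lifts off the stimulus edge this is the
        repolarisation tail of the wave."""
        col = self.grid.nx // 4 if col is None else col
        above = np.nonzero(self.V[:, col] > ACTIVATION_THRESHOLD)[0]
        return int(above.min()) if above.size else -1


def pacing_schedule(sim: TissueSim, protocol: StimulusProtocol):
    idx = sim.line_stim_indices(protocol.line_rows)
    return [(k * protocol.cycle_length,
             k * protocol.cycle_length + protocol.pulse_ms,
             idx, protocol.amplitude)
            for k in range(protocol.count)]


def simulate(grid: TissueGrid, params: IonicParams, protocol: StimulusProtocol,
             duration: float, sampling: float = 1.0,
             dt: float = DEFAULT_DT_MS,
             sim_out: list | None = None) -> VoltageMovie:
    """Run a full protocol and return the sampled movie.

    For 'cross-field-reset' the reset fires when the last paced wavefront
    reaches `reset_at_row_fraction` of the sheet; the movie covers the
    whole run (pacing phase included).  If `sim_out` is given the live
    :class:`TissueSim` is appended to it so callers can continue the run.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    sim = TissueSim(grid, params, dt=dt)
    if sim_out is not None:
        sim_out.append(sim)

    if protocol.kind == "none":
        return sim.run_recorded(duration, sampling)

    schedule = pacing_schedule(sim, protocol)
    if protocol.kind == "line-pace":
        return sim.run_recorded(duration, sampling, schedule)

    # cross-field-reset: pace, watch the last wavefront, reset, continue
    last_onset = (protocol.count - 1) * protocol.cycle_length
    pieces = []
    t_pace_end = min(last_onset + protocol.pulse_ms + 1.0, duration)
    pieces.append(sim.run_recorded(t_pace_end, sampling, schedule))
    target_row = int(protocol.reset_at_row_fraction * grid.ny)
    # march in sampling-sized steps until the wave reaches the target row
    t_limit = duration
    while sim.t - pieces[0].t0 < t_limit:
        marker = (sim.front_row() if protocol.reset_mode == "front"
                  else sim.tail_row())
        if marker >= target_row:
            break
        pieces.append(sim.run_recorded(sampling, sampling))
    else:
        raise ConfigurationError(
            "paced wavefront never reached the reset row; cannot initiate reentry")
    sim.cross_field_reset(protocol.reset_value)
    remaining = duration - (sim.t - pieces[0].t0)
    if remaining > 0:
        pieces.append(sim.run_recorded(remaining, sampling))
    frames = np.concatenate([pieces[0].frames]
                            + [p.frames[1:] for p in pieces[1:]], axis=0)
    movie = VoltageMovie(frames, sampling, pieces[0].t0, grid.dx,
                         {"preset": params.name, "deff": grid.deff,
                          "reset_t": sim.t - remaining})
    return movie


def initiate_reentry(sim: TissueSim, reset_value: float = 0.0) -> int:
    """Cross-field reset on a live simulation (columns >= nx/2 to 0 mV)."""
    return sim.cross_field_reset(reset_value)


# ---------------------------------------------------------------------------
# Wave-property measurements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConductionMeasurement:
    cv: float            # mm/ms
    wavelength: float    # mm
    truncated: bool      # True when the excited band never fit in the sheet


def activation_times(movie: VoltageMovie, threshold: float = ACTIVATION_THRESHOLD,
                     t_after: float = 0.0) -> np.ndarray:
    """First upward threshold crossing (ms, movie time) per node; NaN if none."""
    frames = movie.frames
    k0 = int(np.ceil(max(t_after - movie.t0, 0.0) / movie.dt_sample))
    above = frames[k0:] > threshold
    rising = above[1:] & ~above[:-1]
    first = np.argmax(rising, axis=0)
    any_rise = rising.any(axis=0)
    # include nodes already above at k0 that were stimulated right at k0
    times = movie.t0 + (k0 + first + 1) * movie.dt_sample
    return np.where(any_rise, times, np.nan)


def measure_cv_and_wavelength(movie: VoltageMovie, pacing_cl: float = 600.0,
                              beat_index: int = -1) -> ConductionMeasurement:
    """Planar-wave conduction velocity and wavelength from a line-paced movie.

    CV comes from a least-squares fit of activation time against distance
    along the propagation (row) axis in the middle of the sheet; the
    wavelength is the spatial extent of the band with V >= -60 mV along
    the propagation axis, averaged over >= 3 mid-crossing instants.
    """
    ny, nx = movie.shape
    n_beats = max(int(np.floor((movie.duration - 1.0) / pacing_cl)), 1)
    beat = n_beats - 1 if beat_index == -1 else beat_index
    t_beat = movie.t0 + beat * pacing_cl

    at = activation_times(movie, t_after=t_beat)
    col = nx // 2
    rows = np.arange(int(0.15 * ny), int(0.85 * ny))
    t_act = at[rows, col]
    good = np.isfinite(t_act)
    if good.sum() < max(10, rows.size // 4):
        raise MeasurementError("no propagating planar wave detected")
    slope = np.polyfit(rows[good] * movie.dx, t_act[good], 1)[0]
    if slope <= 0:
        raise MeasurementError("activation does not advance along the sheet")
    cv = 1.0 / slope

    # wavelength: excited-band extent at instants while the wave crosses
    widths = []
    truncated = False
    for k in range(movie.n_frames):
        t = movie.t0 + k * movie.dt_sample
        if t <= t_beat:
            continue
        band = movie.frames[k, :, col] >= EXCITED_THRESHOLD
        if not band.any():
            continue
        r_lo, r_hi = np.nonzero(band)[0][[0, -1]]
        interior = r_lo > 0 and r_hi < ny - 1
        if not interior:
            continue
        widths.append((r_hi - r_lo + 1) * movie.dx)
    if len(widths) < 3:
        # band never fully inside the sheet: report the largest extent seen
        truncated = True
        for k in range(movie.n_frames):
            t = movie.t0 + k * movie.dt_sample
            if t <= t_beat:
                continue
            band = movie.frames[k, :, col] >= EXCITED_THRESHOLD
            if band.any():
                r_lo, r_hi = np.nonzero(band)[0][[0, -1]]
                widths.append((r_hi - r_lo + 1) * movie.dx)
        if not widths:
            raise MeasurementError("no excited band found for wavelength")
        wavelength = float(np.max(widths))
    else:
        wavelength = float(np.mean(widths))
    return ConductionMeasurement(float(cv), wavelength, truncated)


def calibrate_diffusivity(params: IonicParams, target_cv: float = 0.45,
                          deff0: float = DEFAULT_DEFF, n_iter: int = 3,
                          strip=(160, 24), dx: float = DEFAULT_DX_MM,
                          pacing_cl: float = 600.0) -> float:
    """Deff giving the target planar CV at 600-ms line pacing (strip run).

    Uses the CV ~ sqrt(Deff) diffusion scaling to update between runs.
    """
    deff = deff0
    for _ in range(n_iter):
        grid = TissueGrid(nx=strip[1], ny=strip[0], dx=dx, deff=deff)
        protocol = StimulusProtocol(kind="line-pace", cycle_length=pacing_cl,
                                    count=2)
        movie = simulate(grid, params, protocol,
                         duration=pacing_cl + 0.6 * strip[0] * dx / 0.3,
                         sampling=1.0)
        cv = measure_cv_and_wavelength(movie, pacing_cl).cv
        deff *= (target_cv / cv) ** 2
    return float(deff)
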