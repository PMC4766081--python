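"""Analytic and stochastic test fixtures for the analysis stages.

Every fixture returns its own ground truth so each detector (phase, PS,
DF, ShEn, CFAE, tracking, rotor classification) can be validated without
running the PDE.  Spiral fixtures generate Archimedean-spiral phase
fields mapped through an AP-like waveform; electrogram fixtures
superpose biphasic deflection templates at prescribed intervals;
PS-stream fixtures emit point streams with known trajectory
segmentation.  All randomness is seed-controlled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .electrogram import Electrogram
from .rotors import PSPoint, PhaseMovie, wrap_phase
from .tissue import VoltageMovie


@dataclass
class SpiralFixture:
    """Prescribed rotating spiral on a grid.

    core_track: 'stationary', 'circular' (meander radius `meander_mm`),
    or 'linear' (drift at `drift_mm_per_s` along +x).  Angular frequency
    in rad/ms, wavelength in mm.
    """

    ny: int = 64
    nx: int = 64
    dx: float = 0.25
    duration_ms: float = 2000.0
    dt_sample: float = 5.0
    angular_frequency: float = 2 * np.pi * 8e-3   # rad/ms (8 Hz)
    wavelength_mm: float = 12.0
    core_track: str = "stationary"
    core0: tuple[float, float] | None = None      # (row, col), node units
    meander_mm: float = 3.0
    meander_freq: float = 2 * np.pi * 1e-3        # rad/ms
    drift_mm_per_s: float = 4.0
    waveform: str = "ap"                          # 'ap' or 'sinusoid'

    def __post_init__(self):
        if self.wavelength_mm < 4 * self.dx:
            raise ValueError("spiral wavelength below 4 grid spacings (aliased)")
        if self.core0 is None:
            self.core0 = (self.ny / 2.0, self.nx / 2.0)

    def core_at(self, t_ms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Ground-truth core (row, col) in node units at each time."""
        t = np.asarray(t_ms, dtype=float)
        r0, c0 = self.core0
        if self.core_track == "stationary":
            return np.full_like(t, r0), np.full_like(t, c0)
        if self.core_track == "circular":
            rad = self.meander_mm / self.dx
            return (r0 + rad * np.sin(self.meander_freq * t),
                    c0 + rad * np.cos(self.meander_freq * t))
        if self.core_track == "linear":
            v = self.drift_mm_per_s / 1000.0 / self.dx   # nodes per ms
            return np.full_like(t, r0), c0 + v * t
        raise ValueError(f"unknown core track {self.core_track!r}")


def ap_waveform(phase: np.ndarray, v_rest: float = -80.0, v_peak: float = 20.0,
                upstroke_frac: float = 0.05, plateau_frac: float = 0.45
                ) -> np.ndarray:
    """Map phase in [0, 2*pi) onto an AP-like shape (sharp upstroke,
    plateau, smooth repolarisation) rather than a sinusoid, so spectral
    and phase analyses see realistic asymmetric signals."""
    ph = np.mod(phase, 2 * np.pi) / (2 * np.pi)     # [0, 1)
    amp = v_peak - v_rest
    up_end = upstroke_frac
    plat_end = upstroke_frac + plateau_frac
    v = np.empty_like(ph)
    rising = ph < up_end
    v[rising] = v_rest + amp * (ph[rising] / up_end)
    plat = (ph >= up_end) & (ph < plat_end)
    v[plat] = v_peak - 0.15 * amp * (ph[plat] - up_end) / (plat_end - up_end)
    rep = ph >= plat_end
    s = (ph[rep] - plat_end) / (1.0 - plat_end)
    v[rep] = v_rest + (0.85 * amp) * 0.5 * (1 + np.cos(np.pi * s))
    return v


def make_spiral_movie(f: SpiralFixture) -> tuple[VoltageMovie, PhaseMovie, np.ndarray]:
    """Voltage movie + ground-truth phase movie + core track (t, row, col).

    phi(x, t) = theta(x - core(t)) - k*r + omega*t (Archimedean spiral),
    so every frame contains exactly one singularity at the prescribed core.
    """
    nt = int(round(f.duration_ms / f.dt_sample)) + 1
    t = np.arange(nt) * f.dt_sample
    rows, cols = np.meshgrid(np.arange(f.ny, dtype=float),
                             np.arange(f.nx, dtype=float), indexing="ij")
    k = 2 * np.pi / (f.wavelength_mm / f.dx)      # rad per node
    core_r, core_c = f.core_at(t)
    frames = np.empty((nt, f.ny, f.nx), dtype=np.float32)
    phases = np.empty((nt, f.ny, f.nx), dtype=np.float32)
    for i in range(nt):
        dy = rows - core_r[i]
        dc = cols - core_c[i]
        theta = np.arctan2(dy, dc)
        r = np.hypot(dy, dc)
        phi = theta - k * r + f.angular_frequency * t[i]
        phases[i] = wrap_phase(phi).astype(np.float32)
        if f.waveform == "sinusoid":
            # analytic-signal phase of cos(phi) recovers phi exactly
            frames[i] = (-30.0 + 50.0 * np.cos(phi)).astype(np.float32)
        else:
            frames[i] = ap_waveform(phi).astype(np.float32)
    movie = VoltageMovie(frames, f.dt_sample, 0.0, f.dx,
                         {"fixture": "spiral", "core_track": f.core_track})
    pm = PhaseMovie(phases, f.dt_sample, 0.0, f.dx)
    truth = np.column_stack([t, core_r, core_c])
    return movie, pm, truth


@dataclass
class EgmFixture:
    """Deflection train with prescribed inter-deflection intervals.

    Deflections are biphasic (derivative-of-Gaussian) templates of width
    `width_ms`; amplitude and timing jitter are seed-controlled.
    """

    intervals_ms: tuple | list = (150.0,) * 39
    width_ms: float = 8.0
    amplitude_mv: float = 1.0
    amplitude_jitter: float = 0.0
    timing_jitter_ms: float = 0.0
    dt_sample: float = 1.0
    pad_ms: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if np.any(np.asarray(self.intervals_ms) <= 0):
            raise ValueError("intervals must be positive")
        if np.any(np.asarray(self.intervals_ms) < self.width_ms):
            raise ValueError("deflection templates overlap at this interval")


def make_egm(f: EgmFixture) -> tuple[Electrogram, np.ndarray]:
    """Synthesize the electrogram; returns (egm, ground-truth deflection times)."""
    rng = np.random.default_rng(f.seed)
    times = f.pad_ms + np.concatenate([[0.0], np.cumsum(f.intervals_ms)])
    times = times + rng.normal(0.0, f.timing_jitter_ms, times.size)
    amps = f.amplitude_mv * (1.0 + rng.normal(0.0, f.amplitude_jitter, times.size))
    total = times[-1] + f.pad_ms
    t = np.arange(0.0, total, f.dt_sample)
    sig = np.zeros_like(t)
    s = f.width_ms / 4.0
    for tc, a in zip(times, amps):
        arg = (t - tc) / s
        sig += -a * arg * np.exp(-0.5 * arg ** 2)   # biphasic deflection
    return Electrogram(sig, f.dt_sample, None, 0.0), times


def make_ps_stream(paths: list[dict], dt_sample: float = 1.0,
                   n_frames: int | None = None) -> list[list[PSPoint]]:
    """Per-frame PS point lists from a birth/death schedule.

    Each path: {'birth': frame, 'death': frame (inclusive), 'x0', 'y0',
    'vx', 'vy' (nodes/frame), 'charge'}.  Ground truth is the path list
    itself.
    """
    if n_frames is None:
        n_frames = max(p["death"] for p in paths) + 1
    frames: list[list[PSPoint]] = [[] for _ in range(n_frames)]
    for p in paths:
        for k in range(p["birth"], min(p["death"], n_frames - 1) + 1):
            dtk = k - p["birth"]
            frames[k].append(PSPoint(
                t=k * dt_sample,
                x=p["x0"] + p.get("vx", 0.0) * dtk,
                y=p["y0"] + p.get("vy", 0.0) * dtk,
                charge=p.get("charge", 1),
            ))
    return frames
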