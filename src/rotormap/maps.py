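"""Wave-dynamics parameter maps: DF, Shannon entropy, CFAE cycle length.

Per-node dominant frequency comes from the power spectrum of each node's
action potential; ShEn and CFAE-CL are electrogram statistics computed on
a bipolar-electrode tiling and painted back onto the node grid.  The
module also builds the thresholded / percentile "area" masks and the
pairwise spatial-overlap statistics used to compare the rotor with each
parameter map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .electrogram import Electrogram, EgmTiling, egm_grid
from .tissue import VoltageMovie

DF_BAND_HZ = (0.5, 20.0)        # search band for the dominant frequency
DF_RESOLUTION_HZ = 0.05         # zero-padded bin spacing
SHEN_BINS = 50                  # amplitude-histogram bins
SHEN_CLIP_SD = 3.0              # histogram range: +/- 3 SD around the mean
CFAE_DEPTH_FRACTION = 0.2       # minima must reach 20% of the deepest dV/dt
CFAE_REFRACTORY_MS = 30.0       # minimum separation of detected deflections
ANALYSIS_WINDOW_MS = 6000.0     # standard mapping window


class ResolutionError(ValueError):
    """Analysis window too short for the requested spectral resolution."""


@dataclass
class ScalarMap:
    """Per-node scalar field with an undefined-node mask.

    kind 'DF' (Hz), 'ShEn' (bits) or 'CFAE' (ms).  Undefined nodes are
    NaN in `values` and True in `undefined` — never silently zero.
    """

    values: np.ndarray
    kind: str
    window: float
    undefined: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.undefined is None:
            self.undefined = ~np.isfinite(self.values)
        self.undefined = np.asarray(self.undefined, dtype=bool)
        if self.kind not in ("DF", "ShEn", "CFAE"):
            raise ValueError(f"unknown map kind {self.kind!r}")
        finite = self.values[~self.undefined]
        if self.kind == "DF" and finite.size and np.any(finite < 0):
            raise ValueError("negative dominant frequency")
        if self.kind == "ShEn" and finite.size and np.any(finite < -1e-12):
            raise ValueError("negative entropy")
        if self.kind == "CFAE" and finite.size and np.any(finite <= 0):
            raise ValueError("non-positive CFAE cycle length")


@dataclass
class AreaMask:
    """Binary region from a threshold or percentile rule on a ScalarMap."""

    mask: np.ndarray
    rule: str
    source_kind: str

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    @property
    def fraction(self) -> float:
        return self.count / self.mask.size


@dataclass(frozen=True)
class OverlapResult:
    """Percent of mask A covered by mask B plus the 2x2 node contingency."""

    percent: float
    counts: tuple[int, int, int, int]   # (A&B, A&~B, ~A&B, ~A&~B)
    p_value: float
    defined: bool = True


# ---------------------------------------------------------------------------
# Dominant frequency
# ---------------------------------------------------------------------------

def _df_of_block(x: np.ndarray, fs_hz: float, nfft: int,
                 band: tuple[float, float]) -> np.ndarray:
    """Argmax-power frequency per row of a (n_signals, n_samples) block."""
    x = x - x.mean(axis=-1, keepdims=True)
    win = np.hanning(x.shape[-1]).astype(x.dtype)
    spec = sp_fft.rfft(x * win, n=nfft, axis=-1)
    power = np.abs(spec) ** 2
    freqs = sp_fft.rfftfreq(nfft, d=1.0 / fs_hz)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    idx = np.argmax(power[..., sel], axis=-1)
    return freqs[sel][idx]


def dominant_frequency(signal: np.ndarray, dt_ms: float,
                       band: tuple[float, float] = DF_BAND_HZ) -> float:
    """DF (Hz) of a single de-meaned, Hann-windowed signal."""
    n = signal.size
    fs = 1000.0 / dt_ms
    nfft = _df_nfft(n, fs)
    return float(_df_of_block(np.asarray(signal, float)[None, :], fs, nfft, band)[0])


def _df_nfft(n: int, fs_hz: float) -> int:
    target = int(np.ceil(fs_hz / DF_RESOLUTION_HZ))
    return sp_fft.next_fast_len(max(n, target))


def dominant_frequency_map(movie: VoltageMovie, window: float = ANALYSIS_WINDOW_MS,
                           band: tuple[float, float] = DF_BAND_HZ,
                           min_range_mv: float = 5.0,
                           block_rows: int = 16) -> ScalarMap:
    """Per-node DF over the trailing `window` ms of the movie.

    Nodes whose AP dynamic range is below `min_range_mv` (quiescent or
    ablated tissue) are flagged undefined.
    """
    if window > movie.duration + movie.dt_sample:
        raise ResolutionError("analysis window longer than the movie")
    if window < 2000.0:
        raise ResolutionError("DF window shorter than 2 s")
    nt = int(round(window / movie.dt_sample))
    frames = movie.frames[-nt:]
    ny, nx = movie.shape
    fs = 1000.0 / movie.dt_sample
    nfft = _df_nfft(nt, fs)

    values = np.full((ny, nx), np.nan)
    for r0 in range(0, ny, block_rows):
        block = np.asarray(frames[:, r0:r0 + block_rows, :], dtype=np.float64)
        nb = block.shape[1]
        flat = block.transpose(1, 2, 0).reshape(nb * nx, nt)
        rng = flat.max(axis=1) - flat.min(axis=1)
        df = _df_of_block(flat, fs, nfft, band)
        df[rng < min_range_mv] = np.nan
        values[r0:r0 + nb] = df.reshape(nb, nx)
    return ScalarMap(values, "DF", window)


# ---------------------------------------------------------------------------
# Shannon entropy
# ---------------------------------------------------------------------------

def shannon_entropy(egm: Electrogram | np.ndarray, bins: int = SHEN_BINS,
                    clip_sd: float = SHEN_CLIP_SD) -> float:
    """Amplitude-histogram Shannon entropy (bits) of a bipolar electrogram.

    The signal's amplitude distribution is histogrammed over mean +/-
    `clip_sd` standard deviations in `bins` uniform bins; ShEn =
    -sum p_i log2 p_i over the occupied bins.  A zero-variance signal has
    a single occupied bin and entropy 0.
    """
    x = egm.signal if isinstance(egm, Electrogram) else np.asarray(egm, float)
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    mu = float(np.mean(x))
    lo, hi = mu - clip_sd * sd, mu + clip_sd * sd
    counts, _ = np.histogram(np.clip(x, lo, hi), bins=bins, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# CFAE cycle length
# ---------------------------------------------------------------------------

def cfae_deflection_times(egm: Electrogram,
                          depth_fraction: float = CFAE_DEPTH_FRACTION,
                          refractory_ms: float = CFAE_REFRACTORY_MS) -> np.ndarray:
    """Times (ms) of local minima of d(signal)/dt below the depth threshold."""
    dv = np.gradient(egm.signal, egm.dt_sample)
    deepest = dv.min()
    if deepest >= 0:
        return np.empty(0)
    height = -depth_fraction * deepest  # find_peaks works on -dv
    distance = max(int(round(refractory_ms / egm.dt_sample)), 1)
    peaks, _ = sp_signal.find_peaks(-dv, height=height, distance=distance)
    return egm.t0 + peaks * egm.dt_sample


def cfae_cycle_length(egm: Electrogram, window: float = ANALYSIS_WINDOW_MS,
                      depth_fraction: float = CFAE_DEPTH_FRACTION,
                      refractory_ms: float = CFAE_REFRACTORY_MS) -> float:
    """Mean interval (ms) between consecutive dV/dt minima over `window`.

    Returns NaN (undefined) when fewer than two deflections are detected —
    e.g. on flat or quiescent signals.
    """
    n = int(round(window / egm.dt_sample)) + 1
    sub = Electrogram(egm.signal[-n:], egm.dt_sample, egm.spec,
                      egm.t0 + max(egm.signal.size - n, 0) * egm.dt_sample)
    if np.ptp(sub.signal) == 0:
        return float("nan")
    t = cfae_deflection_times(sub, depth_fraction, refractory_ms)
    if t.size < 2:
        return float("nan")
    return float(np.mean(np.diff(t)))


def shannon_entropy_map(movie: VoltageMovie, window: float = ANALYSIS_WINDOW_MS,
                        spacing_mm: float = 2.0,
                        tiling: EgmTiling | None = None) -> ScalarMap:
    """ShEn of the bipolar electrogram per tile, painted per node."""
    sub = movie.window(movie.t0 + movie.duration - window, movie.t0 + movie.duration)
    tiling = tiling or egm_grid(sub, spacing_mm)
    vals = np.array([shannon_entropy(e) for e in tiling.egms])
    return ScalarMap(tiling.paint(vals), "ShEn", window)


def cfae_map(movie: VoltageMovie, window: float = ANALYSIS_WINDOW_MS,
             spacing_mm: float = 2.0,
             tiling: EgmTiling | None = None) -> ScalarMap:
    """CFAE-CL of the bipolar electrogram per tile, painted per node."""
    sub = movie.window(movie.t0 + movie.duration - window, movie.t0 + movie.duration)
    tiling = tiling or egm_grid(sub, spacing_mm)
    vals = np.array([cfae_cycle_length(e, window) for e in tiling.egms])
    return ScalarMap(tiling.paint(vals), "CFAE", window)


# ---------------------------------------------------------------------------
# Area masks and overlaps
# ---------------------------------------------------------------------------

def area_mask(smap: ScalarMap, rule: str, value: float) -> AreaMask:
    """Binary area from a rule on the map.

    rule 'threshold-above': nodes with map > value (e.g. DF > 9 Hz);
    rule 'upper-percentile' / 'lower-percentile': the `value`% of defined
    nodes with the highest / lowest map values.  Percentile ties are
    broken deterministically by row-major node index.
    """
    vals = smap.values
    defined = ~smap.undefined
    if rule == "threshold-above":
        mask = defined & (vals > value)
        return AreaMask(mask, f"{smap.kind}>{value:g}", smap.kind)
    if rule not in ("upper-percentile", "lower-percentile"):
        raise ValueError(f"unknown rule {rule!r}")
    if not 0 < value < 100:
        raise ValueError("percentile must be in (0, 100)")
    n_target = int(round(value / 100.0 * vals.size))
    flat = vals.ravel().copy()
    flat[~defined.ravel()] = np.nan
    order_vals = -flat if rule == "upper-percentile" else flat
    # NaNs sort last under stable mergesort with this key construction
    key = np.where(np.isfinite(order_vals), order_vals, np.inf)
    order = np.argsort(key, kind="stable")
    chosen = order[:n_target]
    chosen = chosen[np.isfinite(flat[chosen])]  # never select undefined nodes
    mask = np.zeros(vals.size, dtype=bool)
    mask[chosen] = True
    tag = "upper" if rule == "upper-percentile" else "lower"
    return AreaMask(mask.reshape(vals.shape), f"{smap.kind} {tag} {value:g}%",
                    smap.kind)


def overlap(a: AreaMask | np.ndarray, b: AreaMask | np.ndarray) -> OverlapResult:
    """Percent of `a` covered by `b`, with a chi-square association test.

    percent = 100 * |a & b| / |a|; the p-value tests node-level
    association of the two binary maps on the 2x2 contingency table.
    """
    ma = a.mask if isinstance(a, AreaMask) else np.asarray(a, bool)
    mb = b.mask if isinstance(b, AreaMask) else np.asarray(b, bool)
    if ma.shape != mb.shape:
        raise ValueError("masks are on different grids")
    n11 = int((ma & mb).sum())
    n10 = int((ma & ~mb).sum())
    n01 = int((~ma & mb).sum())
    n00 = int((~ma & ~mb).sum())
    counts = (n11, n10, n01, n00)
    if ma.sum() == 0:
        return OverlapResult(float("nan"), counts, float("nan"), defined=False)
    percent = 100.0 * n11 / ma.sum()
    table = np.array([[n11, n10], [n01, n00]], dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        p = float("nan")
    else:
        p = float(sp_stats.chi2_contingency(table, correction=True)[1])
    return OverlapResult(float(percent), counts, p)
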