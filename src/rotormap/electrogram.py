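"""Virtual bipolar electrograms.

Emulates a clinical ablation catheter pressed on the sheet: two rectangular
electrodes (distal 3.5 x 2.0 mm, proximal 1.5 x 2.0 mm) separated by a
1.0-mm edge-to-edge gap along the catheter axis.  The electrogram is the
difference of the mean action potential over the two footprints — an
AP-averaging approximation of the bipolar signal, not an extracellular
forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tissue import VoltageMovie

DISTAL_SIZE_MM = (3.5, 2.0)    # (along-axis, across-axis)
PROXIMAL_SIZE_MM = (1.5, 2.0)
GAP_MM = 1.0


class PlacementError(ValueError):
    """Electrode footprint does not fit on the grid."""


@dataclass(frozen=True)
class ElectrodeSpec:
    """Bipolar electrode pair centred at grid position (row, col).

    `orientation` is the catheter axis: 'x' lays the distal/proximal pair
    along columns, 'y' along rows.  Sizes in mm; footprints are the nodes
    whose centers fall inside each rectangle (half-open coverage).
    """

    center: tuple[float, float]            # (row, col), node units
    orientation: str = "x"
    distal_size: tuple[float, float] = DISTAL_SIZE_MM
    proximal_size: tuple[float, float] = PROXIMAL_SIZE_MM
    gap: float = GAP_MM

    def footprints(self, shape: tuple[int, int], dx: float
                   ) -> tuple[np.ndarray, np.ndarray]:
        """Boolean node masks (distal, proximal) on a (ny, nx) grid."""
        ny, nx = shape
        r0, c0 = self.center
        if self.orientation not in ("x", "y"):
            raise PlacementError(f"orientation must be 'x' or 'y'")

        # positions along the catheter axis (mm), symmetric about the center
        total = self.distal_size[0] + self.gap + self.proximal_size[0]
        a_lo = -total / 2.0
        rects = []  # (axis_lo, axis_hi, half_width) per electrode
        rects.append((a_lo, a_lo + self.distal_size[0], self.distal_size[1] / 2))
        p_lo = a_lo + self.distal_size[0] + self.gap
        rects.append((p_lo, p_lo + self.proximal_size[0], self.proximal_size[1] / 2))

        masks = []
        rr, cc = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        for (lo, hi, hw) in rects:
            if self.orientation == "x":
                axis = (cc - c0) * dx
                perp = (rr - r0) * dx
            else:
                axis = (rr - r0) * dx
                perp = (cc - c0) * dx
            mask = (axis >= lo) & (axis < hi) & (perp >= -hw) & (perp < hw)
            if not mask.any():
                raise PlacementError("electrode footprint covers no node")
            masks.append(mask)
        distal, proximal = masks
        if (distal & proximal).any():
            raise PlacementError("electrode footprints overlap")
        # off-grid check: rectangle corners must lie inside the sheet
        for (lo, hi, hw) in rects:
            if self.orientation == "x":
                cs = (c0 + lo / dx, c0 + hi / dx)
                rs = (r0 - hw / dx, r0 + hw / dx)
            else:
                rs = (r0 + lo / dx, r0 + hi / dx)
                cs = (c0 - hw / dx, c0 + hw / dx)
            if min(rs) < -0.5 or max(rs) > ny - 0.5 or min(cs) < -0.5 or max(cs) > nx - 0.5:
                raise PlacementError("electrode footprint off the grid")
        return distal, proximal


@dataclass
class Electrogram:
    """Bipolar signal (mV) sampled like its source movie."""

    signal: np.ndarray
    dt_sample: float
    spec: ElectrodeSpec | None = None
    t0: float = 0.0

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("non-finite electrogram signal")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.signal.size) * self.dt_sample


def bipolar_egm(movie: VoltageMovie, spec: ElectrodeSpec) -> Electrogram:
    """signal(t) = mean V over the distal footprint - mean over the proximal."""
    distal, proximal = spec.footprints(movie.shape, movie.dx)
    sig = (movie.frames[:, distal].mean(axis=1, dtype=np.float64)
           - movie.frames[:, proximal].mean(axis=1, dtype=np.float64))
    return Electrogram(sig, movie.dt_sample, spec, movie.t0)


@dataclass
class EgmTiling:
    """Electrograms on a regular tile lattice covering the sheet.

    `tile_of_node[r, c]` gives the flat tile index of every node so
    per-tile statistics can be painted back as full-resolution maps.
    """

    egms: list[Electrogram]
    centers: np.ndarray          # (n_tiles, 2) row, col
    tile_of_node: np.ndarray     # (ny, nx) int
    shape_tiles: tuple[int, int]

    def paint(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Per-tile values -> per-node map."""
        values = np.asarray(values, dtype=float)
        out = values[self.tile_of_node]
        return out


def egm_grid(movie: VoltageMovie, spacing_mm: float = 2.0,
             orientation: str = "x") -> EgmTiling:
    """One bipolar electrogram per `spacing_mm` tile, tiling the sheet.

    Tiles at the sheet margin whose electrode footprint would fall off the
    grid reuse the nearest interior electrode position (the tile-to-node
    bookkeeping still assigns every node to its own tile).
    """
    ny, nx = movie.shape
    dx = movie.dx
    step = spacing_mm / dx
    if step < 1:
        raise PlacementError("tile spacing below the node spacing")
    total_axis = DISTAL_SIZE_MM[0] + GAP_MM + PROXIMAL_SIZE_MM[0]
    if spacing_mm > max(ny, nx) * dx:
        raise PlacementError("tile spacing exceeds the sheet")

    n_ty = int(np.floor(ny / step))
    n_tx = int(np.floor(nx / step))
    if n_ty < 1 or n_tx < 1:
        raise PlacementError("sheet smaller than one tile")

    # margins keeping the full electrode on-grid
    half_axis = total_axis / 2.0 / dx
    half_perp = max(DISTAL_SIZE_MM[1], PROXIMAL_SIZE_MM[1]) / 2.0 / dx
    if orientation == "x":
        lo_c, hi_c = half_axis, nx - 1 - half_axis
        lo_r, hi_r = half_perp, ny - 1 - half_perp
    else:
        lo_r, hi_r = half_axis, ny - 1 - half_axis
        lo_c, hi_c = half_perp, nx - 1 - half_perp
    if lo_c > hi_c or lo_r > hi_r:
        raise PlacementError("sheet too small for the electrode pair")

    egms, centers = [], []
    for ty in range(n_ty):
        for tx in range(n_tx):
            r = np.clip((ty + 0.5) * step, lo_r, hi_r)
            c = np.clip((tx + 0.5) * step, lo_c, hi_c)
            spec = ElectrodeSpec(center=(float(r), float(c)),
                                 orientation=orientation)
            egms.append(bipolar_egm(movie, spec))
            centers.append((r, c))

    rows = np.minimum((np.arange(ny) / step).astype(int), n_ty - 1)
    cols = np.minimum((np.arange(nx) / step).astype(int), n_tx - 1)
    tile_of_node = rows[:, None] * n_tx + cols[None, :]
    return EgmTiling(egms, np.asarray(centers), tile_of_node, (n_ty, n_tx))
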