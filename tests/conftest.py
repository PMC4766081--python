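"""Shared fixtures: kinematic movies and a paced-strip simulation."""

from __future__ import annotations

import numpy as np
import pytest

from rotormap import ionic, tissue


def kinematic_planar_movie(ny=120, nx=24, dx=0.25, speed=0.4, band_mm=10.0,
                           dt_sample=1.0, duration_ms=None, axis="row",
                           reverse=False, v_rest=-80.0, v_exc=0.0,
                           start_ms=0.0):
    """Constructed movie of a rigid band translating at a known speed.

    A front at `speed` mm/ms moves along the chosen axis trailed by an
    excited band of width `band_mm`; the analytic ground truth for CV and
    wavelength oracles.
    """
    n_axis = ny if axis == "row" else nx
    if duration_ms is None:
        duration_ms = (n_axis * dx + 2 * band_mm) / speed
    nt = int(round(duration_ms / dt_sample)) + 1
    t = np.arange(nt) * dt_sample
    pos = np.arange(n_axis) * dx
    if reverse:
        pos = pos[::-1].copy()
    # node is excited when 0 <= front_position - node_position < band
    lead = speed * (t[:, None] - start_ms)
    rel = lead - pos[None, :]
    excited = (rel >= 0) & (rel < band_mm)
    v_axis = np.where(excited, v_exc, v_rest).astype(np.float32)
    if axis == "row":
        frames = np.repeat(v_axis[:, :, None], nx, axis=2)
    else:
        frames = np.repeat(v_axis[:, None, :], ny, axis=1)
    return tissue.VoltageMovie(frames, dt_sample, 0.0, dx,
                               {"fixture": "kinematic", "speed": speed,
                                "band_mm": band_mm})


@pytest.fixture(scope="session")
def paced_strip_movie():
    """Control-preset strip, two line-paced beats at CL 600 ms."""
    grid = tissue.TissueGrid(nx=24, ny=160, dx=0.25, deff=0.1)
    protocol = tissue.StimulusProtocol(kind="line-pace", cycle_length=600.0,
                                       count=2)
    movie = tissue.simulate(grid, ionic.CONTROL_PARAMS, protocol,
                            duration=840.0, sampling=1.0)
    return movie


@pytest.fixture(scope="session")
def single_cell_traces():
    """Kernel-integrated single-cell APs (control and PeAF), CL 1000 ms."""
    out = {}
    for name, params in (("control", ionic.CONTROL_PARAMS),
                         ("peaf", ionic.PEAF_PARAMS)):
        grid = tissue.TissueGrid(nx=16, ny=16, dx=0.25, deff=0.015)
        sim = tissue.TissueSim(grid, params)
        stim = sim.line_stim_indices(16)   # uniform stimulation of all nodes
        trace = [sim.V[8, 8]]
        for beat in range(3):
            for ms in range(1000):
                if ms < 2:
                    sim.advance(1.0, stim, -20.0)
                else:
                    sim.advance(1.0)
                trace.append(sim.V[8, 8])
        v = np.array(trace)
        out[name] = (np.arange(v.size) * 1.0, v)
    return out
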