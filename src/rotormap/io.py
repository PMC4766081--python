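"""Persistence: HDF5 movie container, CSV maps/masks/tables, AP traces."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


def save_movie(movie, path) -> None:
    """Chunked HDF5 container with sampling/geometry attributes."""
    from .tissue import VoltageMovie  # noqa: F401 (type documented)

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        nt, ny, nx = movie.frames.shape
        chunk_t = min(nt, max(1, 2 ** 22 // (ny * nx * 4)))
        ds = fh.create_dataset("frames", data=movie.frames.astype(np.float32),
                               chunks=(chunk_t, ny, nx), compression="gzip",
                               compression_opts=1)
        ds.attrs["dt_sample"] = movie.dt_sample
        ds.attrs["t0"] = movie.t0
        ds.attrs["dx"] = movie.dx
        fh.attrs["meta"] = json.dumps({k: _jsonable(v)
                                       for k, v in movie.meta.items()})


def load_movie(path):
    from .tissue import VoltageMovie

    with h5py.File(path, "r") as fh:
        ds = fh["frames"]
        movie = VoltageMovie(ds[...], float(ds.attrs["dt_sample"]),
                             float(ds.attrs["t0"]), float(ds.attrs["dx"]),
                             json.loads(fh.attrs.get("meta", "{}")))
    return movie


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def save_map_csv(smap, path) -> None:
    """Gridded CSV: one row per node row; undefined nodes as empty cells."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vals = np.where(smap.undefined, np.nan, smap.values)
    df = pd.DataFrame(vals)
    df.to_csv(path, index=False, header=False, float_format="%.6g")


def load_map_csv(path, kind, window=np.nan):
    from .maps import ScalarMap

    vals = pd.read_csv(path, header=None).to_numpy(dtype=float)
    return ScalarMap(vals, kind, window)


def save_mask_rle(mask: np.ndarray, path, meta: dict | None = None) -> None:
    """Run-length-encoded boolean mask as CSV (start, length over flat index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    flat = np.asarray(mask, bool).ravel()
    edges = np.diff(flat.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    stops = np.nonzero(edges == -1)[0] + 1
    if flat[0]:
        starts = np.concatenate([[0], starts])
    if flat[-1]:
        stops = np.concatenate([stops, [flat.size]])
    df = pd.DataFrame({"start": starts, "length": stops - starts})
    header_meta = dict(meta or {}, ny=mask.shape[0], nx=mask.shape[1])
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header_meta) + "\n")
        df.to_csv(fh, index=False)


def load_mask_rle(path) -> tuple[np.ndarray, dict]:
    with open(path) as fh:
        meta = json.loads(fh.readline().lstrip("# "))
        df = pd.read_csv(fh)
    flat = np.zeros(meta["ny"] * meta["nx"], dtype=bool)
    for s, ln in zip(df["start"], df["length"]):
        flat[s:s + ln] = True
    return flat.reshape(meta["ny"], meta["nx"]), meta


def save_trace_csv(t_ms: np.ndarray, v_mv: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"t_ms": t_ms, "V_mV": v_mv}).to_csv(path, index=False,
                                                      float_format="%.6g")


def save_trajectories_csv(trajs, path) -> None:
    """CSV of (trajectory id, t, x_mm, y_mm, charge)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for tid, tr in enumerate(trajs):
        for t, x, y in zip(tr.t, tr.x, tr.y):
            rows.append((tid, t, x * tr.dx, y * tr.dx, tr.charge))
    pd.DataFrame(rows, columns=["trajectory", "t_ms", "x_mm", "y_mm",
                                "charge"]).to_csv(path, index=False,
                                                  float_format="%.6g")
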