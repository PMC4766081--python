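"""End-to-end experiment driver: pacing + reentry initiation, parameter
mapping, rotor classification, overlap tables and the four ablation arms.

The sequence mirrors the mapping/ablation workflow of the underlying
study: line pacing at 600 ms to measure conduction velocity and
wavelength, cross-field reentry initiation, a fibrillation episode,
PS/DF/ShEn/CFAE maps over the trailing analysis window, mother-rotor
classification against the wavelength criterion, rotor-vs-parameter
spatial overlap statistics, and virtual ablation arms branched from the
same instant of the same episode.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ablation as abl, io as rio, maps as rmaps, rotors as rr
from .config import ExperimentConfig
from .electrogram import egm_grid
from .ionic import get_preset
from .tissue import (ConductionMeasurement, StimulusProtocol, TissueGrid,
                     TissueSim, VoltageMovie, measure_cv_and_wavelength,
                     pacing_schedule)


@dataclass
class EpisodeResult:
    pacing_movie: VoltageMovie   # line-paced phase up to the reset
    af_movie: VoltageMovie       # post-initiation episode
    sim: TissueSim
    conduction: ConductionMeasurement
    reset_t: float


@dataclass
class AnalysisResult:
    maps: dict                   # kind -> ScalarMap
    masks: dict                  # name -> AreaMask / ndarray
    trajectories: list
    rotors: list                 # MotherRotor per long trajectory
    mother: object | None        # best-qualifying rotor (or longest)
    overlaps: dict               # name -> OverlapResult
    df_threshold_hz: float
    conduction: ConductionMeasurement


def run_af_episode(cfg: ExperimentConfig) -> EpisodeResult:
    """Pace, initiate reentry by cross-field reset, run the AF episode."""
    cfg.validate()
    grid = TissueGrid(nx=cfg.nx, ny=cfg.ny, dx=cfg.dx_mm, deff=cfg.deff)
    params = get_preset(cfg.preset)
    sim = TissueSim(grid, params, dt=cfg.dt_ms)
    protocol = StimulusProtocol(kind="cross-field-reset",
                                cycle_length=cfg.pacing_cl_ms,
                                count=cfg.pacing_count,
                                reset_at_row_fraction=cfg.reset_at_row_fraction,
                                reset_mode=cfg.reset_mode)
    schedule = pacing_schedule(sim, protocol)
    t_pace_end = (protocol.count - 1) * protocol.cycle_length + protocol.pulse_ms + 1.0
    pieces = [sim.run_recorded(t_pace_end, cfg.sampling_ms, schedule)]
    target_row = int(protocol.reset_at_row_fraction * grid.ny)
    t_guard = t_pace_end + 4.0 * grid.ny * grid.dx / 0.05  # generous CV floor
    while sim.t < t_guard:
        marker = (sim.front_row() if cfg.reset_mode == "front"
                  else sim.tail_row())
        if marker >= target_row:
            break
        pieces.append(sim.run_recorded(cfg.sampling_ms, cfg.sampling_ms))
    else:
        raise RuntimeError("paced wavefront never reached the reset row")
    reset_t = sim.t
    sim.cross_field_reset(protocol.reset_value)

    pace_frames = np.concatenate([pieces[0].frames]
                                 + [p.frames[1:] for p in pieces[1:]], axis=0)
    pieces.clear()
    meta = {"preset": cfg.preset, "deff": cfg.deff, "reset_t": reset_t}
    pacing_movie = VoltageMovie(pace_frames, cfg.sampling_ms, 0.0, grid.dx,
                                dict(meta))
    conduction = measure_cv_and_wavelength(pacing_movie, cfg.pacing_cl_ms)
    af_movie = sim.run_recorded(cfg.af_duration_ms, cfg.sampling_ms)
    af_movie.meta.update(meta, cv=conduction.cv,
                         wavelength=conduction.wavelength)
    return EpisodeResult(pacing_movie, af_movie, sim, conduction, reset_t)


def analyze_episode(ep: EpisodeResult, cfg: ExperimentConfig,
                    df_threshold_hz: float | None = None) -> AnalysisResult:
    """Maps, rotor classification and overlap statistics for one episode."""
    af = ep.af_movie
    window = min(cfg.map_window_ms, af.duration)

    df_map = rmaps.dominant_frequency_map(af, window=window)
    sub = af.window(af.t0 + af.duration - window, af.t0 + af.duration)
    tiling = egm_grid(sub, cfg.egm_spacing_mm)
    shen_map = rmaps.shannon_entropy_map(af, window=window, tiling=tiling)
    cfae_map_ = rmaps.cfae_map(af, window=window, tiling=tiling)

    # phase / PS / trajectories over the whole episode (2-ms stride: tip
    # displacement per 2 ms is well inside the tracking gate)
    stride = max(int(round(2.0 / af.dt_sample)), 1)
    ps_movie = VoltageMovie(af.frames[::stride], af.dt_sample * stride,
                            af.t0, af.dx)
    pm = rr.phase_movie(ps_movie, block_rows=8)
    per_frame = rr.detect_ps(pm)
    dt_ps, dx_ps = pm.dt_sample, pm.dx
    del pm, ps_movie
    trajs = rr.track_ps(per_frame, dt_ps, dx_ps)

    wavelength = ep.conduction.wavelength
    rotors = [rr.classify_mother_rotor(tr, wavelength, trajs)
              for tr in trajs if tr.duration >= 500.0]
    mother = None
    qualifying = [m for m in rotors if m.qualifies]
    if qualifying:
        mother = max(qualifying, key=lambda m: m.duration)
    elif rotors:
        mother = max(rotors, key=lambda m: m.duration)

    # DF "area" cut: printed threshold at full scale, or relative to the
    # observed peak on scaled sheets (the cut belongs just below the
    # the rotor's peak DF on the map)
    if df_threshold_hz is None:
        finite = df_map.values[~df_map.undefined]
        peak = float(np.nanmax(finite)) if finite.size else float("nan")
        df_threshold_hz = cfg.df_threshold_hz
        if np.isfinite(peak) and peak <= cfg.df_threshold_hz:
            df_threshold_hz = 0.8 * peak

    masks = {
        "df_area": rmaps.area_mask(df_map, "threshold-above", df_threshold_hz),
        "shen_area": rmaps.area_mask(shen_map, "upper-percentile",
                                     cfg.area_percentile),
        "cfae_area": rmaps.area_mask(cfae_map_, "lower-percentile",
                                     cfg.area_percentile),
        "shen_area_cross": rmaps.area_mask(shen_map, "upper-percentile",
                                           cfg.cross_percentile),
        "cfae_area_cross": rmaps.area_mask(cfae_map_, "lower-percentile",
                                           cfg.cross_percentile),
    }
    overlaps = {}
    if mother is not None:
        rotor_mask = rr.rotor_area_mask(mother, af.shape, af.dx)
        masks["rotor_area"] = rotor_mask
        overlaps["df_by_rotor"] = rmaps.overlap(masks["df_area"], rotor_mask)
        overlaps["shen_by_rotor"] = rmaps.overlap(masks["shen_area"], rotor_mask)
        overlaps["cfae_by_rotor"] = rmaps.overlap(masks["cfae_area"], rotor_mask)
    overlaps["df_by_shen"] = rmaps.overlap(masks["df_area"],
                                           masks["shen_area_cross"])
    overlaps["shen_by_cfae"] = rmaps.overlap(masks["shen_area_cross"],
                                             masks["cfae_area_cross"])
    overlaps["cfae_by_df"] = rmaps.overlap(masks["cfae_area_cross"],
                                           masks["df_area"])

    return AnalysisResult({"DF": df_map, "ShEn": shen_map, "CFAE": cfae_map_},
                          masks, trajs, rotors, mother, overlaps,
                          float(df_threshold_hz), ep.conduction)


def run_ablation_arms(ep: EpisodeResult, analysis: AnalysisResult,
                      cfg: ExperimentConfig,
                      strategies=None, keep_movies: bool = False) -> dict:
    """Branch each ablation strategy from the episode's final state.

    Post-ablation movies are dropped after classification unless
    `keep_movies` (they are large)."""
    strategies = list(strategies or cfg.strategies)
    snap = ep.sim.snapshot()
    out = {}
    for strategy in strategies:
        ep.sim.restore(snap)
        if strategy == "PS":
            if not analysis.trajectories:
                out[strategy] = {"plan": None, "post_movie": None,
                                 "report": abl.OutcomeReport(
                                     "indeterminate", None, None, {}, 0.0)}
                continue
            plan = abl.plan_ps_ablation(analysis.trajectories,
                                        ep.af_movie.shape, ep.af_movie.dx,
                                        cfg.ablation_fraction,
                                        cfg.ps_lesion_radius_mm)
        else:
            plan = abl.plan_map_ablation(analysis.maps[strategy], strategy,
                                         cfg.ablation_fraction)
        abl.apply_ablation(ep.sim, plan)
        t_abl = ep.sim.t
        post = ep.sim.run_recorded(cfg.follow_up_ms, cfg.sampling_ms)
        report = abl.classify_outcome(post, t_abl)
        out[strategy] = {"plan": plan, "report": report,
                         "post_movie": post if keep_movies else None}
    ep.sim.restore(snap)
    return out


# ---------------------------------------------------------------------------
# Full run with persistence
# ---------------------------------------------------------------------------

def run_experiment(cfg: ExperimentConfig, out_dir=None) -> dict:
    """Run the full workflow, write CSV/HDF5 outputs, return a manifest."""
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    c_start = time.process_time()

    ep = run_af_episode(cfg)
    analysis = analyze_episode(ep, cfg)

    if cfg.save_movie:
        rio.save_movie(ep.af_movie, out / "movie.h5")
    for kind, smap in analysis.maps.items():
        rio.save_map_csv(smap, out / f"map_{kind.lower()}.csv")
    for name, m in analysis.masks.items():
        mask = m.mask if hasattr(m, "mask") else m
        rio.save_mask_rle(mask, out / f"mask_{name}.csv", {"name": name})
    rio.save_trajectories_csv(analysis.trajectories, out / "ps_trajectories.csv")

    rotor_rows = []
    for m in analysis.rotors:
        rotor_rows.append({
            "birth_ms": m.trajectory.birth, "death_ms": m.trajectory.death,
            "duration_ms": m.duration, "center_x_mm": m.center[0],
            "center_y_mm": m.center[1], "rotor_radius_mm": m.radius,
            "confinement_radius_mm": m.confinement_radius,
            "wavelength_mm": m.wavelength,
            "breakup_observed": m.breakup_observed, "qualifies": m.qualifies,
        })
    pd.DataFrame(rotor_rows).to_csv(out / "rotor_report.csv", index=False,
                                    float_format="%.6g")

    ov_rows = []
    for name, res in analysis.overlaps.items():
        ov_rows.append({"pair": name, "percent": res.percent,
                        "p_value": res.p_value, "n11": res.counts[0],
                        "n10": res.counts[1], "n01": res.counts[2],
                        "n00": res.counts[3]})
    pd.DataFrame(ov_rows).to_csv(out / "overlap_table.csv", index=False,
                                 float_format="%.6g")

    arms = {}
    if cfg.strategies:
        results = run_ablation_arms(ep, analysis, cfg)
        rows = []
        for strategy, r in results.items():
            rep = r["report"]
            rows.append({"strategy": strategy, "outcome": rep.outcome,
                         "event_time_ms": rep.event_time,
                         "post_cycle_length_ms": rep.post_cycle_length,
                         "observed_ms": rep.observed_ms,
                         "lesion_fraction": (r["plan"].achieved_fraction
                                             if r["plan"] is not None
                                             else np.nan)})
            if r["plan"] is not None:
                rio.save_mask_rle(r["plan"].lesion_mask,
                                  out / f"lesion_{strategy.lower()}.csv",
                                  {"strategy": strategy})
            arms[strategy] = rep.outcome
        pd.DataFrame(rows).to_csv(out / "ablation_outcomes.csv", index=False,
                                  float_format="%.6g")

    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "reset_t_ms": ep.reset_t,
        "cv_mm_per_ms": analysis.conduction.cv,
        "wavelength_mm": analysis.conduction.wavelength,
        "wavelength_truncated": analysis.conduction.truncated,
        "df_threshold_hz": analysis.df_threshold_hz,
        "n_trajectories": len(analysis.trajectories),
        "mother_rotor_found": bool(analysis.mother is not None
                                   and analysis.mother.qualifies),
        "overlaps_percent": {k: v.percent for k, v in analysis.overlaps.items()},
        "ablation_outcomes": arms,
        "wall_s": time.time() - t_start,
        "cpu_s": time.process_time() - c_start,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=_json_default))
    cfg.to_yaml(out / "config.yaml")
    return manifest


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(type(o))
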