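#!/usr/bin/env python
"""Map PS/DF/ShEn/CFAE, classify the mother rotor, tabulate overlaps.

Loads the saved AF episode (analysis/03), computes the dominant-frequency
map per node, Shannon entropy and CFAE cycle length per bipolar-electrode
tile, detects and tracks phase singularities, classifies trajectories
against the quantitative mother-rotor definition, and writes the
rotor-vs-parameter overlap table.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from rotormap import io as rio  # noqa: E402
from rotormap.config import ExperimentConfig  # noqa: E402
from rotormap.pipeline import EpisodeResult, analyze_episode  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "maps"


def main():
    movie_path = ROOT / "results" / "episode" / "movie_peaf.h5"
    if not movie_path.exists():
        raise SystemExit("run analysis/03_af_episode.py first")
    af = rio.load_movie(movie_path)       # episode movie (post-initiation)
    cfg = ExperimentConfig(preset="peaf", nx=af.shape[1], ny=af.shape[0],
                           deff=af.meta.get("deff", 0.025),
                           af_duration_ms=af.duration)
    from rotormap.tissue import ConductionMeasurement
    conduction = ConductionMeasurement(af.meta["cv"], af.meta["wavelength"],
                                       False)
    ep = EpisodeResult(None, af, None, conduction, af.meta["reset_t"])
    analysis = analyze_episode(ep, cfg)

    OUT.mkdir(parents=True, exist_ok=True)
    for kind, smap in analysis.maps.items():
        rio.save_map_csv(smap, OUT / f"map_{kind.lower()}.csv")
    rio.save_trajectories_csv(analysis.trajectories,
                              OUT / "ps_trajectories.csv")

    print(f"wavelength {conduction.wavelength:.1f} mm "
          f"(CV {conduction.cv:.3f} mm/ms); DF area cut "
          f"{analysis.df_threshold_hz:.2f} Hz")
    print(f"{len(analysis.trajectories)} PS trajectories; "
          f"longest {max((t.duration for t in analysis.trajectories), default=0)/1000:.1f} s")
    if analysis.mother is not None:
        m = analysis.mother
        print(f"mother rotor: duration {m.duration/1000:.1f} s, "
              f"tip circle diameter {2*m.confinement_radius:.1f} mm "
              f"(limit {m.wavelength/2:.1f} mm), breakup={m.breakup_observed}, "
              f"qualifies={m.qualifies}")
    rows = [{"pair": k, "percent": v.percent, "p": v.p_value}
            for k, v in analysis.overlaps.items()]
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "overlap_table.csv", index=False, float_format="%.4g")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
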