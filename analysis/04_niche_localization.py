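#!/usr/bin/env python
"""Bone/vessel distance analysis of control vs treated 3D volumes.

Simulates two groups with identical niche placement (60% of cells within
5 um of vessels, 50% within 15 um of bone — localization unaffected by
treatment), runs segmentation, 3D detection and distance sampling, and
compares the distance distributions with the Kolmogorov-Smirnov test.
Expected finding: fractions recovered at the requested values and a
non-significant group difference.
"""

import json
from pathlib import Path

import pandas as pd

import ivmotion as m
from ivmotion.pipeline import AnalysisParams, analyze_movie

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SEED = 1


def simulate_group(name: str, seed: int) -> pd.DataFrame:
    n = 20
    cfg = m.SimulationConfig(
        n_cells=n, cell_regimes=("arrested",) * n, mode="3d", n_frames=2,
        field_size=(192.0, 192.0, 60.0), voxel_size=(1.0, 1.0, 2.0),
        vessels=(
            m.VesselSpec((0.0, 64.0, 30.0), (1.0, 0.0, 0.0), 8.0),
            m.VesselSpec((96.0, 0.0, 40.0), (0.0, 1.0, 0.0), 6.0),
        ),
        bone=m.BoneSpec(position=8.0),
        placement_rules=(
            m.PlacementRule("vessel", 5.0, 0.6),
            m.PlacementRule("bone", 15.0, 0.5),
        ),
        noise=m.NoiseModel(background=0.0, signal=200.0, shot_noise=False),
        seed=seed,
    )
    movie = m.render_movie(m.simulate_tracks(cfg), cfg)
    return analyze_movie(movie, AnalysisParams(), group=name)["distances"]


def main() -> None:
    OUT.mkdir(exist_ok=True)
    dists = pd.concat(
        [simulate_group("control", SEED), simulate_group("treated", SEED + 1)],
        ignore_index=True,
    )
    dists.to_csv(OUT / "niche_distances.csv", index=False)
    summary = m.summarize_distances(dists)
    (OUT / "niche_summary.json").write_text(json.dumps(summary, indent=2, default=float))
    for structure, entry in summary["structures"].items():
        for g, s in entry["per_group"].items():
            print(
                f"{g} / {structure}: mean {s['mean_um']:.1f} um, "
                f"{100 * s['fraction_within']:.0f}% within {entry['threshold_um']:.0f} um"
            )
        ks = entry.get("ks")
        if ks:
            print(f"  KS control vs treated: D={ks['D']:.3f}, p={ks['p']:.3f} ({ks['verdict']})")


if __name__ == "__main__":
    main()
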