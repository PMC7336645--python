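# ivmotion

Quantification of leukemia-cell motility and bone-marrow niche localization
in intravital two-photon time-lapse imaging — plus a synthetic movie
generator with exact ground truth, so the whole pipeline is testable by
parameter recovery.

## The problem

In intravital imaging of leukemia-bearing bone marrow, GFP-labelled tumor
cells (green) migrate along blood vessels (red) near the bone surface
(blue, second-harmonic signal). Chemotherapy changes how these cells move:
surviving cells become almost stationary, then regain motility as the
disease regrows. Quantifying that requires three measurements from
multichannel time-lapse movies:

1. **Displacement-area ratio.** Pool the intensity histogram of all green
   frames, compute one Otsu threshold, binarize every frame, median-filter
   the masks, and compute the intersection-over-union between successive
   frames:

   IoU(t) = |M(t) ∧ M(t+1)| / |M(t) ∨ M(t+1)|

   The per-pair statistic is **1 − IoU**: ≈0 when cells neither move nor
   change shape, ≈1 for vigorous amoeboid movement.
2. **Mean track speed.** Cells are detected as spots of one nominal
   diameter (10 μm) via a scale-matched Laplacian-of-Gaussian response,
   linked frame-to-frame by gated greedy nearest-neighbour assignment, and
   each track's mean speed is its path length over elapsed time (μm/min).
   Speeds below ~1 μm/min (a cell diameter per ten minutes) indicate
   passive, arrested cells.
3. **Distance to niche surfaces.** Bone and vessel channels are segmented
   (Otsu), converted to exact anisotropic Euclidean distance fields (μm),
   and sampled at each cell centroid; summaries report mean distances and
   the fraction of cells within 15 μm of bone / 5 μm of vessels.

Group comparisons use the tests such figures are reported with — Student's
t, one-way ANOVA, two-sample Kolmogorov–Smirnov, and the log-rank test for
survival — implemented here from their formulas and cross-checked against
reference libraries.

Because real intravital recordings are rarely shareable, the package ships
a generator (`ivmotion.simulate`) that produces calibrated OME-TIFF movies
of quasi-spherical 10-μm cells performing a persistent random walk in
"motile" (1.5 μm/min, strong protrusion activity) or "arrested"
(0.5 μm/min, weak protrusion) regimes near configurable vessel tubes and a
bone plane — with exact tracks, regime labels, and niche distances as
ground truth.

## Worked example

```python
import ivmotion as m
from ivmotion.displacement import MIPSequence
from ivmotion.pipeline import AnalysisParams, analyze_movie

cfg = m.SimulationConfig.cohort(
    "arrested", n_cells=100, n_frames=61, frame_interval=1.0,
    field_size=(512.0, 512.0, 40.0), voxel_size=(1.0, 1.0, 2.0), seed=11)
truth = m.simulate_tracks(cfg)          # ground-truth tracks, μm
movie = m.render_movie(truth, cfg)      # (T, C, Z, Y, X) uint16
res = analyze_movie(movie, AnalysisParams(), group="arrested",
                    expected_speed=0.5)
print(truth.mean_speeds().mean())                      # 0.500
print(res["speeds"].mean_speed_um_min.mean())          # 0.515
print(res["displacement"].mean_ratio)                  # 0.145
```

The recovered cohort mean (0.515 μm/min) sits within a few percent of the
true simulated mean (0.500) after the full rendering → detection → linking
chain, and the arrested cohort's mean displacement ratio (0.145) is far
below a motile cohort's (≈0.38 under the same conditions) — the movie-level
signature of migration arrest.

The same stages are scripted as a narrative analysis under `analysis/`
(01 simulate → 02 displacement → 03 speeds → 04 localization →
05 survival); each writes its tables to `results/`. A `ivmotion` CLI
exposes the stages for stored movies (`simulate`, `displacement`, `track`,
`distance`, `stats`, `run-all`).

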