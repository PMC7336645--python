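# Methods

## Synthetic movie model

The generator emulates intravital two-photon recordings of leukemia cells
in bone marrow well enough that every downstream measurement can be
validated by parameter recovery. It is deliberately minimal: the aim is a
controllable ground truth, not photorealism.

**Motion.** Each cell performs a persistent random walk. Per frame the
heading is a persistence-weighted blend of the previous heading and a fresh
isotropic direction (persistence p ∈ [0, 1]; p = 0 is an uncorrelated walk,
p = 1 a straight line), and the step length is Gamma-distributed with shape
5 and mean `target_speed × frame_interval`, so per-track speeds fluctuate
realistically (CV ≈ 0.45 per step) while the cohort mean path speed equals
the target by construction. Walks reflect at the field borders and at the
bone surface. The two default regimes are

| regime | target speed | persistence | protrusion amplitude |
|---|---|---|---|
| motile | 1.5 μm/min | 0.6 | 1.5 μm |
| arrested | 0.5 μm/min | 0.3 | 0.4 μm |

chosen so the arrested cohort sits clearly below 1 μm/min and the motile
cohort above it, with protrusion activity scaled accordingly. The frame
interval defaults to 1 min and movie length to 61 frames (one hour);
acquisition cadence is a free choice here, configurable per run.

**Shape and rendering.** A cell is a soft-edged ellipsoid of nominal
diameter 10 μm: intensity 1/(1 + exp((ρ − 1)/0.15)) in the normalized
radial coordinate ρ, evaluated at voxel centres (the centre of voxel i is
at (i + 0.5)·voxel_size). Protrusion activity is modelled as independent
per-axis, per-frame jitter of the ellipsoid radii, uniform within
± the regime's protrusion amplitude — shape change that perturbs the
binary mask (hence 1 − IoU) without moving the centroid, so protrusion and
translocation are partially independent, as they are in amoeboid cells.
Vessels are blurred cylinder masks, bone a blurred low-z slab; a constant
background plus optional Poisson shot noise (defaults: background 10,
signal 200, shot noise on) yields uint16 movies. No bleaching, depth
attenuation, cell division, or cell entry/exit is modelled; tracks all
span the movie, which is what makes exact speed ground truth possible.

**Placement.** Initial positions are rejection-sampled uniformly in the
free space (outside bone and vessel lumina, one cell radius off the
lateral borders, at least one cell diameter apart so cell bodies do not
interpenetrate). Placement rules of the form "fraction f within d μm of a
structure" are honoured exactly: the first round(n·f) cells sample inside
the distance shell, the rest outside, and all candidates keep one voxel of
clearance from the threshold boundary so that rasterization of the
geometry cannot flip a cell across the threshold during analysis. An
unsatisfiable rule (e.g. a vessel rule with no vessels) is an error.

**Determinism.** One root seed per run; per-cell, placement, rendering and
noise substreams are spawned from it, so identical configurations give
bitwise-identical ground truth and movies.

**Survival tables** are exponential event times per group (hazard in
1/day), censored at end of follow-up.

What passing recovery tests shows — and does not. The generator's cells
are bright, well-separated, and homogeneous; recovery of speeds within a
few percent and localization fractions within 1/n demonstrates the
pipeline's correctness, not its robustness to dim, densely packed, or
heterogeneous real recordings.

## Displacement-area ratio

The Otsu threshold is computed once per movie from the histogram of all
frames pooled (per-frame thresholds would confound intensity drift with
motility). Integer data up to 16 bit use one histogram bin per grey level
and an exhaustive scan of the between-class variance (ties resolved toward
the lowest threshold); float data use 256 equal-width bins. Foreground is
strictly `intensity > threshold`. Denoising is a per-frame square median
filter (default 3 × 3, edge-inclusive reflection at borders); on a binary
image this is a majority vote. IoU is computed on the whole per-frame
foreground mask — no per-cell matching. Degenerate pairs are defined, with
a warning: both masks empty → IoU 1 (nothing moved); exactly one empty →
IoU 0 (complete displacement). A constant movie is rejected rather than
thresholded.

## Spot detection and tracking

Detection is single-scale: the nominal 10-μm diameter fixes the LoG sigma
at diameter/(2√2) μm, converted per axis by the voxel calibration; a
diameter spanning fewer than two pixels on any axis is rejected. Local
maxima of the scale-normalized response above a threshold (default 20% of
the frame's maximum response) become spots, refined to sub-pixel precision
by a median-background-subtracted intensity centroid in a diameter-sized
window. Linking is greedy nearest-neighbour with a hard gate (default
3 × the expected frame step when an expected speed is given, half a
diameter otherwise): candidate links are sorted by distance with
lexicographic coordinate tie-breaks, so the result does not depend on
detection order. No gap closing and no division handling — the generator
produces neither. Tracks shorter than 5 frames are excluded from speed
statistics to suppress spurious fragments; mean speed is path length over
elapsed time. 2D MIP tracking is the default for speed analysis; the same
detector runs in 3D for the distance stage.

## Distance analysis

Structures are segmented by Otsu per channel (optional largest-component
cleanup, off by default). The distance field is the exact Euclidean
distance transform with anisotropic physical sampling; distances are to
the segmented occupancy, so centroids inside a lumen or the bone band read
0 — distances are never signed. The field is defined between voxel
centres, so against a continuous surface it carries a systematic bias of
up to half a voxel along the surface normal; the generator's placement
guard band (above) keeps threshold-based fractions exact despite it.
Sampling at spot centroids is trilinear; out-of-bounds spots are excluded
with a warning. Histograms use 5-μm bins; within-threshold fractions
default to 15 μm (bone) and 5 μm (vessels).

## Statistics

All four tests are implemented from their formulas, with scipy supplying
only distribution functions; reference implementations (scipy's test
routines, lifelines) appear in the test suite as independent checks.

* **t test**: Student's pooled-variance, two-sided. Zero pooled variance
  with equal means gives (t, p) = (0, 1); with unequal means p → 0,
  flagged in the result.
* **ANOVA**: F = MS_between/MS_within with (k − 1, N − k) df.
* **Kolmogorov–Smirnov**: D = sup|ECDF difference| with right-continuous
  ECDFs; p = Q_KS(√ne · D) with ne = n_a·n_b/(n_a + n_b), the classical
  asymptotic. Monte-Carlo calibration at n = 30/30 puts the empirical
  type-I error at ≈ 0.036 at α = 0.05 — slightly conservative, as the
  asymptotic KS test is at these sizes. Below 10 observations per group a
  warning marks the p value approximate.
* **log-rank**: hypergeometric observed/expected/variance accumulated at
  distinct event times (tied events pooled in one risk-table row);
  (ΣO − ΣE)²/ΣV against chi-square(1). Tables with no events, or with an
  empty group, are rejected.

No multiple-testing correction is applied anywhere; group summaries report
both SD and SEM, labelled, since figure conventions differ.

## Problem sizes

End-to-end checks run at sizes where the law of large numbers has taken
hold but a laptop finishes in seconds to minutes: speed recovery at 100
cells × 61 frames on a 512 × 512 μm field (recovered cohort means land
within ~5% of target); three-group displacement comparisons at 15 cells ×
20 frames; localization at 10–20 cells on 128–192 μm 3D fields;
statistical calibration at 1000 null replicates of n = 30/30. The
acceptance script (`scripts/acceptance.py`) re-runs all of these from a
single seed.

## Known limitations

* Whole-mask IoU means cell density affects the displacement ratio;
  comparisons should hold density roughly constant across groups (the
  synthetic experiments do).
* Greedy linking is not globally optimal; at high density or speeds near
  the gate it fragments tracks rather than guessing, biasing speed
  statistics toward well-tracked cells.
* The asymptotic KS p value is conservative for small groups; exact
  enumeration is out of scope.
* Rendering ignores photophysics (bleaching, scattering, depth
  attenuation) and vascular network topology; vessels are straight tubes.
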