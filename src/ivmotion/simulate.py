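"""Synthetic intravital-movie generator with ground truth.

Emulates two-photon time-lapse data of GFP-labelled leukemia cells migrating
through bone marrow: amoeboid cells of ~10 um diameter performing a
persistent random walk near a bone surface (SHG-like band) and vessel tubes,
in two motility regimes ("motile": mean speed > 1 um/min, strong protrusion
activity; "arrested": mean speed < 1 um/min, reduced protrusion).  Every
movie comes with exact ground truth (tracks, regime labels, initial niche
distances) so each downstream analysis stage can be validated by parameter
recovery rather than by eye.

Conventions
-----------
* Physical coordinates are (x, y, z) in micrometres; array axes are
  (Z, Y, X).  The centre of voxel index ``i`` along an axis with voxel size
  ``v`` sits at ``(i + 0.5) * v`` um.
* A single root seed drives the run; per-cell and per-stage substreams are
  spawned deterministically from it, so identical configs give bitwise
  identical output.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RegimeParams",
    "VesselSpec",
    "BoneSpec",
    "NoiseModel",
    "SimulationConfig",
    "GroundTruth",
    "TimelapseMovie",
    "simulate_tracks",
    "place_cells",
    "render_movie",
    "simulate_survival",
    "distance_to_bone",
    "distance_to_vessels",
]

CHANNEL_ROLES = ("green", "red", "blue")  # cells, vessels, bone


@dataclass(frozen=True)
class RegimeParams:
    """Motility parameters of one behavioural regime.

    target_speed : um/min, expected path speed of the walk.
    persistence : directional correlation in [0, 1]; 0 is a pure random
        walk, 1 a straight line.
    protrusion_amplitude : um, per-frame radial fluctuation of the rendered
        cell body (shape change without centroid motion).
    """

    target_speed: float
    persistence: float = 0.5
    protrusion_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.target_speed < 0:
            raise ValueError("target_speed must be >= 0")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")
        if self.protrusion_amplitude < 0:
            raise ValueError("protrusion_amplitude must be >= 0")


#: Default regimes: motile cells migrate at 1.5 um/min with strong
#: protrusion activity; arrested cells at 0.5 um/min with weak protrusions.
DEFAULT_REGIMES: Mapping[str, RegimeParams] = {
    "motile": RegimeParams(target_speed=1.5, persistence=0.6, protrusion_amplitude=1.5),
    "arrested": RegimeParams(target_speed=0.5, persistence=0.3, protrusion_amplitude=0.4),
}


@dataclass(frozen=True)
class VesselSpec:
    """Infinite cylinder: a point on the axis, a direction, a radius (um)."""

    point: tuple[float, float, float]
    direction: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("vessel radius must be > 0")
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if n == 0:
            raise ValueError("vessel direction must be nonzero")
        object.__setattr__(self, "direction", tuple(d / n))

    def axis_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from (..., 3) xyz points to the cylinder axis."""
        p = np.asarray(points, dtype=float) - np.asarray(self.point)
        d = np.asarray(self.direction)
        proj = p @ d
        perp = p - proj[..., None] * d
        return np.linalg.norm(perp, axis=-1)


@dataclass(frozen=True)
class BoneSpec:
    """Bone slab occupying ``z <= position`` (um); its surface is the plane."""

    position: float

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("bone position must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    background: float = 10.0
    signal: float = 200.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.background < 0 or self.signal <= 0:
            raise ValueError("background must be >= 0 and signal > 0")


@dataclass(frozen=True)
class PlacementRule:
    """Require a fraction of cells within `threshold_um` of a structure."""

    structure: str  # "bone" | "vessel"
    threshold_um: float
    fraction: float

    def __post_init__(self) -> None:
        if self.structure not in ("bone", "vessel"):
            raise ValueError("structure must be 'bone' or 'vessel'")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("placement fraction must lie in [0, 1]")
        if self.threshold_um <= 0:
            raise ValueError("placement threshold must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic experiment.

    ``mode`` is "mip" (motion confined to the mid-z plane, movie rendered as
    a single-slice 2D projection) or "3d" (full volume).  ``cell_regimes``
    assigns a regime label to each cell; by default every cell is motile.
    """

    n_cells: int = 20
    regimes: Mapping[str, RegimeParams] = field(
        default_factory=lambda: dict(DEFAULT_REGIMES)
    )
    cell_regimes: tuple[str, ...] | None = None
    cell_diameter: float = 10.0
    field_size: tuple[float, float, float] = (200.0, 200.0, 40.0)  # x, y, z um
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 2.0)  # x, y, z um
    n_frames: int = 61
    frame_interval: float = 1.0  # min
    mode: str = "mip"
    vessels: tuple[VesselSpec, ...] = ()
    bone: BoneSpec | None = None
    placement_rules: tuple[PlacementRule, ...] = ()
    min_separation: float | None = None  # um between initial centroids; default one cell diameter
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2 (no displacement definable)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be > 0 componentwise")
        if any(f <= 0 for f in self.field_size):
            raise ValueError("field_size must be > 0 componentwise")
        if self.cell_diameter <= 0:
            raise ValueError("cell_diameter must be > 0")
        if self.mode not in ("mip", "3d"):
            raise ValueError("mode must be 'mip' or '3d'")
        if self.min_separation is None:
            object.__setattr__(self, "min_separation", self.cell_diameter)
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        if self.cell_regimes is None:
            object.__setattr__(self, "cell_regimes", ("motile",) * self.n_cells)
        if len(self.cell_regimes) != self.n_cells:
            raise ValueError("cell_regimes must have one label per cell")
        for label in self.cell_regimes:
            if label not in self.regimes:
                raise ValueError(f"unknown regime label {label!r}")
        for rule in self.placement_rules:
            if rule.threshold_um > max(self.field_size):
                raise ValueError("placement threshold exceeds field size")
            if rule.structure == "vessel" and not self.vessels:
                raise ValueError(
                    "vessel placement rule requested but no vessels configured"
                )
            if rule.structure == "bone" and self.bone is None:
                raise ValueError(
                    "bone placement rule requested but no bone configured"
                )

    @classmethod
    def cohort(cls, regime: str, **kwargs) -> "SimulationConfig":
        """A single-regime cohort (every cell labelled `regime`)."""
        n = kwargs.pop("n_cells", 20)
        return cls(n_cells=n, cell_regimes=(regime,) * n, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regimes"] = {k: dataclasses.asdict(v) for k, v in self.regimes.items()}
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, default=list)


@dataclass
class GroundTruth:
    """Exact simulated state: the oracle for every downstream stage."""

    positions: np.ndarray  # (n_cells, n_frames, 3) xyz um
    regimes: tuple[str, ...]
    frame_interval: float  # min
    d_bone_t0: np.ndarray  # (n_cells,) um, NaN if no bone configured
    d_vessel_t0: np.ndarray  # (n_cells,) um, NaN if no vessels

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def mean_speeds(self) -> np.ndarray:
        """True per-track mean speed: path length / total time (um/min)."""
        steps = np.linalg.norm(np.diff(self.positions, axis=1), axis=-1)
        return steps.sum(axis=1) / ((self.n_frames - 1) * self.frame_interval)

    def to_frame(self) -> pd.DataFrame:
        n, t, _ = self.positions.shape
        idx = np.repeat(np.arange(n), t)
        frames = np.tile(np.arange(t), n)
        pts = self.positions.reshape(-1, 3)
        return pd.DataFrame(
            {
                "track_id": idx,
                "frame": frames,
                "x_um": pts[:, 0],
                "y_um": pts[:, 1],
                "z_um": pts[:, 2],
                "regime": np.repeat(np.asarray(self.regimes, dtype=object), t),
            }
        )


@dataclass
class TimelapseMovie:
    """Calibrated multichannel movie, axes (T, C, Z, Y, X).

    ``channels`` maps the three roles (green = tumor cells, red = vessels,
    blue = bone) to channel indices; ``voxel_size`` is (x, y, z) in um and
    ``frame_interval`` in minutes.
    """

    data: np.ndarray
    channels: Mapping[str, int]
    voxel_size: tuple[float, float, float]
    frame_interval: float

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValueError("movie data must be 5D (T, C, Z, Y, X)")
        if np.issubdtype(self.data.dtype, np.floating) and (self.data < 0).any():
            raise ValueError("intensities must be non-negative")
        if any(v <= 0 for v in self.voxel_size) or self.frame_interval <= 0:
            raise ValueError("calibration must be strictly positive")
        if sorted(self.channels) != sorted(CHANNEL_ROLES[: len(self.channels)]) and not set(
            self.channels
        ) <= set(CHANNEL_ROLES):
            raise ValueError(f"channel roles must be among {CHANNEL_ROLES}")

    def channel(self, role: str) -> np.ndarray:
        """(T, Z, Y, X) stack of one channel role."""
        if role not in self.channels:
            raise KeyError(f"movie has no {role!r} channel")
        return self.data[:, self.channels[role]]

    def mip(self, role: str) -> np.ndarray:
        """Maximum-intensity projection over Z: (T, Y, X)."""
        return self.channel(role).max(axis=1)


# ---------------------------------------------------------------------------
# geometry helpers

def distance_to_bone(points: np.ndarray, bone: BoneSpec | None) -> np.ndarray:
    """Distance (um) from xyz points to the bone surface; NaN without bone."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if bone is None:
        return np.full(pts.shape[0], np.nan)
    return np.maximum(0.0, pts[:, 2] - bone.position)


def distance_to_vessels(
    points: np.ndarray, vessels: Sequence[VesselSpec]
) -> np.ndarray:
    """Distance (um) from xyz points to the nearest vessel surface."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not vessels:
        return np.full(pts.shape[0], np.nan)
    d = np.min([v.axis_distance(pts) - v.radius for v in vessels], axis=0)
    return np.maximum(0.0, d)


def _streams(config: SimulationConfig):
    """Deterministic substreams: placement, one per cell, render, noise."""
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_cells + 3)
    placement = np.random.default_rng(children[0])
    cells = [np.random.default_rng(c) for c in children[1 : config.n_cells + 1]]
    render = np.random.default_rng(children[config.n_cells + 1])
    noise = np.random.default_rng(children[config.n_cells + 2])
    return placement, cells, render, noise


# ---------------------------------------------------------------------------
# placement

_MAX_REJECTION_TRIES = 100_000


def place_cells(config: SimulationConfig) -> np.ndarray:
    """Draw initial xyz positions (um) honouring the placement rules.

    For each rule the number of cells placed inside the distance shell is
    ``round(n_cells * fraction)``; with several rules the first cells (by
    index) take the "inside" role for every rule, which makes the realized
    within-threshold counts exact by construction.  Cells are kept out of
    the bone slab and vessel lumina and away from the field border by one
    cell radius (laterally).
    """
    rng, _, _, _ = _streams(config)
    margin = config.cell_diameter / 2.0
    lo = np.array([margin, margin, 0.0])
    hi = np.array(config.field_size) - [margin, margin, 0.0]
    if config.bone is not None:
        lo[2] = max(lo[2], config.bone.position)
    if config.mode == "mip":
        lo[2] = hi[2] = config.field_size[2] / 2.0
    if np.any(lo > hi):
        raise ValueError("field too small for the requested geometry")

    inside_counts = {
        rule: int(round(config.n_cells * rule.fraction))
        for rule in config.placement_rules
    }

    positions = np.empty((config.n_cells, 3))
    for i in range(config.n_cells):
        for attempt in range(_MAX_REJECTION_TRIES):
            p = rng.uniform(lo, hi)
            if config.vessels:
                if min(v.axis_distance(p[None])[0] - v.radius for v in config.vessels) < 0:
                    continue  # inside a lumen
            if i > 0 and config.min_separation > 0:
                if np.min(np.linalg.norm(positions[:i] - p, axis=1)) < config.min_separation:
                    continue  # cell bodies must not interpenetrate
            ok = True
            # keep cells one voxel clear of each threshold boundary, so the
            # within-threshold counts survive rasterization of the geometry
            band = max(config.voxel_size)
            for rule, k in inside_counts.items():
                if rule.structure == "bone":
                    d = distance_to_bone(p[None], config.bone)[0]
                else:
                    d = distance_to_vessels(p[None], config.vessels)[0]
                want_inside = i < k
                inside = d <= max(rule.threshold_um - band, 0.0)
                outside = d > rule.threshold_um + band
                if (want_inside and not inside) or (not want_inside and not outside):
                    ok = False
                    break
            if ok:
                positions[i] = p
                break
        else:
            raise ValueError(
                "could not satisfy placement constraints "
                f"for cell {i}; geometry may be unsatisfiable"
            )
    return positions


# ---------------------------------------------------------------------------
# motion

def _random_unit(rng: np.random.Generator, planar: bool) -> np.ndarray:
    v = rng.normal(size=3)
    if planar:
        v[2] = 0.0
    n = np.linalg.norm(v)
    while n == 0:  # pragma: no cover - probability zero
        v = rng.normal(size=3)
        if planar:
            v[2] = 0.0
        n = np.linalg.norm(v)
    return v / n


def simulate_tracks(config: SimulationConfig) -> GroundTruth:
    """Persistent-random-walk tracks for every cell.

    Per frame the heading is a persistence-weighted blend of the previous
    heading and a fresh isotropic direction; step lengths are Gamma
    distributed with mean ``target_speed * frame_interval`` (shape 5, so
    speeds fluctuate realistically around the target).  Cells reflect at
    the field borders (and at the bone surface) so tracks never leave the
    imaging volume.
    """
    _, cell_rngs, _, _ = _streams(config)
    planar = config.mode == "mip"
    start = place_cells(config)
    margin = config.cell_diameter / 2.0
    lo = np.array([margin, margin, 0.0])
    hi = np.array(config.field_size) - [margin, margin, 0.0]
    if config.bone is not None:
        lo[2] = max(lo[2], config.bone.position)

    positions = np.empty((config.n_cells, config.n_frames, 3))
    for i, rng in enumerate(cell_rngs):
        params = config.regimes[config.cell_regimes[i]]
        mean_step = params.target_speed * config.frame_interval
        p = start[i].copy()
        positions[i, 0] = p
        heading = _random_unit(rng, planar)
        for t in range(1, config.n_frames):
            fresh = _random_unit(rng, planar)
            heading = params.persistence * heading + (1 - params.persistence) * fresh
            nrm = np.linalg.norm(heading)
            heading = heading / nrm if nrm > 0 else fresh
            if mean_step > 0:
                step = rng.gamma(shape=5.0, scale=mean_step / 5.0)
            else:
                step = 0.0
            p = p + step * heading
            # reflect into the box (per axis), flipping the heading component
            for ax in range(3):
                if planar and ax == 2:
                    continue
                if p[ax] < lo[ax]:
                    p[ax] = 2 * lo[ax] - p[ax]
                    heading[ax] = -heading[ax]
                elif p[ax] > hi[ax]:
                    p[ax] = 2 * hi[ax] - p[ax]
                    heading[ax] = -heading[ax]
                p[ax] = np.clip(p[ax], lo[ax], hi[ax])
            positions[i, t] = p

    return GroundTruth(
        positions=positions,
        regimes=tuple(config.cell_regimes),
        frame_interval=config.frame_interval,
        d_bone_t0=distance_to_bone(start, config.bone),
        d_vessel_t0=distance_to_vessels(start, config.vessels),
    )


# ---------------------------------------------------------------------------
# rendering

def _grid_shape(config: SimulationConfig) -> tuple[int, int, int]:
    nx = int(round(config.field_size[0] / config.voxel_size[0]))
    ny = int(round(config.field_size[1] / config.voxel_size[1]))
    nz = 1 if config.mode == "mip" else int(round(config.field_size[2] / config.voxel_size[2]))
    return nz, ny, nx


def _axis_centers(n: int, voxel: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * voxel


def _render_cell(
    green: np.ndarray,
    center: np.ndarray,
    radii: np.ndarray,
    config: SimulationConfig,
    amplitude: float,
) -> None:
    """Add one soft-edged ellipsoidal cell body into a (Z, Y, X) frame."""
    vz, vy, vx = config.voxel_size[2], config.voxel_size[1], config.voxel_size[0]
    nz, ny, nx = green.shape
    reach = radii.max() + 2.0  # um beyond the nominal edge
    if nz == 1:
        zs = np.array([0])
    else:
        z0 = max(0, int((center[2] - reach) / vz))
        z1 = min(nz, int((center[2] + reach) / vz) + 2)
        zs = np.arange(z0, z1)
    y0 = max(0, int((center[1] - reach) / vy))
    y1 = min(ny, int((center[1] + reach) / vy) + 2)
    x0 = max(0, int((center[0] - reach) / vx))
    x1 = min(nx, int((center[0] + reach) / vx) + 2)
    if y0 >= y1 or x0 >= x1 or zs.size == 0:
        return
    yc = _axis_centers(ny, vy)[y0:y1] - center[1]
    xc = _axis_centers(nx, vx)[x0:x1] - center[0]
    if nz == 1:
        zc = np.zeros(1)
    else:
        zc = _axis_centers(nz, vz)[zs] - center[2]
    # normalized ellipsoidal radius; logistic edge gives a plateau interior
    rho = np.sqrt(
        (zc[:, None, None] / radii[2]) ** 2
        + (yc[None, :, None] / radii[1]) ** 2
        + (xc[None, None, :] / radii[0]) ** 2
    )
    edge = 0.15  # relative softness of the membrane
    body = 1.0 / (1.0 + np.exp((rho - 1.0) / edge))
    green[zs[0] : zs[-1] + 1, y0:y1, x0:x1] += body


def render_movie(truth: GroundTruth, config: SimulationConfig) -> TimelapseMovie:
    """Rasterize ground truth into a calibrated three-channel movie.

    Green: sum of quasi-spherical cell bodies whose per-axis radii jitter
    each frame by up to the regime's protrusion amplitude (shape change
    independent of centroid motion).  Red: blurred vessel tubes.  Blue:
    blurred bone band.  Optional Poisson shot noise on top of a constant
    background; output is uint16.
    """
    if min(config.voxel_size[:2]) > config.cell_diameter:
        warnings.warn("voxel size exceeds cell diameter; cells are sub-resolution")
    _, _, render_rng, noise_rng = _streams(config)
    nz, ny, nx = _grid_shape(config)
    T = truth.n_frames
    noise = config.noise

    movie = np.zeros((T, 3, nz, ny, nx), dtype=np.float64)
    r0 = config.cell_diameter / 2.0

    # static niche channels
    vz, vy, vx = config.voxel_size[2], config.voxel_size[1], config.voxel_size[0]
    if config.vessels or config.bone is not None:
        zc = _axis_centers(nz, vz) if nz > 1 else np.array([config.field_size[2] / 2.0])
        yc = _axis_centers(ny, vy)
        xc = _axis_centers(nx, vx)
        Z, Y, X = np.meshgrid(zc, yc, xc, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
        if config.vessels:
            dv = np.min(
                [v.axis_distance(pts) - v.radius for v in config.vessels], axis=0
            ).reshape(nz, ny, nx)
            red = (dv <= 0).astype(float)
            movie[:, 1] = ndimage.gaussian_filter(red, sigma=1.0)
        if config.bone is not None:
            blue = (Z <= config.bone.position).astype(float)
            movie[:, 2] = ndimage.gaussian_filter(blue, sigma=1.0)

    # dynamic tumor channel; radii jitter drawn from one render stream in
    # (cell, frame) order so rendering is deterministic
    jitter = render_rng.uniform(-1.0, 1.0, size=(truth.n_cells, T, 3))
    for i in range(truth.n_cells):
        amp = config.regimes[truth.regimes[i]].protrusion_amplitude
        radii_all = np.maximum(r0 + amp * jitter[i], 0.3 * r0)
        for t in range(T):
            _render_cell(movie[t, 0], truth.positions[i, t], radii_all[t], config, amp)

    movie[:, 0] = np.minimum(movie[:, 0], 1.5)  # overlapping cells saturate
    out = noise.background + noise.signal * movie
    if noise.shot_noise:
        out = noise_rng.poisson(out).astype(np.float64)
    out = np.clip(out, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return TimelapseMovie(
        data=out,
        channels={"green": 0, "red": 1, "blue": 2},
        voxel_size=config.voxel_size,
        frame_interval=config.frame_interval,
    )


# ---------------------------------------------------------------------------
# survival

def simulate_survival(
    hazards: Mapping[str, float],
    n_per_group: int | Mapping[str, int],
    follow_up: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival times per group, censored at ``follow_up`` days.

    Returns a table with columns (time_days, event, group); event is 1 for
    death, 0 for censoring at end of follow-up.
    """
    if follow_up <= 0:
        raise ValueError("follow_up must be > 0 (time > 0 required)")
    for g, h in hazards.items():
        if h <= 0:
            raise ValueError(f"hazard for group {g!r} must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for group in hazards:
        n = n_per_group if isinstance(n_per_group, int) else n_per_group[group]
        if n < 1:
            raise ValueError("each group needs at least one subject")
        t = rng.exponential(1.0 / hazards[group], size=n)
        event = (t <= follow_up).astype(int)
        t = np.minimum(t, follow_up)
        for ti, ei in zip(t, event):
            rows.append({"time_days": float(ti), "event": int(ei), "group": group})
    return pd.DataFrame(rows)
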