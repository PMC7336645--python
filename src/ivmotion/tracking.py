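"""Fixed-scale spot detection and centroid tracking.

Tumor cells are detected as bright blobs of a single nominal diameter
(10 um by default) using a scale-matched Laplacian-of-Gaussian response
with sigma = diameter / (2 * sqrt(2)) in physical units, converted per axis
through the voxel calibration.  Local response maxima above a threshold
become spot centroids, refined to sub-pixel precision by an
intensity-weighted centroid in a diameter-sized window.

Centroids are linked frame to frame by greedy nearest-neighbour assignment
with a hard distance gate: candidate (track, detection) pairs are sorted by
distance (ties broken lexicographically on coordinates, so linking does not
depend on detection order) and accepted while both partners are free.
Unmatched detections open new tracks; there is no gap closing or division
handling.  A track's mean speed is its path length divided by elapsed time,
and only tracks with at least `min_length` frames enter speed statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SpotSet",
    "Track",
    "detect_spots",
    "detect_movie",
    "link_tracks",
    "mean_track_speed",
    "track_summary",
]


@dataclass
class SpotSet:
    """Detections of one movie: per frame an (n_i, D) array of um coords."""

    frames: list[np.ndarray]
    scores: list[np.ndarray]
    diameter: float  # nominal um

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def counts(self) -> list[int]:
        return [len(f) for f in self.frames]


@dataclass
class Track:
    track_id: int
    frames: list[int] = field(default_factory=list)
    points: list[np.ndarray] = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points)


def _log_sigma_vox(diameter: float, voxel_size: np.ndarray) -> np.ndarray:
    """Per-axis LoG sigma (voxels) matched to a blob of `diameter` um."""
    sigma_um = diameter / (2.0 * np.sqrt(2.0))
    return sigma_um / voxel_size


def detect_spots(
    image: np.ndarray,
    voxel_size: float | tuple[float, ...],
    diameter: float = 10.0,
    threshold_rel: float = 0.2,
    threshold_abs: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect spots of one nominal diameter in a 2D frame or 3D volume.

    Parameters
    ----------
    image : (Y, X) or (Z, Y, X) intensity array.
    voxel_size : um per pixel; scalar or per-axis in array order.
    diameter : nominal spot diameter in um.
    threshold_rel : fraction of the maximum LoG response required for a
        peak (used when `threshold_abs` is None).
    threshold_abs : absolute LoG response threshold, overrides the relative
        one; useful for comparable thresholds across frames.

    Returns
    -------
    centroids : (n, D) physical coordinates in um, axis order matching the
        array axes (i.e. (y, x) or (z, y, x)); sub-pixel refined.
    scores : (n,) LoG response at each peak.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim not in (2, 3):
        raise ValueError("image must be 2D or 3D")
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (img.ndim,)).copy()
    if np.any(diameter < 2.0 * vs):
        raise ValueError("sub-resolution: diameter spans fewer than 2 pixels")
    sigma = _log_sigma_vox(diameter, vs)
    # scale-normalized LoG; bright blobs give positive peaks
    response = -ndimage.gaussian_laplace(img, sigma=sigma) * float(np.mean(sigma) ** 2)
    if threshold_abs is None:
        rmax = response.max()
        if rmax <= 0:
            return np.empty((0, img.ndim)), np.empty((0,))
        thr = threshold_rel * rmax
    else:
        thr = threshold_abs
    # peaks must dominate a neighbourhood about half a diameter wide
    size = np.maximum(3, (0.7 * diameter / vs).astype(int) | 1)
    footprint = np.ones(tuple(size), dtype=bool)
    local_max = response == ndimage.maximum_filter(response, footprint=footprint)
    peaks = np.argwhere(local_max & (response > thr))
    if peaks.size == 0:
        return np.empty((0, img.ndim)), np.empty((0,))
    # deterministic order independent of argwhere internals
    order = np.lexsort(tuple(peaks[:, d] for d in reversed(range(img.ndim))))
    peaks = peaks[order]

    centroids = np.empty((len(peaks), img.ndim))
    scores = np.empty(len(peaks))
    half = np.maximum(1, np.round(0.5 * diameter / vs).astype(int))
    bg = float(np.median(img))
    for k, p in enumerate(peaks):
        sl = tuple(
            slice(max(0, p[d] - half[d]), min(img.shape[d], p[d] + half[d] + 1))
            for d in range(img.ndim)
        )
        w = np.clip(img[sl] - bg, 0, None)
        tot = w.sum()
        if tot == 0:
            centroids[k] = p
        else:
            grids = np.meshgrid(
                *[np.arange(s.start, s.stop) for s in sl], indexing="ij"
            )
            centroids[k] = [float((g * w).sum() / tot) for g in grids]
        scores[k] = response[tuple(p)]
    centroids = (centroids + 0.5) * vs  # voxel index -> um at voxel centre
    return centroids, scores


def detect_movie(
    frames: np.ndarray,
    voxel_size: float | tuple[float, ...],
    diameter: float = 10.0,
    threshold_rel: float = 0.2,
    threshold_abs: float | None = None,
) -> SpotSet:
    """Run `detect_spots` on every frame of a (T, ...) stack."""
    spots, scores = [], []
    for t in range(frames.shape[0]):
        c, s = detect_spots(
            frames[t], voxel_size, diameter, threshold_rel, threshold_abs
        )
        spots.append(c)
        scores.append(s)
    return SpotSet(frames=spots, scores=scores, diameter=diameter)


def _lex_key(point: np.ndarray) -> tuple:
    return tuple(float(x) for x in point)


def link_tracks(spots: SpotSet, max_step: float) -> list[Track]:
    """Greedy nearest-neighbour frame-to-frame linking with a distance gate.

    Deterministic: candidate links are sorted by (distance, track endpoint,
    detection coordinates), so the result is invariant to the order in
    which detections are listed within a frame.
    """
    if max_step <= 0:
        raise ValueError("max_step must be > 0")
    if spots.n_frames < 2:
        raise ValueError("need detections from at least two frames")

    tracks: list[Track] = []
    active: list[Track] = []
    next_id = 0
    for i, p in enumerate(sorted(spots.frames[0], key=_lex_key)):
        tr = Track(track_id=next_id, frames=[0], points=[np.asarray(p, float)])
        next_id += 1
        tracks.append(tr)
        active.append(tr)

    for t in range(1, spots.n_frames):
        dets = [np.asarray(p, float) for p in spots.frames[t]]
        dets.sort(key=_lex_key)
        candidates = []
        for ai, tr in enumerate(active):
            last = tr.points[-1]
            for di, d in enumerate(dets):
                dist = float(np.linalg.norm(d - last))
                if dist <= max_step:
                    candidates.append((dist, _lex_key(last), _lex_key(d), ai, di))
        candidates.sort()
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, _, _, ai, di in candidates:
            if ai in used_tracks or di in used_dets:
                continue
            active[ai].frames.append(t)
            active[ai].points.append(dets[di])
            used_tracks.add(ai)
            used_dets.add(di)
        new_active = [tr for ai, tr in enumerate(active) if ai in used_tracks]
        for di, d in enumerate(dets):
            if di not in used_dets:
                tr = Track(track_id=next_id, frames=[t], points=[d])
                next_id += 1
                tracks.append(tr)
                new_active.append(tr)
        active = new_active
    return tracks


def mean_track_speed(track: Track, frame_interval: float) -> float:
    """Path length / elapsed time, in um/min."""
    if track.n_points < 2:
        raise ValueError("single-point track has no speed")
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    pts = track.as_array()
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return float(steps.sum() / ((track.n_points - 1) * frame_interval))


def track_summary(
    tracks: list[Track],
    frame_interval: float,
    min_length: int = 5,
    group: str | None = None,
) -> pd.DataFrame:
    """Per-track speed table; tracks shorter than `min_length` are dropped."""
    rows = []
    n_excluded = 0
    for tr in tracks:
        if tr.n_points < max(2, min_length):
            n_excluded += 1
            continue
        rows.append(
            {
                "track_id": tr.track_id,
                "n_frames": tr.n_points,
                "mean_speed_um_min": mean_track_speed(tr, frame_interval),
            }
        )
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} track(s) shorter than {min_length} frames"
        )
    df = pd.DataFrame(rows, columns=["track_id", "n_frames", "mean_speed_um_min"])
    if group is not None:
        df["group"] = group
    return df
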