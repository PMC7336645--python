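"""Distance-to-niche analysis: bone and vessel proximity of tumor cells.

From a 3D two-channel anatomy (red = vessels, blue = bone/SHG) the niche
structures are segmented by Otsu thresholding, converted into an exact
anisotropic Euclidean distance field ("distance gradient", um), and the
field is sampled by trilinear interpolation at every detected cell
centroid.  Summaries report, per experimental group, the distance
histogram, the mean distance, and the fraction of cells within a threshold
of each surface (bone 15 um and vessels 5 um by default); two-group
distribution comparisons use the two-sample Kolmogorov-Smirnov test.

Distances are measured to the segmented occupancy, so a cell centroid that
falls inside a vessel lumen or the bone band has distance 0; distances are
never negative.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .displacement import _otsu_threshold
from . import stats as ivstats

__all__ = [
    "segment_structure",
    "distance_field",
    "sample_spot_distances",
    "summarize_distances",
]


def segment_structure(
    volume: np.ndarray, largest_component: bool = False
) -> np.ndarray:
    """Binary occupancy of a structure channel via Otsu thresholding.

    Optionally keeps only the largest connected component (26-connectivity)
    to suppress speckle.
    """
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("expected a 3D single-channel volume")
    if vol.min() == vol.max():
        raise ValueError("degenerate histogram: constant channel")
    mask = vol > _otsu_threshold(vol)
    if largest_component and mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def distance_field(
    mask: np.ndarray, voxel_size: tuple[float, float, float]
) -> np.ndarray:
    """Exact Euclidean distance (um) to the structure, anisotropic voxels.

    `voxel_size` is given in array-axis order (z, y, x).  The field is 0 on
    structure voxels and 1-Lipschitz in physical units.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty structure mask")
    if any(v <= 0 for v in voxel_size):
        raise ValueError("voxel sizes must be > 0")
    return ndimage.distance_transform_edt(~m, sampling=voxel_size)


def sample_spot_distances(
    spots_um: np.ndarray,
    field: np.ndarray,
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Trilinearly interpolate a distance field at spot positions.

    `spots_um` is (n, 3) in array-axis order (z, y, x), um; `voxel_size`
    likewise.  Physical position p maps to fractional index p/v - 0.5
    (voxel centres).  Spots outside the volume are returned as NaN with a
    warning; callers should drop them.
    """
    pts = np.atleast_2d(np.asarray(spots_um, dtype=float))
    if pts.shape[1] != field.ndim:
        raise ValueError("spot dimensionality does not match the field")
    vs = np.asarray(voxel_size, dtype=float)
    extent = np.asarray(field.shape) * vs
    inside = np.all((pts >= 0) & (pts <= extent), axis=1)
    if not inside.all():
        warnings.warn(
            f"excluded {int((~inside).sum())} out-of-bounds spot(s) from "
            "distance sampling"
        )
    idx = pts / vs - 0.5
    # clamp to the centre grid so border spots use the edge voxel value
    idx = np.clip(idx.T, 0, (np.asarray(field.shape) - 1)[:, None])
    vals = ndimage.map_coordinates(field, idx, order=1, mode="nearest")
    vals[~inside] = np.nan
    return vals


def summarize_distances(
    samples: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
    bin_width: float = 5.0,
) -> dict:
    """Group-level localization summary.

    `samples` must have a `group` column and one or both of `d_bone_um`,
    `d_vessel_um`.  For every structure and group the mean distance, the
    histogram (fixed `bin_width` um bins from 0) and the fraction of cells
    within the structure's threshold are reported; for exactly two groups a
    Kolmogorov-Smirnov comparison is added.
    """
    if len(samples) == 0:
        raise ValueError("no distance samples")
    thresholds = {"bone": 15.0, "vessel": 5.0, **(thresholds or {})}
    out: dict = {"groups": sorted(samples["group"].unique()), "structures": {}}
    for structure in ("bone", "vessel"):
        col = f"d_{structure}_um"
        if col not in samples.columns:
            continue
        sub = samples.dropna(subset=[col])
        thr = thresholds[structure]
        entry: dict = {"threshold_um": thr, "per_group": {}}
        for g, grp in sub.groupby("group"):
            d = grp[col].to_numpy()
            edges = np.arange(0, max(d.max(), bin_width) + bin_width, bin_width)
            hist, _ = np.histogram(d, bins=edges)
            entry["per_group"][g] = {
                "n": int(d.size),
                "mean_um": float(d.mean()),
                "median_um": float(np.median(d)),
                "fraction_within": float((d <= thr).mean()),
                "hist_edges_um": edges.tolist(),
                "hist_counts": hist.tolist(),
            }
        groups = sorted(entry["per_group"])
        if len(groups) == 2:
            a = sub.loc[sub["group"] == groups[0], col].to_numpy()
            b = sub.loc[sub["group"] == groups[1], col].to_numpy()
            ks = ivstats.ks_two_sample(a, b)
            entry["ks"] = {
                "D": ks.statistic,
                "p": ks.pvalue,
                "verdict": "NS" if ks.pvalue >= 0.05 else "significant",
            }
        out["structures"][structure] = entry
    if not out["structures"]:
        raise ValueError("samples contain no d_bone_um / d_vessel_um columns")
    return out
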