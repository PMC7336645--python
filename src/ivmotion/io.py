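"""OME-TIFF movie IO, ground-truth tables, and run manifests.

Movies are stored as OME-TIFF with axes TCZYX; the physical voxel size
(um) and the frame interval (min) are written into the OME metadata, so a
round trip through disk preserves both the intensities (bitwise) and the
calibration.  Ground truth and analysis outputs are plain CSV with a
``# manifest: <hash>`` header line; summary files are JSON.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from .simulate import CHANNEL_ROLES, GroundTruth, TimelapseMovie

__all__ = [
    "write_movie",
    "read_movie",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_csv",
    "read_csv",
    "manifest_hash",
    "write_manifest",
]

DEFAULT_CHANNEL_MAP: Mapping[str, int] = {"green": 0, "red": 1, "blue": 2}


def write_movie(movie: TimelapseMovie, path: str | Path) -> Path:
    """Write a calibrated movie as OME-TIFF (axes TCZYX)."""
    path = Path(path)
    vx, vy, vz = movie.voxel_size
    names = [r for r, _ in sorted(movie.channels.items(), key=lambda kv: kv[1])]
    tifffile.imwrite(
        path,
        movie.data,
        ome=True,
        metadata={
            "axes": "TCZYX",
            "PhysicalSizeX": vx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": vy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": vz,
            "PhysicalSizeZUnit": "µm",
            "TimeIncrement": movie.frame_interval,
            "TimeIncrementUnit": "min",
            "Channel": {"Name": names},
        },
    )
    return path


def _pixels_attrs(path: Path) -> dict:
    with tifffile.TiffFile(path) as tf:
        if tf.ome_metadata is None:
            return {}
        meta = tifffile.xml2dict(tf.ome_metadata)
    image = meta.get("OME", {}).get("Image", {})
    if isinstance(image, list):
        image = image[0]
    return image.get("Pixels", {})


def read_movie(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
    frame_interval: float | None = None,
) -> TimelapseMovie:
    """Read an OME-TIFF movie back into a calibrated TimelapseMovie.

    Calibration comes from the OME metadata unless explicitly overridden;
    a file without calibration and without overrides is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
    # normalize to TCZYX
    axes = axes.replace("S", "C")
    if set(axes) <= set("TCZYX") and len(set(axes)) == len(axes):
        for missing in set("TCZYX") - set(axes):
            data = data[np.newaxis]
            axes = missing + axes
        order = [axes.index(a) for a in "TCZYX"]
        data = np.transpose(data, order)
    else:
        # plain TIFF with anonymous leading dimensions: read them as
        # (T[, C[, Z]]) in front of the trailing YX plane
        if data.ndim < 2 or data.ndim > 5:
            raise ValueError(f"{path.name}: cannot interpret {data.ndim}D TIFF")
        lead = list(data.shape[:-2]) + [1, 1, 1]
        t, c, z = lead[:3]
        data = data.reshape(t, c, z, *data.shape[-2:])

    pixels = _pixels_attrs(path)
    if voxel_size is None:
        try:
            voxel_size = (
                float(pixels["PhysicalSizeX"]),
                float(pixels["PhysicalSizeY"]),
                float(pixels["PhysicalSizeZ"]),
            )
        except KeyError:
            raise ValueError(
                f"{path.name}: no voxel size in metadata; pass voxel_size=(x, y, z) um"
            )
    if frame_interval is None:
        if "TimeIncrement" in pixels:
            frame_interval = float(pixels["TimeIncrement"])
        else:
            raise ValueError(
                f"{path.name}: no frame interval in metadata; pass frame_interval (min)"
            )
    if any(v <= 0 for v in voxel_size) or frame_interval <= 0:
        raise ValueError("calibration must be strictly positive")

    if channel_map is None:
        channel_map = {
            role: idx
            for role, idx in DEFAULT_CHANNEL_MAP.items()
            if idx < data.shape[1]
        }
    for role, idx in channel_map.items():
        if role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {role!r}")
        if not 0 <= idx < data.shape[1]:
            raise ValueError(f"channel index {idx} for {role!r} out of range")
    return TimelapseMovie(
        data=data,
        channels=dict(channel_map),
        voxel_size=tuple(voxel_size),
        frame_interval=float(frame_interval),
    )


# ---------------------------------------------------------------------------
# tables and manifests

def manifest_hash(manifest: dict) -> str:
    payload = json.dumps(manifest, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(manifest: dict, path: str | Path) -> str:
    """Write a JSON run manifest; returns its hash (also stored inside)."""
    h = manifest_hash(manifest)
    out = {"manifest_hash": h, **manifest}
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True, default=str))
    return h


def write_csv(df: pd.DataFrame, path: str | Path, manifest_hash: str | None = None) -> Path:
    """CSV writer that stamps the manifest hash as a comment header."""
    path = Path(path)
    buf = _io.StringIO()
    if manifest_hash is not None:
        buf.write(f"# manifest: {manifest_hash}\n")
    df.to_csv(buf, index=False, lineterminator="\n", float_format="%.6f")
    path.write_text(buf.getvalue())
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_tracks_csv(
    truth_or_df: GroundTruth | pd.DataFrame,
    path: str | Path,
    manifest_hash: str | None = None,
) -> Path:
    df = truth_or_df.to_frame() if isinstance(truth_or_df, GroundTruth) else truth_or_df
    return write_csv(df, path, manifest_hash)


def read_tracks_csv(path: str | Path) -> pd.DataFrame:
    return read_csv(path)
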