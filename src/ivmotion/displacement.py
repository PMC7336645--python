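"""Displacement-area-ratio statistic for time-lapse cell masks.

The motility readout works on the green (tumor) channel of a
maximum-intensity-projection movie: one Otsu threshold is computed from the
intensity histogram of *all* frames pooled together, every frame is
binarized against it, the binary masks are median-filter denoised, and the
intersection-over-union (IoU) between successive frame masks is computed.
The per-pair "displacement area ratio" is 1 - IoU: near 0 for arrested
cells that barely change shape or position, near 1 for motile cells.

A single pooled threshold (rather than per-frame Otsu) keeps the masks
comparable across frames, so intensity drift is not confounded with
motility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "MIPSequence",
    "BinaryMaskSequence",
    "DisplacementResult",
    "pooled_otsu_threshold",
    "binarize_and_denoise",
    "iou_pair",
    "displacement_series",
    "displacement_pipeline",
]


@dataclass(frozen=True)
class MIPSequence:
    """A (T, Y, X) single-channel intensity movie with calibration."""

    frames: np.ndarray
    pixel_size: float  # um
    frame_interval: float  # min

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError("frames must be a (T, Y, X) array")
        if f.shape[0] < 2:
            raise ValueError("need at least two frames")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("calibration must be strictly positive")
        object.__setattr__(self, "frames", f)


@dataclass(frozen=True)
class BinaryMaskSequence:
    masks: np.ndarray  # (T, Y, X) bool
    threshold_used: float
    kernel_used: int


@dataclass(frozen=True)
class DisplacementResult:
    iou: np.ndarray  # (T-1,)
    displacement_ratio: np.ndarray  # (T-1,) = 1 - iou
    mean_ratio: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_pair": [f"{t}-{t + 1}" for t in range(len(self.iou))],
                "iou": self.iou,
                "displacement_ratio": self.displacement_ratio,
            }
        )


def _otsu_threshold(values: np.ndarray) -> float:
    """Otsu threshold of a pooled sample; foreground is ``value > t``.

    Integer data up to 16 bit are scanned over every integer candidate;
    float data over 256 equal-width bins.  Among ties the lowest threshold
    wins.  Implemented directly from the between-class-variance criterion.
    """
    v = np.asarray(values).ravel()
    vmin, vmax = v.min(), v.max()
    if vmin == vmax:
        raise ValueError("degenerate histogram: constant image")
    if np.issubdtype(v.dtype, np.integer) and int(vmax) - int(vmin) <= 65535:
        # exact: one histogram bin per integer value
        counts = np.bincount(
            (v.astype(np.int64) - int(vmin)), minlength=int(vmax) - int(vmin) + 1
        ).astype(np.float64)
        centers = np.arange(int(vmin), int(vmax) + 1, dtype=np.float64)
    else:
        counts, edges = np.histogram(v.astype(np.float64), bins=256)
        counts = counts.astype(np.float64)
        centers = (edges[:-1] + edges[1:]) / 2.0
    # candidate threshold t = centers[j]: class 0 is bins 0..j, class 1 the rest
    total = counts.sum()
    w0 = np.cumsum(counts)[:-1]
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    tsum = float((counts * centers).sum())
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, csum / np.maximum(w0, 1), 0.0)
    mu1 = np.where(valid, (tsum - csum) / np.maximum(w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return float(centers[int(np.argmax(between))])


def pooled_otsu_threshold(seq: MIPSequence | np.ndarray) -> float:
    """Otsu threshold over the histogram of all frames pooled together."""
    frames = seq.frames if isinstance(seq, MIPSequence) else np.asarray(seq)
    return _otsu_threshold(frames)


def binarize_and_denoise(
    seq: MIPSequence | np.ndarray, threshold: float, kernel: int = 3
) -> BinaryMaskSequence:
    """Threshold every frame (strict ``> threshold``) and median-denoise.

    ``kernel`` is the odd side length of the square median window applied
    per frame (reflect padding at the borders); kernel=1 is the identity.
    """
    frames = seq.frames if isinstance(seq, MIPSequence) else np.asarray(seq)
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("median kernel must be odd and >= 1")
    raw = frames > threshold
    if kernel == 1:
        masks = raw
    else:
        masks = np.empty_like(raw)
        for t in range(raw.shape[0]):
            masks[t] = (
                ndimage.median_filter(
                    raw[t].astype(np.uint8), size=kernel, mode="reflect"
                )
                > 0
            )
    return BinaryMaskSequence(masks=masks, threshold_used=float(threshold), kernel_used=kernel)


def iou_pair(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks.

    Both masks empty means nothing moved (IoU 1, displacement 0); exactly
    one empty means complete displacement (IoU 0).  Both degenerate cases
    are reported with a warning.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        warnings.warn("both masks empty; IoU defined as 1")
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    if inter == 0 and (not a.any() or not b.any()):
        warnings.warn("one mask empty; IoU defined as 0")
        return 0.0
    return inter / union


def displacement_series(masks: BinaryMaskSequence | np.ndarray) -> DisplacementResult:
    """IoU and 1 - IoU between every pair of successive frame masks."""
    m = masks.masks if isinstance(masks, BinaryMaskSequence) else np.asarray(masks, bool)
    if m.shape[0] < 2:
        raise ValueError("need at least two frames")
    ious = np.array([iou_pair(m[t], m[t + 1]) for t in range(m.shape[0] - 1)])
    ratios = 1.0 - ious
    return DisplacementResult(iou=ious, displacement_ratio=ratios, mean_ratio=float(ratios.mean()))


def displacement_pipeline(
    seq: MIPSequence, kernel: int = 3
) -> tuple[DisplacementResult, BinaryMaskSequence]:
    """Pooled Otsu -> binarize -> median denoise -> successive-frame IoU."""
    thr = pooled_otsu_threshold(seq)
    masks = binarize_and_denoise(seq, thr, kernel)
    return displacement_series(masks), masks
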