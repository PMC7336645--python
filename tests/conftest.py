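"""Shared fixtures and brute-force oracles.

The oracles deliberately re-derive each quantity the slowest, most explicit
way (per-pixel loops, exhaustive scans, pairwise distances) so they stay
independent of the library code paths they validate.
"""

from __future__ import annotations

import numpy as np
import pytest


def brute_force_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Pixel-by-pixel intersection and union counting."""
    inter = union = 0
    for pa, pb in zip(np.asarray(a, bool).ravel(), np.asarray(b, bool).ravel()):
        if pa and pb:
            inter += 1
        if pa or pb:
            union += 1
    return 1.0 if union == 0 else inter / union


def brute_force_otsu_8bit(values: np.ndarray) -> int:
    """Exhaustive intra-class-variance scan over all 8-bit thresholds."""
    v = np.asarray(values, dtype=float).ravel()
    best_t, best_icv = None, np.inf
    for t in range(256):
        lo, hi = v[v <= t], v[v > t]
        if lo.size == 0 or hi.size == 0:
            continue
        icv = lo.size * lo.var() + hi.size * hi.var()
        if icv < best_icv - 1e-9:
            best_icv, best_t = icv, t
    return best_t


def brute_force_median(mask: np.ndarray, kernel: int) -> np.ndarray:
    """Direct per-pixel median of a binary image, reflect padding."""
    r = kernel // 2
    # edge-inclusive reflection: border pixels are mirrored including
    # themselves, matching the filter's documented boundary handling
    padded = np.pad(mask.astype(np.uint8), r, mode="symmetric")
    out = np.zeros_like(mask, dtype=bool)
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            win = padded[i : i + kernel, j : j + kernel]
            out[i, j] = np.median(win) > 0
    return out


def brute_force_distance_field(
    mask: np.ndarray, voxel_size: tuple[float, float, float]
) -> np.ndarray:
    """Nearest-structure-voxel search in physical units."""
    vs = np.asarray(voxel_size, dtype=float)
    targets = np.argwhere(mask) * vs
    out = np.empty(mask.shape)
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx) * vs
        out[idx] = np.sqrt(((targets - p) ** 2).sum(axis=1)).min()
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort_config():
    """A quick single-regime cohort used across modules."""
    import ivmotion as m

    def make(regime: str, seed: int = 0, **kw):
        kw.setdefault("n_cells", 8)
        kw.setdefault("n_frames", 12)
        kw.setdefault("field_size", (150.0, 150.0, 40.0))
        kw.setdefault("voxel_size", (1.0, 1.0, 2.0))
        return m.SimulationConfig.cohort(regime, seed=seed, **kw)

    return make
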