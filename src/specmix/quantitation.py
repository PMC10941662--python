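"""Quantitation of unmixed channels: signal-to-background, subcellular-voxel
relative quantitation, and display scaling.

Amplified signal scales approximately linearly with the number of target
molecules per voxel, so two channels that redundantly detect the same target
should produce a tight linear voxel scatter through the origin.  Voxel
intensities are aggregated by *sum* (a voxel's signal models molecule count;
summing preserves linearity in content) and normalized by a high quantile
(robust to isolated hot voxels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .unmixing import UnmixedImage

__all__ = [
    "VoxelTable",
    "ScatterStats",
    "signal_to_background",
    "bin_voxels",
    "normalize_voxels",
    "qhcr_scatter_stats",
    "display_scale",
]


def signal_to_background(
    channel_image: np.ndarray,
    high_mask: np.ndarray,
    low_mask: np.ndarray,
) -> float:
    """Signal-to-background from a high-expression and a low-expression region.

    ``(mean_high − mean_low) / mean_low``.  Measuring "background" in a region
    of little or no expression over-counts background (it may include true
    signal), so this is a conservative lower bound on the true S/B.
    """
    img = np.asarray(channel_image, dtype=float)
    hi = np.asarray(high_mask, dtype=bool)
    lo = np.asarray(low_mask, dtype=bool)
    if not hi.any() or not lo.any():
        raise ValueError("both masks must be non-empty")
    if np.any(hi & lo):
        raise ValueError("high and low masks overlap")
    mean_hi = img[hi].mean()
    mean_lo = img[lo].mean()
    if mean_lo == 0:
        raise ValueError(
            "zero background estimate; consider adding a read-noise floor to the image"
        )
    return float((mean_hi - mean_lo) / mean_lo)


@dataclass
class VoxelTable:
    """Per-voxel summed channel intensities.

    ``table`` has columns ``vz, vy, vx`` (voxel indices) plus one column per
    channel; voxels cover full pixel blocks only (trailing partial blocks on
    each axis are dropped).
    """

    table: pd.DataFrame
    voxel_size_um: tuple[float, float, float]
    pixels_per_voxel: tuple[int, int, int]
    channel_names: list[str]


def bin_voxels(
    unmixed: UnmixedImage,
    voxel_size_um: tuple[float, float, float],
) -> VoxelTable:
    """Aggregate an unmixed image into subcellular voxels.

    Pixels per voxel on each axis = ``round(voxel_size / pixel_size)`` with a
    minimum of 1 (the physical ratio is rarely an exact integer, e.g. 2.0 µm
    voxels over 0.18 µm pixels → 11 pixels).  Aggregation is the sum of raw
    unmixed intensities; trailing pixels that do not fill a block are dropped.
    """
    if len(voxel_size_um) != 3:
        raise ValueError("voxel_size_um must be (z, y, x)")
    px = unmixed.pixel_size
    for v, p in zip(voxel_size_um, px):
        if v < p:
            raise ValueError(f"voxel size {v} µm smaller than pixel size {p} µm")
    nper = tuple(max(1, round(v / p)) for v, p in zip(voxel_size_um, px))
    coeffs = unmixed.coefficients
    nz, ny, nx, c = coeffs.shape
    counts = (nz // nper[0], ny // nper[1], nx // nper[2])
    if min(counts) == 0:
        raise ValueError("image smaller than one voxel on some axis")
    trimmed = coeffs[
        : counts[0] * nper[0], : counts[1] * nper[1], : counts[2] * nper[2], :
    ]
    blocks = trimmed.reshape(
        counts[0], nper[0], counts[1], nper[1], counts[2], nper[2], c
    )
    sums = blocks.sum(axis=(1, 3, 5))  # (Vz, Vy, Vx, C)
    vz, vy, vx = np.meshgrid(*(np.arange(n) for n in counts), indexing="ij")
    df = pd.DataFrame({"vz": vz.ravel(), "vy": vy.ravel(), "vx": vx.ravel()})
    for j, name in enumerate(unmixed.channel_names):
        df[name] = sums[..., j].ravel()
    return VoxelTable(
        table=df,
        voxel_size_um=tuple(float(v) for v in voxel_size_um),
        pixels_per_voxel=nper,
        channel_names=list(unmixed.channel_names),
    )


def normalize_voxels(
    table: VoxelTable,
    channel: str,
    quantile: float = 0.999,
) -> np.ndarray:
    """Channel voxel intensities divided by the channel's given quantile.

    Values above the quantile exceed 1 (no clipping).  Quantile rather than
    max keeps the scale robust to single hot voxels.
    """
    if channel not in table.channel_names:
        raise KeyError(f"channel {channel!r} not in table ({table.channel_names})")
    vals = table.table[channel].to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("empty voxel table")
    divisor = float(np.quantile(vals, quantile))
    if divisor <= 0:
        raise ValueError(f"channel {channel!r} is all zero; cannot normalize")
    return vals / divisor


@dataclass(frozen=True)
class ScatterStats:
    """Linearity statistics of a two-channel voxel scatter."""

    pearson_r: float
    slope_through_origin: float
    slope: float
    intercept: float
    n_voxels: int


def qhcr_scatter_stats(
    a: np.ndarray,
    b: np.ndarray,
) -> ScatterStats:
    """Pearson correlation and linear fits for paired voxel intensities.

    Reports the product-moment correlation, the through-origin slope
    ``Σab/Σa²``, and the ordinary-least-squares slope/intercept (the free
    intercept makes "zero intercept" accuracy checkable).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    n = a.size
    if n < 2:
        raise ValueError("need at least two voxels")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("degenerate scatter: zero variance in a channel")
    da, db = a - a.mean(), b - b.mean()
    r = float((da @ db) / np.sqrt((da @ da) * (db @ db)))
    slope0 = float((a @ b) / (a @ a))
    slope = float((da @ db) / (da @ da))
    intercept = float(b.mean() - slope * a.mean())
    return ScatterStats(
        pearson_r=r,
        slope_through_origin=slope0,
        slope=slope,
        intercept=intercept,
        n_voxels=n,
    )


def qhcr_scatter_from_table(
    table: VoxelTable,
    channel_a: str,
    channel_b: str,
    quantile: float = 0.999,
) -> ScatterStats:
    """Normalize two channels of a voxel table and compute scatter stats."""
    a = normalize_voxels(table, channel_a, quantile)
    b = normalize_voxels(table, channel_b, quantile)
    return qhcr_scatter_stats(a, b)


def display_scale(
    images: list[np.ndarray],
    saturation_fraction: float = 0.001,
) -> list[np.ndarray]:
    """Scale replicate images to 8-bit with a shared clip level.

    The clip value is the ``1 − saturation_fraction`` quantile pooled across
    all provided replicates, so (up to quantile granularity) exactly that top
    fraction of pixels saturates; the map is linear from [0, clip] to
    [0, 255].  ``saturation_fraction=0`` clips at the pooled maximum, so no
    pixel is pushed into saturation (single-molecule display convention).
    """
    if not 0 <= saturation_fraction < 1:
        raise ValueError("saturation_fraction must be in [0, 1)")
    pooled = np.concatenate([np.asarray(im, dtype=float).ravel() for im in images])
    if pooled.size == 0:
        raise ValueError("no pixels to scale")
    clip = float(pooled.max()) if saturation_fraction == 0 else float(
        np.quantile(pooled, 1.0 - saturation_fraction)
    )
    out = []
    for im in images:
        arr = np.asarray(im, dtype=float)
        if clip <= 0:
            scaled = np.zeros(arr.shape)
        else:
            # 255 is reserved for clipped pixels so the saturated count is
            # exactly the count of values at or above the clip level
            scaled = np.where(arr >= clip, 255.0, np.floor(arr / clip * 255.0))
        out.append(scaled.astype(np.uint8))
    return out
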