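"""Chromatin spatial heterogeneity: segmentation, COV, masks, volume.

The heterogeneity statistic is the coefficient of variation of the
intra-nuclear fluorescence intensity,

    COV = std(I) / (mean(I) - background),

with the background measured from cell-free image regions. Gaussian blur is
applied only when building the segmentation mask; the COV itself is computed
on raw intensities (blurring would systematically deflate it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import morphology

from nucphase.thresholds import otsu_threshold


@dataclass
class NucleusMask:
    mask: np.ndarray  # boolean, single connected component
    area_um2: float
    label: int


@dataclass
class HeterogeneityResult:
    cov: float
    mean_intensity: float
    std_intensity: float
    background: float
    dimensionality: str  # "2d" or "3d"


@dataclass
class VolumeResult:
    volume_um3: float
    n_slices: int
    z_step: float


def segment_nucleus(
    image: np.ndarray,
    pixel_size: float,
    blur_sigma_px: float = 1.0,
    min_size_um2: float = 10.0,
) -> list[NucleusMask]:
    """Segment nuclei: 1 px Gaussian blur, 256-bin Otsu threshold, connected
    components, and a minimum-area filter (10 um^2 by default).

    A constant image has no threshold; returns an empty list with a warning.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_nucleus expects a 2D image or z-slice")
    blurred = ndimage.gaussian_filter(img, blur_sigma_px)
    if blurred.max() == blurred.min():
        warnings.warn("constant image: no Otsu threshold, returning no masks")
        return []
    thr = otsu_threshold(blurred)
    labels, n = ndimage.label(blurred > thr)
    out = []
    px_area = pixel_size**2
    for lab in range(1, n + 1):
        m = labels == lab
        area = m.sum() * px_area
        if area >= min_size_um2:
            out.append(NucleusMask(m, float(area), lab))
    return out


def estimate_background(
    image: np.ndarray, cellfree_region: np.ndarray, masks: list[NucleusMask] | None = None
) -> float:
    """Median intensity over a cell-free region of the image.

    The region must not overlap any provided nucleus mask.
    """
    region = np.asarray(cellfree_region, dtype=bool)
    if not region.any():
        raise ValueError("cell-free region is empty")
    if masks:
        for m in masks:
            if (region & m.mask).any():
                raise ValueError("cell-free region overlaps a nucleus mask")
    return float(np.median(np.asarray(image, dtype=float)[region]))


def compute_cov(
    image: np.ndarray,
    mask: np.ndarray,
    background: float,
    dimensionality: str = "2d",
) -> HeterogeneityResult:
    """COV = std / (mean - background) over raw in-mask intensities.

    ``dimensionality`` records whether the voxels come from a mid-plane
    ("2d") or a full z-stack ("3d"); the arithmetic is identical, the image
    and mask just carry an extra axis in 3D.
    """
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if img.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    if not m.any():
        raise ValueError("mask is empty")
    vals = img[m]
    mean, std = float(vals.mean()), float(vals.std())
    if mean <= background:
        raise ValueError(
            f"mean intensity {mean:.3g} <= background {background:.3g}; "
            "check the background region"
        )
    return HeterogeneityResult(
        cov=std / (mean - background),
        mean_intensity=mean,
        std_intensity=std,
        background=float(background),
        dimensionality=dimensionality,
    )


def interior_periphery(
    nucleus_mask: np.ndarray, erosion_radius_px: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Split a nucleus mask into interior (eroded) and periphery (rest).

    The default 3 px disk corresponds to ~0.4 um at 0.133 um/px. The two
    masks partition the nucleus exactly: union = mask, intersection = empty.
    """
    m = np.asarray(nucleus_mask, dtype=bool)
    interior = morphology.erosion(m, morphology.disk(erosion_radius_px))
    if not interior.any():
        raise ValueError(
            f"erosion by {erosion_radius_px} px annihilates the mask"
        )
    return interior, m & ~interior


def nuclear_volume(
    slice_masks: np.ndarray, pixel_size: float, z_step: float = 0.3
) -> VolumeResult:
    """Nuclear volume from per-slice masks: sum of slice areas times z-step."""
    m = np.asarray(slice_masks, dtype=bool)
    if m.ndim != 3 or m.shape[0] < 2:
        raise ValueError("need a (n_slices, H, W) stack with >= 2 slices")
    volume = float(m.sum()) * pixel_size**2 * z_step
    return VolumeResult(volume, int(m.shape[0]), float(z_step))


def mid_plane(slice_masks: np.ndarray) -> int:
    """Mid-plane index = z-slice with the largest mask area."""
    m = np.asarray(slice_masks, dtype=bool)
    return int(m.reshape(m.shape[0], -1).sum(1).argmax())


def size_density_correlation(
    droplets: pd.DataFrame,
    pre_activation_image: np.ndarray,
    nucleus_mask: np.ndarray,
    pixel_size: float,
    disk_radius_factor: float = 2.0,
) -> dict:
    """Pearson correlation between condensate size and the chromatin density
    at the condensate's location before activation.

    Local density = mean pre-activation intensity in a disk of radius
    ``disk_radius_factor`` times the droplet radius around its centroid.
    Returns dict(r, p, n, degenerate).
    """
    need = {"x_um", "y_um", "equivalent_diameter_um"}
    if not need <= set(droplets.columns):
        raise ValueError(f"droplet table must contain {sorted(need)}")
    if len(droplets) < 5:
        raise ValueError("need at least 5 droplets for a correlation")
    img = np.asarray(pre_activation_image, dtype=float)
    m = np.asarray(nucleus_mask, dtype=bool)
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    sizes, densities = [], []
    for _, row in droplets.iterrows():
        cx = row["x_um"] / pixel_size - 0.5
        cy = row["y_um"] / pixel_size - 0.5
        ci, ri = int(round(cx)), int(round(cy))
        if not (0 <= ri < h and 0 <= ci < w and m[ri, ci]):
            raise ValueError("droplet centroid falls outside the nucleus mask")
        rad_px = disk_radius_factor * (row["equivalent_diameter_um"] / 2) / pixel_size
        disk = ((yy - cy) ** 2 + (xx - cx) ** 2) <= max(rad_px, 1.0) ** 2
        sizes.append(row["equivalent_diameter_um"])
        densities.append(img[disk & m].mean())
    sizes = np.asarray(sizes)
    densities = np.asarray(densities)
    if sizes.std() == 0 or densities.std() == 0:
        return {"r": np.nan, "p": np.nan, "n": len(sizes), "degenerate": True}
    r, p = stats.pearsonr(sizes, densities)
    return {"r": float(r), "p": float(p), "n": len(sizes), "degenerate": False}
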