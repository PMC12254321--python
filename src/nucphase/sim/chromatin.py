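"""Synthetic nuclei with controllable chromatin heterogeneity.

The intensity field inside an elliptical nucleus is a low-pass-filtered
Gaussian random field, exponentiated (so dense "chromatin clusters" appear as
bright blobs) and affinely rescaled so that the coefficient of variation
COV = std / (mean - background) inside the mask hits ``cov_target``. Because
the rescale is applied to the final noisy pixels, the ground-truth COV is met
essentially exactly; downstream estimators are validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from nucphase.config import SimConfig


@dataclass
class ChromatinGroundTruth:
    intensity_field: np.ndarray
    nucleus_mask: np.ndarray
    true_cov: float
    background_level: float

    def __post_init__(self) -> None:
        if self.true_cov < 0:
            raise ValueError("true_cov must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if not self.nucleus_mask.any():
            raise ValueError("nucleus mask is empty")


def _ellipse_mask(shape: tuple[int, int], semi_axes_px: tuple[float, float]) -> np.ndarray:
    r = (np.arange(shape[0]) - (shape[0] - 1) / 2.0) / semi_axes_px[0]
    c = (np.arange(shape[1]) - (shape[1] - 1) / 2.0) / semi_axes_px[1]
    return (r[:, None] ** 2 + c[None, :] ** 2) <= 1.0


def gen_chromatin_field(
    cov_target: float,
    geometry_um: tuple[float, float],
    config: SimConfig,
    mean_intensity: float = 2000.0,
    background_level: float = 100.0,
    correlation_length_um: float = 0.8,
) -> ChromatinGroundTruth:
    """Generate a nucleus image with in-mask COV equal to ``cov_target``.

    Parameters
    ----------
    cov_target : float
        Target coefficient of variation (std over background-subtracted
        mean) of the intra-nuclear intensity. 0 gives a uniform nucleus.
    geometry_um : (a, b)
        Ellipse semi-axes of the nucleus in um; must fit in the frame.
    mean_intensity : float
        Mean intra-nuclear intensity in arbitrary units (above background).
    correlation_length_um : float
        Spatial scale of the chromatin blobs.
    """
    if cov_target < 0:
        raise ValueError(f"cov_target must be >= 0, got {cov_target}")
    shape = config.image_shape
    semi_px = (
        geometry_um[0] / config.pixel_size,
        geometry_um[1] / config.pixel_size,
    )
    if 2 * semi_px[0] > shape[0] or 2 * semi_px[1] > shape[1]:
        raise ValueError(
            f"nucleus geometry {geometry_um} um does not fit in frame "
            f"{shape} px at {config.pixel_size} um/px"
        )
    mask = _ellipse_mask(shape, semi_px)

    rng = config.rng("chromatin")
    sigma_px = correlation_length_um / config.pixel_size
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px)

    img = np.full(shape, float(background_level))
    if cov_target == 0:
        img[mask] = background_level + mean_intensity
        true_cov = 0.0
    else:
        # lognormal texture keeps every pixel positive at any target COV;
        # the affine map then pins std/(mean - bg) to cov_target exactly
        g = field[mask]
        g = (g - g.mean()) / max(g.std(), 1e-12)
        sigma_ln = np.sqrt(np.log1p(cov_target**2))
        x = np.exp(sigma_ln * g)
        gain = cov_target * mean_intensity / x.std()
        offset = background_level + mean_intensity - gain * x.mean()
        vals = gain * x + offset
        if vals.min() < 0:  # degenerate texture; clip and report achieved COV
            vals = np.clip(vals, 0, None)
            true_cov = float(vals.std() / (vals.mean() - background_level))
        else:
            true_cov = float(cov_target)
        img[mask] = vals

    # shot noise outside the nucleus only (the mask interior is exact by
    # construction; estimator noise robustness is tested separately)
    outside = ~mask
    img[outside] = rng.poisson(background_level, size=int(outside.sum()))
    return ChromatinGroundTruth(img, mask, true_cov, float(background_level))


def two_level_field(
    shape: tuple[int, int] = (64, 64),
    fraction_high: float = 0.5,
    high: float = 2.0,
    low: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic two-level intensity field (background 0).

    With fraction f at intensity `high` and 1-f at `low`=0, the closed-form
    COV is sqrt(f*(1-f)) * |high - low| / mean; for f = 1/2, low = 0 it is
    exactly 1 regardless of `high`. Returns (image, full mask).
    """
    img = np.full(shape, float(low))
    n = img.size
    k = int(round(fraction_high * n))
    flat = img.ravel()
    flat[:k] = high
    return flat.reshape(shape), np.ones(shape, dtype=bool)
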