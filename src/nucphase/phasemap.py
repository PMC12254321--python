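"""Intracellular phase-diagram mapping.

Cells expressing a two-component optogenetic condensate system are scattered
in the (core concentration, core-to-IDR ratio) plane and labeled
phase-separated (PS) or not (nonPS) from post-activation images. A
soft-margin SVM fitted on standardized log10 axes provides an unbiased
decision boundary; its zero-level contour is the empirical binodal, and its
intersection with a fixed core-to-IDR ratio (1/16 by convention) gives the
saturation concentration c_sat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from nucphase.condensates import segment_droplets


@dataclass
class CalibrationModel:
    """Linear intensity (a.u.) -> concentration (uM) mapping per channel."""

    slope: float
    intercept: float
    channel: str = ""
    residual_std: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def to_conc(self, intensity) -> np.ndarray:
        return self.slope * np.asarray(intensity, dtype=float) + self.intercept


@dataclass
class PhaseBoundary:
    decision: Callable[[np.ndarray, np.ndarray], np.ndarray]  # (conc, ratio) -> margin
    boundary: pd.DataFrame  # columns ratio, conc_uM along the zero level set
    n_ps: int
    n_nonps: int
    kernel: str


@dataclass
class SaturationResult:
    c_sat_uM: float
    at_ratio: float


def fit_calibration(
    intensities: np.ndarray, concentrations_uM: np.ndarray, channel: str = ""
) -> CalibrationModel:
    """Least-squares line through (intensity, concentration) pairs.

    Needs >= 3 pairs spanning more than a 2x intensity range.
    """
    x = np.asarray(intensities, dtype=float)
    y = np.asarray(concentrations_uM, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 calibration pairs")
    if x.min() <= 0 or x.max() / x.min() < 2:
        raise ValueError("calibration intensities must span > 2x dynamic range")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return CalibrationModel(
        float(slope), float(intercept), channel, float(resid.std(ddof=2))
    )


def classify_ps(
    post_activation_image: np.ndarray,
    frame_interval: float,
    pixel_size: float,
    min_droplets: int = 1,
    blur_sigma_px: float = 1.0,
) -> tuple[str, int]:
    """PS/nonPS call for one cell from its post-activation frame.

    PS iff at least ``min_droplets`` condensates are segmented (per-cell
    Renyi threshold on the single frame). An unsegmentable (constant) image
    yields ('undetermined', 0). A flat nucleoplasmic signal whose contrast
    is indistinguishable from shot noise (no pixels above
    median + 6 * 1.4826 MAD) is called nonPS without segmentation, since an
    entropy threshold on pure noise would hallucinate foreground.
    """
    img = np.asarray(post_activation_image, dtype=float)
    if img.max() == img.min():
        return "undetermined", 0
    med = np.median(img)
    mad = np.median(np.abs(img - med))
    if img.max() <= med + 6 * 1.4826 * mad:
        return "nonPS", 0
    movie = img[None, ...]
    table = segment_droplets(
        movie, frame_interval, pixel_size, reference_time_s=0.0,
        blur_sigma_px=blur_sigma_px,
    )
    n = len(table)
    return ("PS" if n >= min_droplets else "nonPS"), n


def fit_boundary(
    cells: pd.DataFrame,
    kernel: str = "rbf",
    C: float = 1.0,
    grid_size: int = 200,
    min_class_size: int = 20,
) -> PhaseBoundary:
    """Fit the PS/nonPS decision boundary with a soft-margin SVM.

    Input columns: core_conc_uM, core_to_idr_ratio, ps_label. Both axes are
    log10-transformed and standardized; class imbalance is handled with
    inverse-frequency weights. The binodal polyline is the zero contour of
    the decision function sampled on a ``grid_size``^2 grid spanning the
    data: for each ratio column, the concentration where the margin changes
    sign (linearly interpolated).
    """
    labels = cells["ps_label"].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both PS and nonPS cells to fit a boundary")
    if counts.min() < min_class_size:
        raise ValueError(
            f"each class needs >= {min_class_size} cells, got {dict(zip(classes, counts))}"
        )
    X = np.column_stack(
        [
            np.log10(cells["core_conc_uM"].to_numpy(dtype=float)),
            np.log10(cells["core_to_idr_ratio"].to_numpy(dtype=float)),
        ]
    )
    y = (labels == "PS").astype(int)
    model = make_pipeline(
        StandardScaler(),
        SVC(kernel=kernel, C=C, class_weight="balanced"),
    )
    model.fit(X, y)

    def decision(conc_uM, ratio):
        pts = np.column_stack(
            [np.log10(np.atleast_1d(conc_uM)), np.log10(np.atleast_1d(ratio))]
        )
        return model.decision_function(pts)

    log_c = np.linspace(X[:, 0].min(), X[:, 0].max(), grid_size)
    log_r = np.linspace(X[:, 1].min(), X[:, 1].max(), grid_size)
    rows = []
    for lr in log_r:
        margins = model.decision_function(
            np.column_stack([log_c, np.full_like(log_c, lr)])
        )
        sign_change = np.flatnonzero(np.diff(np.sign(margins)) != 0)
        if len(sign_change) == 0:
            continue
        # lowest concentration crossing = the binodal at this ratio
        i = sign_change[0]
        f = margins[i] / (margins[i] - margins[i + 1])
        rows.append((10.0 ** lr, 10.0 ** (log_c[i] + f * (log_c[i + 1] - log_c[i]))))
    boundary = pd.DataFrame(rows, columns=["ratio", "conc_uM"])
    return PhaseBoundary(
        decision=decision,
        boundary=boundary,
        n_ps=int(y.sum()),
        n_nonps=int((1 - y).sum()),
        kernel=kernel,
    )


def saturation_conc(boundary: PhaseBoundary, at_ratio: float = 1 / 16) -> SaturationResult:
    """Saturation concentration: the binodal interpolated at a fixed ratio.

    Linear interpolation in (log10 ratio, log10 conc); no extrapolation
    outside the sampled ratio range.
    """
    b = boundary.boundary
    if len(b) < 2:
        raise ValueError("boundary polyline too short to interpolate")
    lr = np.log10(b["ratio"].to_numpy())
    lc = np.log10(b["conc_uM"].to_numpy())
    order = np.argsort(lr)
    lr, lc = lr[order], lc[order]
    x = np.log10(at_ratio)
    if x < lr[0] or x > lr[-1]:
        raise ValueError(
            f"ratio {at_ratio} outside sampled range "
            f"[{10**lr[0]:.4g}, {10**lr[-1]:.4g}]"
        )
    return SaturationResult(float(10.0 ** np.interp(x, lr, lc)), float(at_ratio))
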