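"""Condensate segmentation, size/number time series, and coarsening fits.

Activation movies are segmented with a threshold frozen at a reference time
(1 min after activation, when condensate sizes reach quasi-equilibrium) using
the Renyi-entropy method; per-frame droplet geometry feeds a log-log fit of
mean equivalent diameter vs time whose slope is the coarsening exponent. For
Brownian-motion-driven coalescence with area conservation and size-dependent
mobility, that exponent is one third of the droplets' diffusive exponent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from nucphase.thresholds import renyi_threshold
from nucphase.tracking import fit_anomalous, msd_ensemble
from nucphase.tracks import TrajectorySet


@dataclass
class CoarseningFit:
    exponent: float
    prefactor: float  # um * s^-exponent
    window: tuple[float, float]
    r_squared: float
    n_frames: int


def segment_droplets(
    movie: np.ndarray,
    frame_interval: float,
    pixel_size: float,
    reference_time_s: float = 60.0,
    blur_sigma_px: float = 1.0,
    min_size_px: int = 4,
) -> pd.DataFrame:
    """Segment condensates in every frame with a frozen Renyi threshold.

    The threshold is determined once on the blurred frame nearest
    ``reference_time_s`` and reused for all frames, so late-movie intensity
    growth cannot silently move the segmentation. Centroids are
    intensity-weighted centers of mass of the above-threshold pixels.

    Returns a droplet table: frame, t_s, droplet_id, x_um, y_um, area_um2,
    equivalent_diameter_um. droplet_id is per-frame (no linking here).
    """
    mv = np.asarray(movie, dtype=float)
    if mv.ndim != 3:
        raise ValueError("movie must be (T, H, W)")
    ref_idx = int(round(reference_time_s / frame_interval))
    if not (0 <= ref_idx < mv.shape[0]):
        raise ValueError(
            f"reference time {reference_time_s}s (frame {ref_idx}) outside movie"
        )
    blurred = np.stack([ndimage.gaussian_filter(f, blur_sigma_px) for f in mv])
    ref = blurred[ref_idx]
    if ref.max() == ref.min():
        warnings.warn("reference frame is constant; no droplets segmented")
        return _empty_droplet_table()
    thr = renyi_threshold(ref)

    rows = []
    px_area = pixel_size**2
    for f in range(mv.shape[0]):
        fg = blurred[f] > thr
        labels, n = ndimage.label(fg)
        if n == 0:
            continue
        areas_px = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        # intensity-weighted centroid (cntrd-style) on the blurred frame
        coms = ndimage.center_of_mass(blurred[f], labels, range(1, n + 1))
        did = 0
        for lab in range(n):
            if areas_px[lab] < min_size_px:
                continue
            area = areas_px[lab] * px_area
            cy, cx = coms[lab]
            rows.append(
                (
                    f,
                    f * frame_interval,
                    did,
                    (cx + 0.5) * pixel_size,
                    (cy + 0.5) * pixel_size,
                    area,
                    2.0 * np.sqrt(area / np.pi),
                )
            )
            did += 1
    if not rows:
        warnings.warn("no droplets found in any frame")
        return _empty_droplet_table()
    return pd.DataFrame(
        rows,
        columns=[
            "frame", "t_s", "droplet_id", "x_um", "y_um",
            "area_um2", "equivalent_diameter_um",
        ],
    )


def _empty_droplet_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "frame", "t_s", "droplet_id", "x_um", "y_um",
            "area_um2", "equivalent_diameter_um",
        ]
    )


def droplet_timeseries(table: pd.DataFrame) -> pd.DataFrame:
    """Per-frame droplet count and mean equivalent diameter.

    Returns columns t_s, count, mean_diameter_um.
    """
    if len(table) == 0:
        raise ValueError("empty droplet table")
    g = table.groupby("frame")
    out = pd.DataFrame(
        {
            "t_s": g["t_s"].first(),
            "count": g["droplet_id"].size(),
            "mean_diameter_um": g["equivalent_diameter_um"].mean(),
        }
    ).reset_index(drop=True)
    return out


def fit_coarsening(
    series: pd.DataFrame, window_s: tuple[float, float]
) -> CoarseningFit:
    """OLS of log(mean diameter) on log(t) within the coarsening window.

    Frames without droplets inside the window are excluded; fewer than 5
    usable frames is an error. The default analysis window starts at 60 s
    (the first minute of nucleation/growth is discarded).
    """
    t = series["t_s"].to_numpy(dtype=float)
    d = series["mean_diameter_um"].to_numpy(dtype=float)
    sel = (t >= window_s[0]) & (t <= window_s[1]) & (d > 0) & (t > 0)
    if sel.sum() < 5:
        raise ValueError(
            f"need >= 5 frames with droplets inside window, got {int(sel.sum())}"
        )
    x, y = np.log(t[sel]), np.log(d[sel])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return CoarseningFit(
        exponent=float(slope),
        prefactor=float(np.exp(intercept)),
        window=(float(window_s[0]), float(window_s[1])),
        r_squared=float(r2),
        n_frames=int(sel.sum()),
    )


def coalescence_scaling_check(
    droplet_table: pd.DataFrame,
    frame_interval: float,
    coarsening_window_s: tuple[float, float],
    msd_fit_window_s: tuple[float, float] | None = None,
    min_track_length: int = 20,
) -> dict:
    """Ratio of coarsening exponent to droplet diffusive exponent.

    Feeds a simulated (or segmented+linked) droplet table through both fits:
    mean-diameter growth exponent from :func:`fit_coarsening`, diffusive
    exponent from the ensemble MSD of per-droplet trajectories. For
    Brownian-motion-driven coalescence the ratio is ~1/3.

    The MSD is fitted over the first 10 lags by default: in a coalescing
    population long-lived droplets are systematically larger and slower, so
    long lags mix track compositions and bias the exponent downward.
    """
    from nucphase.sim.coalescence import droplet_trajectories

    series = droplet_timeseries(droplet_table)
    coarse = fit_coarsening(series, coarsening_window_s)
    tracks = droplet_trajectories(
        droplet_table, frame_interval, min_length=min_track_length
    )
    if tracks.n_tracks < 2:
        raise ValueError("too few persistent droplet tracks for an MSD fit")
    curve = msd_ensemble(tracks, min_track_len=min_track_length)
    if msd_fit_window_s is None:
        msd_fit_window_s = (curve.lags[0], 10 * frame_interval)
    msd_fit = fit_anomalous(curve, msd_fit_window_s)
    return {
        "coarsening_exponent": coarse.exponent,
        "diffusive_exponent": msd_fit.alpha,
        "ratio": coarse.exponent / msd_fit.alpha,
        "coarsening_r2": coarse.r_squared,
        "msd_r2": msd_fit.r_squared,
    }
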