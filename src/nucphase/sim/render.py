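"""Render trajectories into a synthetic fluorescence movie.

Each particle becomes a 2D Gaussian spot (diffraction-limited PSF proxy) on a
Poisson photon background. 40 nm tracer particles are far below the
diffraction limit, so the spot width is set by the PSF, not particle size.
Ground-truth positions travel with the movie for end-to-end detector tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nucphase.config import SimConfig
from nucphase.tracks import TrajectorySet


@dataclass
class ImageStack:
    """Time-lapse (or z) stack with physical calibration and ground truth."""

    frames: np.ndarray  # (T, H, W) float
    pixel_size: float
    frame_interval: float
    truth: TrajectorySet | None = None


def render_movie(
    tracks: TrajectorySet,
    psf_sigma_um: float,
    snr: float,
    config: SimConfig,
    background_photons: float = 100.0,
) -> ImageStack:
    """Render every (frame, position) of ``tracks`` as a Gaussian spot.

    ``snr`` is the spot peak amplitude over the background shot-noise std
    (sqrt of background photons). Positions must lie inside the field of view.
    """
    if snr <= 0:
        raise ValueError(f"snr must be > 0, got {snr}")
    h, w = config.image_shape
    px = config.pixel_size
    xmax, ymax = w * px, h * px
    d = tracks.data
    if len(d) and (
        (d["x_um"].min() < 0)
        or (d["y_um"].min() < 0)
        or (d["x_um"].max() >= xmax)
        or (d["y_um"].max() >= ymax)
    ):
        raise ValueError("track positions fall outside the field of view")

    n_frames = int(d["frame"].max()) + 1 if len(d) else 1
    amp = snr * np.sqrt(background_photons)
    sig_px = psf_sigma_um / px
    half = max(int(np.ceil(4 * sig_px)), 2)

    clean = np.zeros((n_frames, h, w))
    for frame, sub in d.groupby("frame"):
        # pixel centers: position_um = (index + 0.5) * pixel_size
        cx = sub["x_um"].to_numpy() / px - 0.5
        cy = sub["y_um"].to_numpy() / px - 0.5
        for x0, y0 in zip(cx, cy):
            r0, r1 = int(np.floor(y0)) - half, int(np.floor(y0)) + half + 1
            c0, c1 = int(np.floor(x0)) - half, int(np.floor(x0)) + half + 1
            r0c, r1c = max(r0, 0), min(r1, h)
            c0c, c1c = max(c0, 0), min(c1, w)
            yy = np.arange(r0c, r1c)[:, None]
            xx = np.arange(c0c, c1c)[None, :]
            clean[int(frame), r0c:r1c, c0c:c1c] += amp * np.exp(
                -((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * sig_px**2)
            )

    rng = config.rng("render")
    frames = rng.poisson(clean + background_photons).astype(float)
    return ImageStack(frames, px, tracks.frame_interval, truth=tracks)


def render_droplet_movie(
    droplet_table,
    config: SimConfig,
    droplet_intensity: float = 1000.0,
    background_photons: float = 100.0,
    poisson_noise: bool = True,
) -> ImageStack:
    """Render a droplet table (from the coalescence simulator) as a movie of
    uniform bright disks on Poisson background, wrapping positions into the
    field of view. Used to exercise segmentation end to end.
    """
    h, w = config.image_shape
    px = config.pixel_size
    n_frames = int(droplet_table["frame"].max()) + 1
    clean = np.zeros((n_frames, h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    for _, row in droplet_table.iterrows():
        cx = (row["x_um"] % (w * px)) / px - 0.5
        cy = (row["y_um"] % (h * px)) / px - 0.5
        r_px = row["radius_um"] / px if "radius_um" in row else (
            row["equivalent_diameter_um"] / 2 / px
        )
        disk = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r_px**2
        clean[int(row["frame"])][disk] = droplet_intensity
    clean += background_photons
    if poisson_noise:
        frames = config.rng("render").poisson(clean).astype(float)
    else:
        frames = clean
    return ImageStack(frames, px, config.frame_interval)
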