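"""Anomalous-diffusion trajectory generator.

Tracks are fractional Brownian motion with Hurst index H = alpha/2, so the
ensemble mean square displacement follows MSD(tau) = D * tau**alpha exactly
(in expectation). Increments are generated from the exact fractional Gaussian
noise covariance via a Cholesky factor, so the generator carries no synthesis
bias that could confound fit validation.

Localization noise is additive i.i.d. Gaussian on positions (static error
only). ``loc_noise_sigma`` is the total 2D error magnitude: each coordinate
receives std sigma/sqrt(2), which shifts the observed MSD by +2*sigma**2 at
every lag. A uniform drift v adds |v|**2 * tau**2.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from nucphase.config import SimConfig
from nucphase.tracks import TrajectorySet


@dataclass(frozen=True)
class PopulationSpec:
    """One diffusing sub-population.

    amplitude_D is the MSD prefactor in um^2/s^alpha (2D MSD convention);
    exponent_alpha in (0, 2): <1 subdiffusive, 1 Brownian, >1 superdiffusive.
    """

    n_tracks: int
    n_steps: int
    amplitude_D: float
    exponent_alpha: float
    loc_noise_sigma: float = 0.0
    drift_velocity: tuple[float, float] = (0.0, 0.0)
    fraction: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.exponent_alpha < 2):
            raise ValueError(
                f"exponent_alpha must lie in (0, 2), got {self.exponent_alpha}"
            )
        if self.n_tracks < 1 or self.n_steps < 2:
            raise ValueError("need n_tracks >= 1 and n_steps >= 2")
        if self.amplitude_D < 0 or self.loc_noise_sigma < 0:
            raise ValueError("amplitude_D and loc_noise_sigma must be >= 0")


@lru_cache(maxsize=32)
def _fgn_cholesky(n_increments: int, alpha: float) -> np.ndarray:
    """Lower Cholesky factor of the unit fGn covariance (unit lag spacing)."""
    k = np.arange(n_increments, dtype=float)
    gamma = 0.5 * (
        np.abs(k + 1) ** alpha - 2 * np.abs(k) ** alpha + np.abs(k - 1) ** alpha
    )
    cov = gamma[np.abs(k[:, None] - k[None, :]).astype(int)]
    # tiny jitter keeps the factorization stable for alpha near 2
    return np.linalg.cholesky(cov + 1e-12 * np.eye(n_increments))


def fbm_paths(
    n_tracks: int,
    n_steps: int,
    amplitude_D: float,
    alpha: float,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample fBm positions of shape (n_tracks, n_steps, 2), starting at 0.

    Per-axis displacement variance over lag tau is (D/2) * tau**alpha so the
    2D MSD is D * tau**alpha.
    """
    n_inc = n_steps - 1
    if amplitude_D == 0:
        return np.zeros((n_tracks, n_steps, 2))
    L = _fgn_cholesky(n_inc, float(alpha))
    z = rng.standard_normal((n_tracks, 2, n_inc))
    scale = np.sqrt(amplitude_D / 2.0) * dt ** (alpha / 2.0)
    inc = scale * np.einsum("ij,naj->nai", L, z)  # (tracks, axes, increments)
    pos = np.zeros((n_tracks, n_steps, 2))
    pos[:, 1:, :] = np.cumsum(inc, axis=2).transpose(0, 2, 1)
    return pos


def gen_trajectories(
    populations: list[PopulationSpec],
    config: SimConfig,
    start_box_um: tuple[float, float] | None = None,
) -> TrajectorySet:
    """Generate a mixed-population TrajectorySet with ground-truth labels.

    Population fractions must sum to 1 (they are ground-truth metadata; the
    per-population track counts are explicit). Track starting points are
    scattered uniformly over ``start_box_um`` (defaults to the central 80% of
    the configured field of view).
    """
    if not populations:
        raise ValueError("need at least one population")
    total_frac = sum(p.fraction for p in populations)
    if not np.isclose(total_frac, 1.0, atol=1e-6):
        raise ValueError(f"population fractions must sum to 1, got {total_frac}")

    rng = config.rng("trajectories")
    h_um = config.image_shape[0] * config.pixel_size
    w_um = config.image_shape[1] * config.pixel_size
    if start_box_um is None:
        x0, x1 = 0.1 * w_um, 0.9 * w_um
        y0, y1 = 0.1 * h_um, 0.9 * h_um
    else:
        x0, y0 = 0.0, 0.0
        x1, y1 = start_box_um

    dt = config.frame_interval
    frames_chunks = []
    tid = 0
    for ipop, pop in enumerate(populations):
        pos = fbm_paths(
            pop.n_tracks, pop.n_steps, pop.amplitude_D, pop.exponent_alpha, dt, rng
        )
        t = np.arange(pop.n_steps) * dt
        pos = pos + np.stack(
            [pop.drift_velocity[0] * t, pop.drift_velocity[1] * t], axis=-1
        )
        if pop.loc_noise_sigma > 0:
            pos = pos + rng.normal(
                0.0, pop.loc_noise_sigma / np.sqrt(2.0), size=pos.shape
            )
        starts = np.column_stack(
            [rng.uniform(x0, x1, pop.n_tracks), rng.uniform(y0, y1, pop.n_tracks)]
        )
        pos = pos + starts[:, None, :]
        label = pop.label or f"pop{ipop}"
        for i in range(pop.n_tracks):
            frames_chunks.append(
                pd.DataFrame(
                    {
                        "track_id": tid,
                        "frame": np.arange(pop.n_steps),
                        "t_s": t,
                        "x_um": pos[i, :, 0],
                        "y_um": pos[i, :, 1],
                        "population_label": label,
                    }
                )
            )
            tid += 1
    return TrajectorySet(pd.concat(frames_chunks, ignore_index=True), dt)
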