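"""Acquisition/simulation configuration shared by every synthetic generator.

Physical calibration defaults follow a spinning-disk confocal setup typical
for live-cell nuclear imaging: ~0.133 um/px (100x objective, so a 3 px
erosion kernel is ~0.4 um), condensate movies at 1.2 frames per second, and
z-stacks at 0.3 um steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Fixed per-stage offsets so each generator draws from its own child stream:
# regenerating one stage never perturbs another.
_STREAM_OFFSETS = {
    "chromatin": 11,
    "trajectories": 23,
    "render": 37,
    "coalescence": 41,
    "phase": 53,
    "frap": 67,
}


@dataclass(frozen=True)
class SimConfig:
    """Physical calibration and master seed for synthetic data generation.

    Parameters
    ----------
    seed : int
        Master seed; each generator derives a child stream from it.
    pixel_size : float
        Lateral calibration, um per pixel.
    frame_interval : float
        Time between frames, seconds.
    z_step : float
        Axial spacing of optical sections, um.
    image_shape : tuple of int
        (rows, cols) of generated frames, pixels.
    """

    seed: int = 0
    pixel_size: float = 0.133
    frame_interval: float = 1 / 1.2
    z_step: float = 0.3
    image_shape: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.frame_interval <= 0:
            raise ValueError(
                f"frame_interval must be > 0, got {self.frame_interval}"
            )
        if self.z_step <= 0:
            raise ValueError(f"z_step must be > 0, got {self.z_step}")
        if len(self.image_shape) != 2 or min(self.image_shape) < 1:
            raise ValueError(f"image_shape must be 2D, got {self.image_shape}")

    def rng(self, stage: str) -> np.random.Generator:
        """Child random stream for a named generator stage."""
        if stage not in _STREAM_OFFSETS:
            raise KeyError(f"unknown stage {stage!r}")
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAM_OFFSETS[stage]])
        )
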