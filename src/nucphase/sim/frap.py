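"""Synthetic FRAP recovery curves.

Ground-truth model: y(t) = b * (1 - exp(-k * (t - t0))) for t >= t0, else 0,
with b the mobile fraction (0..1), k the recovery rate (1/s) and t0 the
bleach time; i.i.d. Gaussian noise of std ``noise_sigma`` is added on top.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nucphase.config import SimConfig


@dataclass(frozen=True)
class FrapGroundTruth:
    b: float
    k: float
    t0: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.b <= 1):
            raise ValueError(f"mobile fraction b must lie in [0, 1], got {self.b}")
        if self.k <= 0:
            raise ValueError(f"rate k must be > 0, got {self.k}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = self.b * (1.0 - np.exp(-self.k * (t - self.t0)))
        return np.where(t >= self.t0, y, 0.0)


def gen_frap(truth: FrapGroundTruth, times_s: np.ndarray, config: SimConfig) -> pd.DataFrame:
    """Noisy recovery curve sampled at ``times_s`` (sorted, containing t0).

    Returns columns t_s, y (normalized intensity).
    """
    t = np.asarray(times_s, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.any(np.isclose(t, truth.t0)) and not (t.min() < truth.t0 < t.max()):
        raise ValueError("times must bracket or include the bleach time t0")
    y = truth.evaluate(t)
    if truth.noise_sigma > 0:
        y = y + config.rng("frap").normal(0.0, truth.noise_sigma, t.shape)
    return pd.DataFrame({"t_s": t, "y": y})
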