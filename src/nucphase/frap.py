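"""FRAP normalization and single-exponential recovery fitting.

Recovery model: y(t) = b * (1 - exp(-k * (t - t0))), with b the mobile
fraction and t0 fixed at the bleach time. Raw traces are background
subtracted, optionally corrected for acquisition bleaching with a reference
ROI, then min-max normalized so the post-bleach minimum maps to 0 and the
pre-bleach plateau to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class FRAPCurve:
    t_s: np.ndarray
    y: np.ndarray
    bleach_frame: int

    @property
    def t0(self) -> float:
        return float(self.t_s[self.bleach_frame])


@dataclass
class FRAPFit:
    b: float  # mobile fraction
    k: float  # 1/s
    t0: float  # s, fixed at bleach time
    rss: float

    def __post_init__(self) -> None:
        if not (0 <= self.b <= 1.05):  # soft cap: noise can push b past 1
            raise ValueError(f"mobile fraction {self.b} outside [0, 1.05]")
        if self.k <= 0:
            raise ValueError("rate k must be positive")

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = self.b * (1.0 - np.exp(-self.k * (t - self.t0)))
        return np.where(t >= self.t0, y, 0.0)


def normalize_frap(
    raw: pd.DataFrame, bleach_frame: int
) -> FRAPCurve:
    """Normalize a raw FRAP trace to the unit interval.

    ``raw`` columns: t_s, I_roi, optional I_ref (unbleached reference ROI in
    the same cell, used as a multiplicative drift correction), optional I_bg
    (background, subtracted first). Normalization maps the minimum of the
    trace to 0 and the maximum (pre-bleach plateau) to 1.
    """
    if not (0 < bleach_frame < len(raw)):
        raise ValueError("bleach_frame must lie inside the series")
    t = raw["t_s"].to_numpy(dtype=float)
    y = raw["I_roi"].to_numpy(dtype=float).copy()
    if "I_bg" in raw.columns:
        y = y - raw["I_bg"].to_numpy(dtype=float)
    if "I_ref" in raw.columns:
        ref = raw["I_ref"].to_numpy(dtype=float)
        if "I_bg" in raw.columns:
            ref = ref - raw["I_bg"].to_numpy(dtype=float)
        pre = ref[:bleach_frame].mean()
        if pre <= 0 or np.any(ref <= 0):
            raise ValueError("reference trace must stay positive")
        y = y / (ref / pre)
    lo, hi = y.min(), y.max()
    if hi <= lo:
        raise ValueError("flat trace: nothing to normalize (max == min)")
    return FRAPCurve((t - 0), (y - lo) / (hi - lo), bleach_frame)


def fit_frap(
    curve: FRAPCurve,
    min_post_bleach: int = 8,
    k_starts: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0),
    fit_t0: bool = False,
) -> FRAPFit:
    """Nonlinear least squares fit of the recovery model to a FRAPCurve.

    t0 is fixed at the bleach time (set ``fit_t0`` to free it). Multistart
    over ``k_starts`` avoids local minima; the best converged fit wins.
    """
    post = curve.t_s >= curve.t0
    t = curve.t_s[post]
    y = curve.y[post]
    if len(t) < min_post_bleach:
        raise ValueError(
            f"need >= {min_post_bleach} post-bleach points, got {len(t)}"
        )
    t0 = curve.t0
    best = None
    for k0 in k_starts:
        try:
            if fit_t0:
                def model(tt, b, k, tt0):
                    return b * (1 - np.exp(-k * np.maximum(tt - tt0, 0.0)))

                p, _ = curve_fit(
                    model, t, y, p0=[max(y.max(), 0.1), k0, t0],
                    bounds=([0, 1e-8, t.min() - 1 / k0], [1.05, np.inf, t.max()]),
                    maxfev=10000,
                )
                b_hat, k_hat, t0_hat = p
            else:
                def model(tt, b, k):
                    return b * (1 - np.exp(-k * (tt - t0)))

                p, _ = curve_fit(
                    model, t, y, p0=[max(y.max(), 0.1), k0],
                    bounds=([0, 1e-8], [1.05, np.inf]),
                    maxfev=10000,
                )
                b_hat, k_hat, t0_hat = p[0], p[1], t0
        except RuntimeError:
            continue
        rss = float(((model(t, *p)) - y).dot((model(t, *p)) - y))
        if best is None or rss < best.rss:
            best = FRAPFit(float(b_hat), float(k_hat), float(t0_hat), rss)
    if best is None:
        raise RuntimeError("FRAP fit failed to converge from every start")
    return best
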