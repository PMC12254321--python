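"""Synthetic cell ensembles in the (core concentration, core-to-IDR ratio)
plane with a known binodal.

Each simulated cell is a point sampled log-uniformly over both axes and
labeled phase-separated (PS) iff its core concentration exceeds the
ground-truth saturation concentration c_sat(ratio), with optional label
noise emulating classification errors in real post-activation images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from nucphase.config import SimConfig


def power_law_binodal(c_at_ref: float, slope: float, ref_ratio: float = 1 / 16) -> Callable[[np.ndarray], np.ndarray]:
    """Ground-truth binodal c_sat(ratio) = c_at_ref * (ratio/ref_ratio)**slope.

    ``c_at_ref`` anchors the saturation concentration at the reference
    core-to-IDR ratio (1/16 by convention); positive ``slope`` makes phase
    separation harder when IDR is scarce (high core-to-IDR ratio).
    """
    if c_at_ref <= 0:
        raise ValueError("c_at_ref must be positive")

    def c_sat(ratio):
        return c_at_ref * (np.asarray(ratio, dtype=float) / ref_ratio) ** slope

    return c_sat


@dataclass
class PhaseEnsembleSpec:
    n_cells: int
    conc_range_uM: tuple[float, float]
    ratio_range: tuple[float, float]
    binodal: Callable[[np.ndarray], np.ndarray]
    label_flip_prob: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.label_flip_prob < 0.5):
            raise ValueError("label_flip_prob must lie in [0, 0.5)")
        if min(self.conc_range_uM) <= 0 or min(self.ratio_range) <= 0:
            raise ValueError("ranges must be positive")
        if self.conc_range_uM[0] >= self.conc_range_uM[1] or self.ratio_range[0] >= self.ratio_range[1]:
            raise ValueError("ranges must be nonempty (lo < hi)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def gen_phase_ensemble(spec: PhaseEnsembleSpec, config: SimConfig) -> pd.DataFrame:
    """Sample the cell ensemble; returns per-cell phenotypes.

    Columns: cell_id, core_conc_uM, core_to_idr_ratio, ps_label ('PS' or
    'nonPS'), true_label, c_sat_true_uM. The ground-truth binodal must be
    positive over the ratio range.
    """
    rng = config.rng("phase")
    c_lo, c_hi = spec.conc_range_uM
    r_lo, r_hi = spec.ratio_range
    csat_check = spec.binodal(np.geomspace(r_lo, r_hi, 64))
    if not np.all(np.asarray(csat_check) > 0):
        raise ValueError("binodal must be positive over ratio_range")

    conc = np.exp(rng.uniform(np.log(c_lo), np.log(c_hi), spec.n_cells))
    ratio = np.exp(rng.uniform(np.log(r_lo), np.log(r_hi), spec.n_cells))
    c_sat = np.asarray(spec.binodal(ratio))
    true_ps = conc > c_sat
    flip = rng.random(spec.n_cells) < spec.label_flip_prob
    ps = np.where(flip, ~true_ps, true_ps)
    return pd.DataFrame(
        {
            "cell_id": np.arange(spec.n_cells),
            "core_conc_uM": conc,
            "core_to_idr_ratio": ratio,
            "ps_label": np.where(ps, "PS", "nonPS"),
            "true_label": np.where(true_ps, "PS", "nonPS"),
            "c_sat_true_uM": c_sat,
        }
    )
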