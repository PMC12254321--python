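#!/usr/bin/env python
"""FRAP mobile-fraction recovery across binding regimes.

Simulates 60 s recovery curves (0.5 s sampling, noise sigma 0.02) for three
chromatin-binding regimes — strongly incorporated histone-like (b = 0.03
mobile), partially bound (b = 0.5), and freely exchanging (b = 0.97) — plus
a 100-curve random batch, fits the single-exponential recovery model with t0
fixed at the bleach time, and reports mobile-fraction accuracy.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nucphase.config import SimConfig
from nucphase.frap import FRAPCurve, fit_frap
from nucphase.sim import FrapGroundTruth, gen_frap
from nucphase.studies import frap_recovery_study

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

REGIMES = {
    "histone_incorporated": (0.03, 0.05),
    "partially_bound": (0.50, 0.10),
    "freely_exchanging": (0.97, 0.30),
}
t = np.arange(0.0, 60.0, 0.5)

rows = []
for name, (b, k) in REGIMES.items():
    truth = FrapGroundTruth(b, k, 0.0, noise_sigma=0.02)
    df = gen_frap(truth, t, SimConfig(seed=7))
    fit = fit_frap(FRAPCurve(df["t_s"].to_numpy(), df["y"].to_numpy(), 0))
    rows.append(
        {"regime": name, "b_true": b, "b_fit": fit.b, "k_true": k,
         "k_fit": fit.k, "rss": fit.rss}
    )
    print(
        f"{name}: mobile fraction {fit.b:.3f} (truth {b:.2f}), "
        f"rate {fit.k:.3f}/s (truth {k:.2f})"
    )

pd.DataFrame(rows).to_csv(OUT / "frap_fits.csv", index=False)

batch = frap_recovery_study(seed=9, n_curves=100)
print(
    f"\n100-curve batch: mean |b_hat - b| = {batch['mean_abs_b_error']:.4f}, "
    f"mean relative rate error = {batch['mean_rel_k_error']:.3f}"
)
print(f"wrote {OUT / 'frap_fits.csv'}")
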