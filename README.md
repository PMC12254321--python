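# nucphase

Quantitative analysis of **chromatin heterogeneity and nuclear condensate
phase behavior** from live-cell fluorescence microscopy, with seeded
synthetic-data generators that provide ground truth for every analysis stage.

The nucleus is a crowded, spatially heterogeneous environment: dense
heterochromatin clusters coexist with open euchromatic regions, and this
mesoscale structure constrains how nanoparticles diffuse, how biomolecular
condensates nucleate, grow, and coalesce, and where the intracellular phase
boundary of optogenetic condensate systems sits. This package implements the
measurement chain a cell-biophysics lab needs to quantify those effects:

- **Chromatin heterogeneity** — nucleus segmentation (Gaussian blur +
  256-bin Otsu), cell-free background estimation, and the coefficient of
  variation `COV = std(I) / (mean(I) − background)` on raw intra-nuclear
  intensities; interior/periphery masks and nuclear volume from z-stacks.
- **Single-particle tracking microrheology** — spot detection with
  sub-pixel centroids, Hungarian-assignment linking with gap memory,
  time-averaged/ensemble/pairwise MSD estimators, and anomalous-diffusion
  fits `MSD(τ) = D·τ^α` by log-log least squares. The pairwise MSD (MSD of
  relative separations, halved) cancels uniform drift exactly. Amplitude
  distributions at a fixed lag are classified unimodal/bimodal by
  BIC-compared Gaussian mixtures on log10 values.
- **Condensate coarsening** — Rényi-entropy segmentation with the threshold
  frozen at a reference time, per-frame droplet number/size series, and the
  coarsening exponent from `log(mean diameter)` vs `log(t)`. For
  Brownian-motion-driven coalescence with conserved area and size-dependent
  mobility, the coarsening exponent is one third of the droplet diffusive
  exponent — the package verifies this against its own coalescence
  simulator.
- **Phase-diagram mapping** — per-cell (core concentration, core-to-IDR
  ratio) phenotypes, PS/nonPS classification from post-activation images, a
  soft-margin SVM boundary on standardized log10 axes, and the saturation
  concentration `c_sat` read off the boundary at a fixed ratio (1/16 by
  convention).
- **FRAP** — normalization of raw recovery traces (background subtraction,
  optional reference-ROI drift correction, min-max scaling) and the
  single-exponential fit `y = b·(1 − e^{−k(t−t₀)})` with mobile fraction
  `b` and `t₀` fixed at the bleach time.

Every stage has a matching generator in `nucphase.sim` (chromatin fields of
controllable COV, exact-covariance fractional-Brownian-motion trajectories,
droplet nucleation/coalescence in a periodic box, cell ensembles with a
known binodal, FRAP curves), so the whole pipeline is testable without any
microscopy data.

## Worked example

```python
from nucphase.config import SimConfig
from nucphase.sim import PopulationSpec, gen_trajectories
from nucphase.tracking import fit_tracks_anomalous, msd_ensemble, fit_anomalous

cfg = SimConfig(seed=1, frame_interval=0.1)          # 10 fps tracer imaging
tracks = gen_trajectories([PopulationSpec(200, 300, 0.1, 1.0)], cfg)
fits = fit_tracks_anomalous(tracks)
print(fits["alpha"].mean(), fits["D"].mean())
# 0.9789284345381608 0.10064827337251496
curve = msd_ensemble(tracks)
print(fit_anomalous(curve).alpha)
# 1.0080992233833892
```

200 simulated free-diffusion tracks (`D = 0.1 µm²/s`, `α = 1`) give a mean
per-track fitted exponent of 0.979 and amplitude 0.101 µm²/s — the small
downward exponent bias is the usual cost of time-averaged MSDs at finite
track length, and the ensemble-level fit recovers 1.008.

The numbered drivers under `analysis/` run the full studies and write their
tables to `results/`; for example

```bash
python analysis/03_condensate_coarsening.py
# coarsening/diffusive exponent ratio over 10 seeds: 0.346 +- 0.032 (expected 1/3)
# segmented-image coarsening exponent 0.351 vs simulator-truth exponent 0.360
python analysis/04_phase_diagram.py
# control: 482 PS / 318 nonPS cells; c_sat(1/16) = 0.107 uM (truth 0.10)
# treated: 328 PS / 472 nonPS cells; c_sat(1/16) = 0.505 uM (truth 0.45)
```

`01` measures the COV decline across a homogenization series, `02` the
bimodal-to-unimodal shift in tracer mobility, `05` FRAP mobile-fraction
recovery across binding regimes.

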