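# Methods

This note records the models, estimators, numerical choices, and known
limitations behind `nucphase`, and what the synthetic generators do and do
not emulate.

## Synthetic data generation

All generators hang off a frozen `SimConfig` (master seed, pixel size,
frame interval, z-step, frame shape). Each generator stage draws from its
own child stream derived from the master seed by a fixed offset, so
regenerating one kind of data never perturbs another and identical
seed + parameters give bit-identical output. Default calibration is
0.133 µm/px (100× objective — a 3 px erosion kernel is ~0.4 µm), 1/1.2 s
frame interval for condensate movies, 0.1 s for tracer imaging, and 0.3 µm
z-steps.

### Chromatin intensity fields

A nucleus is an ellipse whose interior intensity is a low-pass-filtered
Gaussian random field (correlation length 0.8 µm by default — blob-like
"chromatin clusters"), exponentiated so the texture is strictly positive and
right-skewed like dense chromatin, then affinely rescaled so the realized
in-mask `std/(mean − background)` equals the requested COV target exactly.
Because the rescale acts on the final pixels, ground truth is exact by
construction except at extreme COV where clipping at zero intensity can
shave a fraction of a percent (the realized value is then stored as the
ground truth). Outside the mask, pixels are Poisson draws around the
background level. The field makes no biophysical claim about chromatin —
it exists to give the COV estimator a known answer and the segmenter a
realistic-looking target.

### Trajectories

Tracks are fractional Brownian motion with Hurst index `H = α/2`, generated
from the exact fractional-Gaussian-noise covariance via its Cholesky factor
(valid for the track lengths used here, ≤4096 steps; the factor is cached
per (length, α)). Per-axis displacement variance over lag τ is
`(D/2)·τ^α`, so the 2D MSD is `D·τ^α` in expectation with no synthesis
bias — fit validation is then a test of the estimator, not the generator.

Localization noise is additive i.i.d. Gaussian on positions, static error
only. The `loc_noise_sigma` parameter is the **total 2D error magnitude**
(each coordinate gets σ/√2), so the observed ensemble MSD is
`D·τ^α + 2σ²` at every lag; a uniform drift `v` adds `|v|²τ²`. The
dynamic-error/motion-blur term of real cameras is deliberately not modeled.

### Droplet coalescence

Droplets live in a periodic 2D box. Each step displaces droplet *i* by a
Gaussian increment with variance `D₀·(dᵢ/d_ref)^(−p)·Δt^α` (per two
dimensions), i.e. mobility decreases with diameter with power `p`; for
`α ≠ 1` increments are correlated fGn per droplet id. After each step,
transitively touching groups (center distance ≤ sum of radii, periodic
minimum image) merge into a droplet placed at the conserved-quantity-weighted
centroid with radius `(Σrⁿ)^(1/n)`, `n = 2` (area) or `3` (volume) — the
conserved sum is preserved to floating-point precision, which the tests
assert at 1e−9 relative. Merging is order-independent within a step.
Recorded positions are unwrapped so MSD analysis sees continuous paths; the
renderer wraps them back into the box.

Mean-field kinetics for `p = 1`, area conservation, and Brownian steps give
`n ∝ t^(−2/3)` and mean diameter `∝ t^(1/3)`: the coarsening exponent is one
third of the droplet diffusive exponent. The canonical study (500 droplets
of radius 0.5 µm at ~5% area fraction in a 70 µm box, `D₀ = 0.2 µm²/s` at
1 µm diameter, 1200 1-s steps, coarsening fitted from t = 100 s) reproduces
this ratio to within a few percent; the driver and reproduction script
average it over 10 seeds.

### Phase ensembles, FRAP curves

Cells are sampled log-uniformly over both axes; the ground-truth binodal is
a power law `c_sat(ratio) = c_ref·(ratio/r_ref)^s` anchored at the 1/16
reference ratio (defaults `c_ref = 0.10 µM`, `s = 0.6`, chosen so phase
separation gets harder when IDR is scarce, and matching the scale of
published intracellular optogenetic phase diagrams). A cell is PS iff its
concentration exceeds the binodal, then labels flip with probability
`label_flip_prob` (default 0.05) to emulate classification noise. Study
size is 800 cells per condition, the scale of real high-throughput phase
mapping. FRAP curves are the recovery model evaluated on the sampling grid
plus Gaussian noise (default σ = 0.02 on the normalized scale).

## Estimators and fits

**MSD.** Single-track MSD is time-averaged over all ordered pairs at each
integer lag, reported up to 25% of track length (bias/variance compromise;
configurable). The ensemble estimator pools per-track values weighted by
their pair counts; its SE is the across-track spread. The pairwise estimator
computes the MSD of relative separations of co-imaged pairs and divides by
2, so independent identical diffusers give the single-particle MSD and any
common-mode motion cancels identically. Its SE accounts for pairs sharing
tracks: with m contributing tracks the effective number of independent units
is m, not m(m−1)/2, giving `SE = std(pairs)·√(2/m)`.

**Anomalous-diffusion fit.** Ordinary least squares of `log MSD` on
`log τ`; α is the slope, `D = exp(intercept)`. Nonpositive MSD values are
excluded; fewer than 4 usable lags is an error. The default window is the
full reported curve (frame interval to 25% of duration). The localization
noise floor is *not* subtracted before fitting — fits are on raw MSD; a
known floor can be removed via the `noise_offset` argument. Minimum track
length is 10 frames.

**Coalescing-population MSD.** In a coalescing population long-lived
droplets are systematically larger and slower, so the ensemble MSD's track
composition changes with lag and biases the exponent downward at long lags.
The scaling check therefore fits the droplet MSD over the first 10 lags by
default.

**Bimodality.** Per-track MSD amplitudes at the requested lag (snapped to
the nearest frame multiple, within half a frame) are log10-transformed and
fitted with 1- and 2-component Gaussian mixtures (fixed random state,
5 inits); the 2-component model must win by ΔBIC > 6 to call "bimodal".
Fewer than 20 qualifying tracks returns "undetermined".

**Thresholds.** Otsu and Rényi-entropy thresholds operate on 256-bin
histograms built after min–max scaling (the ImageJ convention; ties go to
the lowest bin). The Rényi method follows the Sahoo three-order rule:
maximum-entropy thresholds at orders 1/2, 1 (Shannon limit), and 2,
combined with the ±5-bin proximity weighting. Both are verified against
exhaustive brute-force searches in the tests. A property worth knowing:
on images whose background histogram is a narrow peak with a small
foreground fraction, entropy thresholds sit just above the background —
segmented droplet areas are then inflated by roughly the blur width, which
is why precise-area validation uses noiseless unblurred fixtures and noisy
fixtures validate counts and centroids instead.

**Segmentation.** Nuclei: 1 px Gaussian blur → Otsu → connected components
≥ 10 µm². Blur is used only to build the mask; the COV statistic uses raw
intensities, since blurring would deflate it systematically. Condensates:
1 px blur → Rényi threshold frozen at the reference frame (60 s by
default) → components ≥ 4 px, intensity-weighted centroids. The mid-plane
of a z-stack is the slice of maximal mask area. Droplet-size/chromatin
density correlation uses the mean pre-activation intensity in a disk of
2× droplet radius at each centroid.

**Detection/linking.** Spots are local maxima of the blurred frame above
both an intensity percentile and a robust noise floor
(median + 6·1.4826·MAD), refined by intensity-weighted centroid in a
5×5 window after subtracting the window-border median; maxima within the
refinement radius keep only the brightest. Linking minimizes total squared
displacement per frame pair (Hungarian algorithm) with a hard gate at
`max_disp` and bridges gaps up to `memory` frames; cost ties resolve by
detection order. Crossing tracks closer than the gate can swap identity —
the QC counter reports frames with multiple in-gate candidates rather than
silently ignoring the ambiguity. Tracks are assigned to the nuclear
interior/periphery by the majority of their positions against the
3-px-eroded mask (tracks are short relative to region size).

**Phase boundary.** The SVM uses an RBF kernel, `C = 1`, inverse-frequency
class weights, on standardized log10 axes — concentrations span decades, and
raw-axis margins would be dominated by high-concentration cells; a linear
kernel remains available via the `kernel` argument. The binodal polyline is
the lowest-concentration zero crossing of the decision function on a
200×200 grid spanning the data; `c_sat` is interpolated on the polyline in
log-log space, with no extrapolation outside the sampled ratio range.
PS calling uses ≥1 segmented droplet by default.

**FRAP.** Normalization maps the trace minimum to 0 and maximum to 1 after
background subtraction and optional multiplicative reference-ROI correction
(reference divided by its pre-bleach mean). The fit fixes t₀ at the bleach
time — the model names t₀ as the bleach start, so freeing it is opt-in —
and multistarts over k ∈ {0.01, 0.1, 1, 10} s⁻¹ to avoid local minima. The
mobile fraction is capped at 1.05 to tolerate noise excursions above 1.

## What passing tests do and do not show

The generators match the *statistical structure* of the live-cell readouts
(power-law MSDs with mixed populations, blob-textured nuclei, droplet
coalescence kinetics, noisy classification near a binodal, exponential FRAP
recovery) but none of their optics beyond a Gaussian PSF and Poisson noise,
no photobleaching, no motion blur, no cell-to-cell variability in
acquisition settings, and no physically detailed chromatin polymer model.
Passing recovery tests therefore demonstrates estimator correctness under
the stated noise models, not robustness to every microscopy artifact.

Known limitations: 2D tracking only; single-exponential FRAP (no
reaction–diffusion model); the binodal is an empirical classifier boundary,
not a thermodynamic fit; entropy-threshold area inflation on low-contrast
images as noted above.

## Study sizes

Validation studies run at 200 tracks × 300 steps (tracer fits), 500
droplets × 1200 s × 10 seeds (coalescence scaling), 800 cells × 10 seeds
(phase mapping), and 100 curves (FRAP) — sizes at which every recovered
quantity's sampling error is comfortably inside its acceptance band while
the full suite stays fast on a laptop.
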