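"""Canonical simulation studies with frozen study conditions.

Each function wires a synthetic generator to the analysis pipeline at the
conditions used throughout this package's validation: free-diffusion tracer
ensembles (200 tracks x 300 steps at 0.1 s), Brownian-coalescence runs
(500 droplets, area conservation, size-dependent mobility), GEM-like
mixed-mobility ensembles, phase-mapping ensembles (800 cells, 5% label
noise), and FRAP batches. The same entry points back both the test suite
and the reproduction script, so reported numbers always come from one
definition of the study.
"""

from __future__ import annotations

import numpy as np

from nucphase.config import SimConfig
from nucphase.sim import (
    CoalescenceSimState,
    FrapGroundTruth,
    PhaseEnsembleSpec,
    PopulationSpec,
    gen_coalescence,
    gen_frap,
    gen_phase_ensemble,
    gen_trajectories,
    power_law_binodal,
)
from nucphase.condensates import coalescence_scaling_check
from nucphase.frap import FRAPCurve, fit_frap
from nucphase.phasemap import fit_boundary, saturation_conc
from nucphase.tracking import (
    amplitude_distribution,
    fit_tracks_anomalous,
)

# GEM-like tracer acquisition: fast streaming at 10 fps
TRACER_FRAME_INTERVAL_S = 0.1
TRACER_N_TRACKS = 200
TRACER_N_STEPS = 300


def tracer_ensemble(
    alpha: float,
    D: float,
    seed: int,
    loc_noise_sigma: float = 0.0,
    n_tracks: int = TRACER_N_TRACKS,
    n_steps: int = TRACER_N_STEPS,
):
    """Single-population tracer trajectory ensemble."""
    cfg = SimConfig(seed=seed, frame_interval=TRACER_FRAME_INTERVAL_S)
    return gen_trajectories(
        [PopulationSpec(n_tracks, n_steps, D, alpha, loc_noise_sigma)], cfg
    )


def free_diffusion_exponent(seed: int) -> dict:
    """Mean per-track anomalous exponent for free Brownian diffusion.

    200 tracks x 300 steps, D = 0.1 um^2/s, alpha = 1, no localization
    noise; per-track time-averaged MSD fitted over lags up to 25% of track
    length.
    """
    tracks = tracer_ensemble(1.0, 0.1, seed)
    fits = fit_tracks_anomalous(tracks)
    return {
        "mean_alpha": float(fits["alpha"].mean()),
        "mean_D": float(fits["D"].mean()),
        "n_tracks": int(len(fits)),
    }


# Brownian-coalescence study: 500 droplets of radius 0.5 um at ~5% area
# fraction, unit-diameter reference mobility 0.2 um^2/s, 1200 one-second
# steps; coarsening fitted from t = 100 s (past the initial transient).
COALESCENCE_N_DROPLETS = 500
COALESCENCE_INIT_RADIUS_UM = 0.5
COALESCENCE_BOX_UM = 70.0
COALESCENCE_BASE_D = 0.2
COALESCENCE_N_STEPS = 1200
COALESCENCE_FIT_START_S = 100.0


def brownian_coalescence_ratio(seed: int) -> dict:
    """Coarsening-to-diffusive exponent ratio for one seeded run."""
    cfg = SimConfig(seed=seed, frame_interval=1.0)
    sim = CoalescenceSimState(
        box_size_um=COALESCENCE_BOX_UM,
        base_D=COALESCENCE_BASE_D,
        mobility_exponent_alpha=1.0,
        mobility_size_power=1.0,
        conserve="area",
    )
    table = gen_coalescence(
        COALESCENCE_N_DROPLETS,
        COALESCENCE_INIT_RADIUS_UM,
        sim,
        COALESCENCE_N_STEPS,
        cfg,
    )
    res = coalescence_scaling_check(
        table,
        cfg.frame_interval,
        (COALESCENCE_FIT_START_S, COALESCENCE_N_STEPS * cfg.frame_interval),
    )
    res["table"] = table
    return res


def brownian_coalescence_study(base_seed: int, n_seeds: int = 10) -> dict:
    """Ratio averaged over seeds; the Brownian-coalescence expectation is 1/3."""
    ratios = []
    for i in range(n_seeds):
        ratios.append(brownian_coalescence_ratio(base_seed + i)["ratio"])
    ratios = np.asarray(ratios)
    return {
        "ratios": ratios,
        "mean_ratio": float(ratios.mean()),
        "sd_ratio": float(ratios.std(ddof=1)),
        "n_seeds": n_seeds,
    }


# GEM-like mobility mixtures: untreated nuclei show a slow sub-diffusive
# population (alpha ~0.5) coexisting with a fast near-Brownian one
# (alpha ~1); homogenized chromatin shows a single alpha ~0.75 population.
# Amplitudes chosen to separate the two MSD modes ~10x at the 0.1 s lag.
def untreated_like_mixture(seed: int, n_tracks_per_pop: int = 100):
    cfg = SimConfig(seed=seed, frame_interval=TRACER_FRAME_INTERVAL_S)
    return gen_trajectories(
        [
            PopulationSpec(n_tracks_per_pop, TRACER_N_STEPS, 0.02, 0.5,
                           fraction=0.5, label="slow"),
            PopulationSpec(n_tracks_per_pop, TRACER_N_STEPS, 0.63, 1.0,
                           fraction=0.5, label="fast"),
        ],
        cfg,
    )


def homogenized_like_population(seed: int, n_tracks: int = 200):
    cfg = SimConfig(seed=seed, frame_interval=TRACER_FRAME_INTERVAL_S)
    return gen_trajectories(
        [PopulationSpec(n_tracks, TRACER_N_STEPS, 0.1, 0.75)], cfg
    )


def bimodality_study(seed: int, lag_s: float = 0.1) -> dict:
    """Amplitude-distribution modality of the two GEM-like conditions."""
    mixed = amplitude_distribution(untreated_like_mixture(seed), lag_s)
    single = amplitude_distribution(homogenized_like_population(seed), lag_s)
    return {"mixed": mixed, "single": single}


# Phase-mapping study: 800 cells per condition sampled log-uniformly over
# core concentration 0.01-10 uM and core-to-IDR ratio 1/64-1, with a
# power-law binodal anchored at c_sat = 0.10 uM at ratio 1/16 and 5% label
# flips (the untreated-cell headline value).
PHASE_N_CELLS = 800
PHASE_CONC_RANGE_UM = (0.01, 10.0)
PHASE_RATIO_RANGE = (1 / 64, 1.0)
PHASE_CSAT_TRUE_UM = 0.10
PHASE_BINODAL_SLOPE = 0.6
PHASE_LABEL_FLIP = 0.05


def phase_boundary_recovery(seed: int, at_ratio: float = 1 / 16) -> dict:
    """Recovered vs ground-truth saturation concentration for one ensemble."""
    cfg = SimConfig(seed=seed)
    spec = PhaseEnsembleSpec(
        PHASE_N_CELLS,
        PHASE_CONC_RANGE_UM,
        PHASE_RATIO_RANGE,
        power_law_binodal(PHASE_CSAT_TRUE_UM, PHASE_BINODAL_SLOPE),
        PHASE_LABEL_FLIP,
    )
    cells = gen_phase_ensemble(spec, cfg)
    boundary = fit_boundary(cells)
    sat = saturation_conc(boundary, at_ratio)
    return {
        "c_sat_uM": sat.c_sat_uM,
        "c_sat_true_uM": PHASE_CSAT_TRUE_UM,
        "relative_error": abs(sat.c_sat_uM - PHASE_CSAT_TRUE_UM) / PHASE_CSAT_TRUE_UM,
        "cells": cells,
        "boundary": boundary,
    }


# FRAP batch: 60 s of monitoring at 2 fps, noise sigma 0.02 — chromatin
# H2B-like mobile fractions span the nearly-immobile to fully-mobile range.
def frap_recovery_study(seed: int, n_curves: int = 100) -> dict:
    """Mean absolute mobile-fraction error over a batch of noisy curves."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 60.0, 0.5)
    errors_b, errors_k = [], []
    for i in range(n_curves):
        b = rng.uniform(0.1, 0.97)
        k = 10.0 ** rng.uniform(-1.3, -0.3)  # 0.05-0.5 /s
        truth = FrapGroundTruth(b, k, 0.0, 0.02)
        cfg = SimConfig(seed=int(rng.integers(2**31 - 1)))
        df = gen_frap(truth, t, cfg)
        fit = fit_frap(FRAPCurve(df["t_s"].to_numpy(), df["y"].to_numpy(), 0))
        errors_b.append(abs(fit.b - b))
        errors_k.append(abs(fit.k / k - 1.0))
    return {
        "mean_abs_b_error": float(np.mean(errors_b)),
        "mean_rel_k_error": float(np.mean(errors_k)),
        "n_curves": n_curves,
    }
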