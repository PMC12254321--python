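"""Brownian-coalescence droplet simulator.

Droplets random-walk in a periodic 2D box with size-dependent mobility
(per-step displacement variance proportional to diameter**-p); droplets in
contact merge, conserving total area (Sum r^2) or volume (Sum r^3). Mean-field
kinetics for p = 1, area conservation and Brownian motion (alpha = 1) give
mean diameter growth d ~ t**(1/3), i.e. a coarsening exponent of one third of
the droplet diffusive exponent — the expectation this simulator exists to
check against the condensate analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from nucphase.config import SimConfig
from nucphase.tracks import TrajectorySet
from nucphase.sim.trajectories import _fgn_cholesky


@dataclass(frozen=True)
class CoalescenceSimState:
    """Mobility and conservation rules for the droplet simulation.

    base_D : 2D MSD prefactor (um^2/s^alpha) of a droplet at diameter
    ``ref_diameter``; a droplet of diameter d moves with prefactor
    base_D * (d / ref_diameter)**(-mobility_size_power).
    """

    box_size_um: float
    base_D: float
    mobility_exponent_alpha: float = 1.0
    mobility_size_power: float = 1.0
    ref_diameter_um: float = 1.0
    conserve: str = "area"

    def __post_init__(self) -> None:
        if self.conserve not in ("area", "volume"):
            raise ValueError(f"conserve must be 'area' or 'volume', got {self.conserve}")
        if not (0 < self.mobility_exponent_alpha < 2):
            raise ValueError("mobility_exponent_alpha must lie in (0, 2)")
        if self.box_size_um <= 0 or self.base_D < 0:
            raise ValueError("box_size_um must be > 0 and base_D >= 0")


def _place_nonoverlapping(
    n: int,
    radius: float,
    box: float,
    rng: np.random.Generator,
    existing_centers: np.ndarray | None = None,
    existing_radii: np.ndarray | None = None,
    max_attempts: int = 10_000,
) -> np.ndarray:
    centers = [] if existing_centers is None else list(existing_centers)
    radii = [] if existing_radii is None else list(existing_radii)
    n_placed = 0
    attempts = 0
    out = []
    while n_placed < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} non-overlapping droplets of radius "
                f"{radius} in box {box} after {max_attempts} attempts"
            )
        attempts += 1
        c = rng.uniform(0, box, 2)
        ok = True
        for cc, rr in zip(centers, radii):
            dv = np.abs(c - cc)
            dv = np.minimum(dv, box - dv)  # periodic minimum image
            if np.hypot(*dv) <= radius + rr:
                ok = False
                break
        if ok:
            centers.append(c)
            radii.append(radius)
            out.append(c)
            n_placed += 1
    return np.asarray(out)


def _merge_components(
    centers: np.ndarray, radii: np.ndarray, box: float
) -> list[np.ndarray]:
    """Indices of transitively-touching droplet groups (periodic contact)."""
    n = len(centers)
    if n < 2:
        return [np.array([0])] if n else []
    tree = cKDTree(np.mod(centers, box), boxsize=box)
    pairs = tree.query_pairs(2 * radii.max(), output_type="ndarray")
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        dv = np.abs(centers[i] - centers[j])
        dv = np.minimum(dv, box - dv)
        if np.hypot(*dv) <= radii[i] + radii[j]:
            parent[find(i)] = find(j)
    roots = np.array([find(i) for i in range(n)])
    return [np.flatnonzero(roots == r) for r in np.unique(roots)]


def gen_coalescence(
    n_init: int,
    init_radius_um: float,
    sim: CoalescenceSimState,
    n_steps: int,
    config: SimConfig,
    initial_centers: np.ndarray | None = None,
    nucleation_window_steps: int = 0,
    nucleation_per_step: float = 0.0,
) -> pd.DataFrame:
    """Simulate droplet diffusion + coalescence; return a per-frame table.

    Columns: frame, t_s, droplet_id, x_um, y_um, radius_um, area_um2,
    equivalent_diameter_um. Droplet ids persist between merges; a merge
    creates a fresh id placed at the conserved-quantity-weighted centroid.
    Touching groups merge transitively within one step (order-independent).
    Recorded positions are unwrapped (diffusion is in a periodic box but MSD
    analysis needs continuous coordinates); wrap modulo box when rendering.
    """
    if n_init < 2:
        raise ValueError("need n_init >= 2")
    if init_radius_um <= 0:
        raise ValueError("init_radius_um must be > 0")
    rng = config.rng("coalescence")
    box = sim.box_size_um
    dt = config.frame_interval
    alpha = sim.mobility_exponent_alpha
    power = 2.0 if sim.conserve == "area" else 3.0

    if initial_centers is not None:
        centers = np.asarray(initial_centers, dtype=float)
        if len(centers) != n_init:
            raise ValueError("initial_centers length must equal n_init")
    else:
        centers = _place_nonoverlapping(n_init, init_radius_um, box, rng)
    radii = np.full(n_init, float(init_radius_um))
    ids = np.arange(n_init)
    next_id = n_init

    # unit-scale correlated increments per droplet id (fBm memory); white
    # noise shortcut when alpha == 1
    max_ids = 4 * n_init + int(nucleation_per_step * max(nucleation_window_steps, 0)) * 4 + 8
    if alpha != 1.0:
        L = _fgn_cholesky(n_steps, float(alpha))
        unit_inc = np.einsum(
            "ij,naj->nai", L, rng.standard_normal((max_ids, 2, n_steps))
        )

    def step_noise(ids_now: np.ndarray, k: int) -> np.ndarray:
        if alpha == 1.0:
            return rng.standard_normal((len(ids_now), 2))
        return unit_inc[ids_now % max_ids, :, k]

    rows = []

    def record(frame: int) -> None:
        t = frame * dt
        for i in range(len(ids)):
            r = radii[i]
            rows.append(
                (frame, t, int(ids[i]), centers[i, 0], centers[i, 1],
                 r, np.pi * r * r, 2 * r)
            )

    record(0)
    for k in range(1, n_steps):
        # nucleation while the window is open
        if k <= nucleation_window_steps and nucleation_per_step > 0:
            n_new = rng.poisson(nucleation_per_step)
            if n_new:
                try:
                    new_c = _place_nonoverlapping(
                        n_new, init_radius_um, box, rng,
                        existing_centers=np.mod(centers, box),
                        existing_radii=radii,
                    )
                except RuntimeError:
                    new_c = np.empty((0, 2))
                if len(new_c):
                    centers = np.vstack([centers, new_c])
                    radii = np.concatenate([radii, np.full(len(new_c), init_radius_um)])
                    ids = np.concatenate(
                        [ids, np.arange(next_id, next_id + len(new_c))]
                    )
                    next_id += len(new_c)

        # size-dependent mobility: 2D MSD prefactor D(d) = D0 (d/dref)^-p
        d_fac = (2 * radii / sim.ref_diameter_um) ** (-sim.mobility_size_power)
        step_sd = np.sqrt(sim.base_D * d_fac / 2.0) * dt ** (alpha / 2.0)
        centers = centers + step_sd[:, None] * step_noise(ids, k - 1)

        # transitive merging with conservation
        groups = _merge_components(np.mod(centers, box), radii, box)
        if len(groups) < len(ids):
            new_centers, new_radii, new_ids = [], [], []
            for g in sorted(groups, key=lambda g: int(ids[g].min())):
                if len(g) == 1:
                    new_centers.append(centers[g[0]])
                    new_radii.append(radii[g[0]])
                    new_ids.append(ids[g[0]])
                else:
                    w = radii[g] ** power
                    # weighted centroid via minimum-image displacements
                    ref = centers[g[0]]
                    dv = centers[g] - ref
                    dv -= box * np.round(dv / box)
                    new_centers.append(ref + (w[:, None] * dv).sum(0) / w.sum())
                    new_radii.append(w.sum() ** (1.0 / power))
                    new_ids.append(next_id)
                    next_id += 1
            centers = np.asarray(new_centers)
            radii = np.asarray(new_radii)
            ids = np.asarray(new_ids)
        record(k)

    return pd.DataFrame(
        rows,
        columns=[
            "frame", "t_s", "droplet_id", "x_um", "y_um",
            "radius_um", "area_um2", "equivalent_diameter_um",
        ],
    )


def droplet_trajectories(
    table: pd.DataFrame, frame_interval: float, min_length: int = 10
) -> TrajectorySet:
    """Extract per-droplet tracks (um) from a droplet table for MSD analysis.

    Positions are unwrapped coordinates as recorded; droplets living fewer
    than ``min_length`` frames are dropped.
    """
    d = table.rename(columns={"droplet_id": "track_id"})[
        ["track_id", "frame", "t_s", "x_um", "y_um"]
    ]
    counts = d.groupby("track_id")["frame"].size()
    keep = counts[counts >= min_length].index
    d = d[d["track_id"].isin(keep)].reset_index(drop=True)
    return TrajectorySet(d, frame_interval)
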