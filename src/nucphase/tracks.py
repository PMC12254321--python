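"""Particle-trajectory container shared by the simulator and the analysis.

A ``TrajectorySet`` is a long-format table of linked particle positions in
physical units (um, s) plus the acquisition frame interval. The CSV schema is
``track_id, frame, t_s, x_um, y_um[, population_label]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

_REQUIRED = ["track_id", "frame", "x_um", "y_um"]


@dataclass
class TrajectorySet:
    data: pd.DataFrame
    frame_interval: float

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns {missing}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        g = self.data.groupby("track_id")["frame"]
        if not (g.apply(lambda f: bool(np.all(np.diff(f.to_numpy()) > 0)))).all():
            raise ValueError("frames must be strictly increasing within a track")
        if "t_s" not in self.data.columns:
            self.data = self.data.assign(
                t_s=self.data["frame"] * self.frame_interval
            )

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def track_ids(self) -> np.ndarray:
        return self.data["track_id"].unique()

    def iter_tracks(self) -> Iterator[tuple[int, np.ndarray, np.ndarray]]:
        """Yield (track_id, frames, xy) with xy of shape (n, 2) in um."""
        for tid, sub in self.data.groupby("track_id", sort=True):
            yield tid, sub["frame"].to_numpy(), sub[["x_um", "y_um"]].to_numpy()

    def select(self, track_ids) -> "TrajectorySet":
        keep = self.data["track_id"].isin(np.atleast_1d(track_ids))
        return TrajectorySet(self.data.loc[keep].copy(), self.frame_interval)

    def with_drift(self, velocity_um_s: tuple[float, float]) -> "TrajectorySet":
        """Return a copy with a uniform drift added to every position.

        Useful for testing drift sensitivity of MSD estimators.
        """
        out = self.data.copy()
        out["x_um"] = out["x_um"] + velocity_um_s[0] * out["t_s"]
        out["y_um"] = out["y_um"] + velocity_um_s[1] * out["t_s"]
        return TrajectorySet(out, self.frame_interval)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, frame_interval: float) -> "TrajectorySet":
        return cls(pd.read_csv(path), frame_interval)
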