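"""Trajectory statistics for freely moving animals in a home cage.

Body positions tracked per video frame are reduced to two summaries used to
test whether carrying the fiberscope alters behavior: the distribution of
locomotion speed (inter-frame displacement over the frame interval,
smoothed over 200 ms to suppress tracking jitter) and the exploration rate
(fraction of a fixed 48-zone partition of the cage floor that the animal
visits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidConfigurationError

__all__ = ["Trajectory", "compute_speed", "exploration_rate", "N_ZONES", "ZONE_GRID"]

#: The cage floor is tiled by 8 x 6 zones of 4.625 x 3.5 cm.
ZONE_GRID = (8, 6)  # (n_cols along x, n_rows along y)
ZONE_SIZE = (4.625, 3.5)  # cm
N_ZONES = ZONE_GRID[0] * ZONE_GRID[1]


@dataclass
class Trajectory:
    """Tracked 2D body positions.

    ``times`` in s (strictly increasing), ``positions`` (n, 2) in cm,
    ``cage`` = (width, height) in cm.  Positions outside the cage are
    flagged (tracking reflections are removed upstream) and clipped where a
    computation needs in-cage coordinates.
    """

    times: np.ndarray
    positions: np.ndarray
    fps: float
    cage: tuple[float, float] = (37.0, 21.0)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise InvalidConfigurationError("times must be strictly increasing")
        w, h = self.cage
        out = (
            (self.positions[:, 0] < 0)
            | (self.positions[:, 0] > w)
            | (self.positions[:, 1] < 0)
            | (self.positions[:, 1] > h)
        )
        self.out_of_cage = out
        if out.any():
            warnings.warn(
                f"{int(out.sum())} position(s) outside the cage bounds "
                "(possible tracking reflections)",
                stacklevel=2,
            )

    @classmethod
    def from_csv(
        cls,
        path: str,
        fps: float,
        cm_per_pixel: float = 1.0,
        cage: tuple[float, float] = (37.0, 21.0),
    ) -> "Trajectory":
        """Read (frame, x, y[, likelihood]) positions in pixels from CSV."""
        df = pd.read_csv(path)
        frames = df["frame"].to_numpy()
        pos = df[["x", "y"]].to_numpy() * cm_per_pixel
        return cls(times=frames / fps, positions=pos, fps=fps, cage=cage)


def compute_speed(traj: Trajectory, smoothing_window: float = 0.2) -> np.ndarray:
    """Per-interval speed (cm/s), moving-averaged over ``smoothing_window`` s.

    The raw speed is the inter-frame distance divided by the inter-frame
    interval; smoothing over 200 ms suppresses unrealistic single-frame
    speed artifacts from tracking noise.
    """
    if traj.positions.shape[0] < 2:
        raise InvalidConfigurationError("need at least 2 frames to compute speed")
    d = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    dt = np.diff(traj.times)
    v = d / dt
    n_win = max(1, int(round(smoothing_window * traj.fps)))
    if n_win <= 1:
        return v
    kernel = np.ones(n_win) / n_win
    # centered moving average with edge renormalization
    num = np.convolve(v, kernel, mode="same")
    den = np.convolve(np.ones_like(v), kernel, mode="same")
    return num / den


def zone_index(positions: np.ndarray, cage: tuple[float, float]) -> np.ndarray:
    """Flat zone index (row-major) of each position on the 8 x 6 grid.

    Half-open cells: a point on a boundary belongs to the lower-index zone;
    the far cage edges fold into the last zone.
    """
    ncol, nrow = ZONE_GRID
    w, h = cage
    x = np.clip(positions[:, 0], 0.0, np.nextafter(w, 0.0))
    y = np.clip(positions[:, 1], 0.0, np.nextafter(h, 0.0))
    col = np.minimum((x / (w / ncol)).astype(int), ncol - 1)
    row = np.minimum((y / (h / nrow)).astype(int), nrow - 1)
    return row * ncol + col


def exploration_rate(traj: Trajectory) -> float:
    """Fraction of the 48 cage zones visited at least once."""
    visited = np.unique(zone_index(traj.positions, traj.cage))
    return visited.size / N_ZONES
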