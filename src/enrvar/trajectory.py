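"""Open-field trajectory analysis: occupancy grids, roaming entropy, habituation.

A tracked open-field trial is a sequence of time-stamped (x, y) positions
inside a square arena.  The arena is partitioned into ``rows x cols``
equal subfields (10 x 10 by default) and the dwell-time distribution over
the k = rows*cols subfields is summarized by the *roaming entropy*

    RE = -sum_i p_i log p_i / log k,

the Shannon entropy of the occupancy distribution normalized to [0, 1]:
0 for an animal that never leaves one subfield, 1 for an animal that
spends equal time in every subfield.  Habituation across repeated trials
is the drop in RE from the first to the second exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fraction of the arena side within which out-of-bounds points (tracking
#: jitter) are clamped to the boundary instead of rejected.
CLAMP_TOLERANCE = 0.01


class TrajectoryError(ValueError):
    """Raised for trajectories that violate the tracking-data contract."""


@dataclass
class Trajectory:
    """Positions of one animal in one trial inside a square arena.

    Parameters
    ----------
    animal_id, trial_id
        Labels identifying the animal and the trial.
    t
        Sample times in seconds, strictly increasing, at least 2 samples.
    x, y
        Arena coordinates in the same length unit as ``arena_side``.
    arena_side
        Side length of the square arena (origin at (0, 0)).
    clamp_tolerance
        Points outside the arena by at most this fraction of the side are
        clamped to the nearest boundary; anything farther out is rejected.
    """

    animal_id: str
    trial_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena_side: float
    clamp_tolerance: float = CLAMP_TOLERANCE

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.arena_side <= 0:
            raise TrajectoryError("arena_side must be positive")
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise TrajectoryError("t, x, y must have equal length")
        if self.t.size < 2:
            raise TrajectoryError(
                f"trajectory {self.animal_id}/{self.trial_id}: "
                f"needs >= 2 samples, got {self.t.size}"
            )
        if not np.all(np.diff(self.t) > 0):
            raise TrajectoryError(
                f"trajectory {self.animal_id}/{self.trial_id}: "
                "timestamps must be strictly increasing"
            )
        tol = self.clamp_tolerance * self.arena_side
        for name, v in (("x", self.x), ("y", self.y)):
            if np.any(v < -tol) or np.any(v > self.arena_side + tol):
                worst = float(np.max(np.maximum(-v, v - self.arena_side)))
                raise TrajectoryError(
                    f"trajectory {self.animal_id}/{self.trial_id}: {name} "
                    f"exceeds arena bounds by {worst:.3g} "
                    f"(> tolerance {tol:.3g})"
                )
        # clamp residual tracking jitter onto the boundary
        self.x = np.clip(self.x, 0.0, self.arena_side)
        self.y = np.clip(self.y, 0.0, self.arena_side)

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass
class OccupancyGrid:
    """Dwell-time distribution over the arena subfields.

    ``p`` is stored row-major as a flat vector of length ``k = rows*cols``;
    cell (r, c) covers x in [c*side/cols, (c+1)*side/cols) and
    y in [r*side/rows, (r+1)*side/rows), with the top/right edges closed
    so that every in-bounds point belongs to exactly one cell.
    """

    rows: int
    cols: int
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")
        if self.p.shape != (self.rows * self.cols,):
            raise ValueError("p must be a flat vector of length rows*cols")
        if np.any(self.p < 0):
            raise ValueError("occupancy probabilities must be non-negative")
        if abs(float(self.p.sum()) - 1.0) > 1e-12:
            raise ValueError("occupancy probabilities must sum to 1")

    @property
    def k(self) -> int:
        return self.rows * self.cols


@dataclass(frozen=True)
class REResult:
    """Roaming entropy of one animal in one trial, in [0, 1]."""

    animal_id: str
    trial_id: str
    re: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.re <= 1.0):
            raise ValueError(f"roaming entropy {self.re} outside [0, 1]")


def _cell_index(v: np.ndarray, side: float, n: int) -> np.ndarray:
    # half-open bins [low, high) with the top edge closed
    idx = np.floor(v / side * n).astype(int)
    return np.clip(idx, 0, n - 1)


def occupancy(traj: Trajectory, rows: int = 10, cols: int = 10) -> OccupancyGrid:
    """Dwell-time occupancy distribution of a trajectory.

    Each inter-sample interval is credited to the subfield of its starting
    sample (the final sample carries no dwell time), so the cell weights
    are trial *time*, not raw sample counts; at a constant frame rate the
    two coincide up to one frame.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    row = _cell_index(traj.y, traj.arena_side, rows)
    col = _cell_index(traj.x, traj.arena_side, cols)
    cell = row * cols + col
    dwell = np.diff(traj.t)
    weights = np.bincount(cell[:-1], weights=dwell, minlength=rows * cols)
    return OccupancyGrid(rows=rows, cols=cols, p=weights / weights.sum())


def roaming_entropy(grid: OccupancyGrid, animal_id: str = "", trial_id: str = "") -> REResult:
    """Normalized Shannon entropy of an occupancy grid.

    RE = -sum p_i log p_i / log k, with the 0*log(0) = 0 limit convention.
    The value is independent of the logarithm base and lies in [0, 1].
    """
    if grid.k < 2:
        raise ValueError("roaming entropy needs k >= 2 subfields")
    p = grid.p[grid.p > 0]
    h = -float(np.sum(p * np.log(p))) / np.log(grid.k)
    # guard against tiny negative round-off at the entropy extremes
    return REResult(animal_id=animal_id, trial_id=trial_id, re=float(np.clip(h, 0.0, 1.0)))


def habituation(re_trial1: REResult, re_trial2: REResult | None) -> float:
    """Drop in roaming entropy from trial 1 to trial 2.

    Positive values mean habituation (the animal covered less of the arena
    on re-exposure).  A missing trial-2 record propagates as NaN — lost
    records must never score as zero habituation.
    """
    if re_trial2 is None:
        return float("nan")
    if re_trial1.animal_id != re_trial2.animal_id:
        raise ValueError(
            f"habituation requires the same animal: "
            f"{re_trial1.animal_id!r} vs {re_trial2.animal_id!r}"
        )
    return re_trial1.re - re_trial2.re


def path_length(traj: Trajectory) -> float:
    """Total distance travelled: the sum of consecutive segment lengths."""
    return float(np.hypot(np.diff(traj.x), np.diff(traj.y)).sum())


def heatmap(grid: OccupancyGrid) -> np.ndarray:
    """Occupancy probabilities as a rows x cols field for rendering."""
    return grid.p.reshape(grid.rows, grid.cols)


# ---------------------------------------------------------------------------
# tracking-table I/O

#: accepted aliases for the canonical tracking columns
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "animal_id": ("animal_id", "animal", "subject", "id"),
    "trial_id": ("trial_id", "trial"),
    "t": ("t", "time", "time_s", "timestamp"),
    "x": ("x", "x_cm", "pos_x"),
    "y": ("y", "y_cm", "pos_y"),
}


def read_trajectories(
    path,
    arena_side: float,
    aliases: dict[str, tuple[str, ...]] | None = None,
    sep: str | None = None,
) -> list[Trajectory]:
    """Read a tracking table (CSV or tab-delimited tracker export).

    The canonical schema is ``animal_id, trial_id, t, x, y`` with a header
    row; common tracker aliases are remapped via ``aliases``.  One
    Trajectory is returned per (animal, trial), samples sorted by time.
    """
    aliases = aliases or COLUMN_ALIASES
    df = pd.read_csv(path, sep=sep, engine="python")
    rename = {}
    for canon, names in aliases.items():
        hit = [c for c in df.columns if c.strip().lower() in names]
        if not hit:
            raise TrajectoryError(f"{path}: no column matching {canon!r} (aliases {names})")
        rename[hit[0]] = canon
    df = df.rename(columns=rename)
    out = []
    for (animal, trial), g in df.groupby(["animal_id", "trial_id"], sort=True):
        g = g.sort_values("t")
        out.append(
            Trajectory(
                animal_id=str(animal),
                trial_id=str(trial),
                t=g["t"].to_numpy(),
                x=g["x"].to_numpy(),
                y=g["y"].to_numpy(),
                arena_side=arena_side,
            )
        )
    logger.info("read %d trajectories from %s", len(out), path)
    return out


def re_table(
    trajectories: list[Trajectory], rows: int = 10, cols: int = 10
) -> pd.DataFrame:
    """Per-animal roaming-entropy table with trial columns and habituation.

    Output columns: ``animal_id, re_trial1, re_trial2, habituation,
    path_length_trial1, path_length_trial2``.  Animals missing the second
    trial get NaN for that trial and for habituation.
    """
    recs: dict[str, dict[str, float]] = {}
    for traj in trajectories:
        re = roaming_entropy(occupancy(traj, rows, cols), traj.animal_id, traj.trial_id)
        d = recs.setdefault(traj.animal_id, {})
        d[f"re_trial{traj.trial_id}"] = re.re
        d[f"path_length_trial{traj.trial_id}"] = path_length(traj)
    df = pd.DataFrame.from_dict(recs, orient="index").sort_index()
    df.index.name = "animal_id"
    for c in ("re_trial1", "re_trial2", "path_length_trial1", "path_length_trial2"):
        if c not in df.columns:
            df[c] = np.nan
    df["habituation"] = df["re_trial1"] - df["re_trial2"]
    n_lost = int(df["re_trial2"].isna().sum())
    if n_lost:
        logger.warning("%d animals missing trial 2; habituation set to NaN", n_lost)
    return df[
        ["re_trial1", "re_trial2", "habituation", "path_length_trial1", "path_length_trial2"]
    ].reset_index()
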