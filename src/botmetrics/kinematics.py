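"""Per-position motion metrics and block-level movement indices.

Trajectories are tables of tracked 2D positions sampled at a fixed interval
(2.5 s by default, matching 5-h timelapse tracking).  From each trajectory we
derive per-position kinematics (step distance, linear speed, heading, angular
speed), segment it into non-overlapping 30-s blocks, and compute for each
complete block:

* the **straightness index** ``S`` = 1 − circular variance of the block's
  headings (1 for a perfectly straight line);
* the **gyration index** ``G`` = 1 − CV(ω) / CV(ω ∪ −ω), where CV is the
  circular variance of the angular speeds interpreted as angles (1 for a
  perfect circle: consistent, nonzero turning);
* the **normalized prediction error** ``E``: a constant-speed constant-turn
  dead-reckoning predictor is applied at every interior position and the sum
  of prediction errors is divided by the block's path length.  Inactive
  (jittering) bots are unpredictable relative to the tiny distance they
  cover, so ``E`` separates active from inactive blocks downstream.

Undefined quantities (heading of a zero-length step, indices of degenerate
blocks) propagate as ``NaN``, never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "BehaviorBlock",
    "compute_kinematics",
    "segment_blocks",
    "circular_variance",
    "straightness_index",
    "gyration_index",
    "block_prediction_error",
]


@dataclass
class Trajectory:
    """Tracked 2D positions for one bot.

    Coordinates are in µm (image convention: y increases downward), time in
    seconds.  Time must be strictly increasing; at least 3 samples are
    required for any kinematic metric.
    """

    bot_id: str
    frame: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y) == len(self.frame)):
            raise ValueError("frame, t, x, y must have equal length")
        dt = np.diff(self.t)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise ValueError(
                f"time not strictly increasing at frame index {bad[0] + 1} "
                f"(frame {self.frame[bad[0] + 1]})"
            )

    def __len__(self) -> int:
        return len(self.t)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, bot_id: str | None = None) -> "Trajectory":
        """Build from a table with columns id, frame, t_s, x_um, y_um."""
        if bot_id is None:
            ids = df["id"].unique()
            if len(ids) != 1:
                raise ValueError(f"expected one bot id, found {len(ids)}")
            bot_id = str(ids[0])
        df = df.sort_values("t_s")
        return cls(
            bot_id=bot_id,
            frame=df["frame"].to_numpy(),
            t=df["t_s"].to_numpy(),
            x=df["x_um"].to_numpy(),
            y=df["y_um"].to_numpy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.bot_id, "frame": self.frame, "t_s": self.t,
             "x_um": self.x, "y_um": self.y}
        )


@dataclass
class BehaviorBlock:
    """One complete, fixed-duration trajectory segment with its indices."""

    bot_id: str
    block_index: int
    samples: pd.DataFrame  # per-position kinematics rows of this block
    straightness: float = np.nan
    gyration: float = np.nan
    normalized_error: float = np.nan
    active: bool | None = None
    class_label: str | None = None
    flags: dict = field(default_factory=dict)


def _wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) into (−π, π]."""
    return -((-np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi)


def compute_kinematics(traj: Trajectory) -> pd.DataFrame:
    """Per-position kinematics for a trajectory.

    Returns a DataFrame with one row per sample and columns ``frame, t_s,
    x_um, y_um, dt_s, step_um, speed, heading, ang_speed``.  The heading at
    position *i* is the direction (atan2) of the displacement from position
    *i−1* to *i*; the angular speed is the wrapped difference of successive
    headings divided by the elapsed time between the two positions.  Entries
    that are undefined (first sample, zero-length steps) are NaN.
    """
    if len(traj) < 3:
        raise ValueError("at least 3 samples are required for kinematics")
    n = len(traj)
    dt = np.full(n, np.nan)
    dt[1:] = np.diff(traj.t)
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    step = np.full(n, np.nan)
    step[1:] = np.hypot(dx, dy)
    speed = step / dt
    heading = np.full(n, np.nan)
    moved = step[1:] > 0
    heading[1:][moved] = np.arctan2(dy[moved], dx[moved])
    ang_speed = np.full(n, np.nan)
    both = ~np.isnan(heading[1:]) & ~np.isnan(heading[:-1])
    ang_speed[1:][both] = (
        _wrap_angle(heading[1:][both] - heading[:-1][both]) / dt[1:][both]
    )
    return pd.DataFrame(
        {
            "frame": traj.frame,
            "t_s": traj.t,
            "x_um": traj.x,
            "y_um": traj.y,
            "dt_s": dt,
            "step_um": step,
            "speed": speed,
            "heading": heading,
            "ang_speed": ang_speed,
        }
    )


def exclude_edge_samples(
    traj: Trajectory,
    arena_bounds: tuple[float, float, float, float],
    margin_um: float = 100.0,
) -> Trajectory | None:
    """Drop samples within ``margin_um`` (≈ one bot length) of the arena edge.

    ``arena_bounds`` is (xmin, xmax, ymin, ymax) in µm.  Returns ``None``
    when fewer than 3 samples survive.
    """
    xmin, xmax, ymin, ymax = arena_bounds
    keep = (
        (traj.x >= xmin + margin_um)
        & (traj.x <= xmax - margin_um)
        & (traj.y >= ymin + margin_um)
        & (traj.y <= ymax - margin_um)
    )
    if keep.sum() < 3:
        return None
    return Trajectory(
        traj.bot_id, traj.frame[keep], traj.t[keep], traj.x[keep], traj.y[keep]
    )


def segment_blocks(
    traj: Trajectory,
    block_s: float = 30.0,
    dt_s: float | None = None,
    arena_bounds: tuple[float, float, float, float] | None = None,
    edge_margin_um: float = 100.0,
    compute_indices: bool = True,
    error_floor_um: float = 1e-6,
    error_sentinel: float = 10.0,
) -> list[BehaviorBlock]:
    """Cut a trajectory into non-overlapping fixed-duration blocks.

    Only complete blocks (no missing timestamp on the regular sampling grid)
    are returned; incomplete blocks are dropped and counted in the first
    returned block's ``flags['n_dropped']`` (0 blocks → empty list).  When
    ``arena_bounds`` is given, samples within one bot length of the boundary
    are removed before blocking (edge-effect exclusion); blocks losing
    samples that way become incomplete and are dropped.

    Raises ``ValueError`` if ``block_s`` is not an integer multiple of the
    sampling interval.
    """
    if arena_bounds is not None:
        reduced = exclude_edge_samples(traj, arena_bounds, edge_margin_um)
        if reduced is None:
            import warnings

            warnings.warn(
                f"bot {traj.bot_id}: no samples remain after edge exclusion",
                stacklevel=2,
            )
            return []
        traj = reduced
    if dt_s is None:
        dt_s = float(np.median(np.diff(traj.t)))
    n_per_block = block_s / dt_s
    if abs(n_per_block - round(n_per_block)) > 1e-9:
        raise ValueError(
            f"block_s={block_s} is not a multiple of the sampling interval "
            f"{dt_s} (remainder {block_s % dt_s:g})"
        )
    n_per_block = int(round(n_per_block))
    kin = compute_kinematics(traj)
    t0 = traj.t[0]
    block_of = np.floor((traj.t - t0) / block_s + 1e-9).astype(int)
    # sample's slot on the regular grid, used to detect missing timestamps
    slot = np.rint((traj.t - t0) / dt_s).astype(int)
    on_grid = np.abs(traj.t - (t0 + slot * dt_s)) < dt_s * 1e-6

    blocks: list[BehaviorBlock] = []
    n_dropped = 0
    for b in range(block_of.max() + 1):
        sel = block_of == b
        complete = (
            sel.sum() == n_per_block
            and on_grid[sel].all()
            and len(np.unique(slot[sel])) == n_per_block
        )
        if not complete:
            n_dropped += 1
            continue
        rows = kin.loc[sel].reset_index(drop=True)
        blk = BehaviorBlock(bot_id=traj.bot_id, block_index=b, samples=rows)
        if compute_indices:
            blk.straightness = straightness_index(rows["heading"].to_numpy())
            blk.gyration = gyration_index(rows["ang_speed"].to_numpy())
            blk.normalized_error = block_prediction_error(
                blk, path_floor_um=error_floor_um, sentinel=error_sentinel
            )
        blocks.append(blk)
    if blocks:
        blocks[0].flags["n_dropped"] = n_dropped
    return blocks


def circular_variance(angles: np.ndarray) -> float:
    """1 − mean resultant length of the unit vectors at the given angles."""
    angles = np.asarray(angles, dtype=float)
    angles = angles[~np.isnan(angles)]
    if angles.size == 0:
        return np.nan
    return 1.0 - float(np.abs(np.exp(1j * angles).mean()))


def straightness_index(headings: np.ndarray) -> float:
    """1 − circular variance of the block headings; in [0, 1].

    Equals the mean resultant length of the heading unit vectors: 1 for a
    perfectly straight line, 0 for perfectly dispersed headings.  NaN when
    fewer than 2 headings are defined.
    """
    headings = np.asarray(headings, dtype=float)
    headings = headings[~np.isnan(headings)]
    if headings.size < 2:
        return np.nan
    return 1.0 - circular_variance(headings)


def gyration_index(angular_speeds: np.ndarray) -> float:
    """1 − CV(ω) / CV(ω ∪ −ω), with ω values read as angles in radians.

    The denominator pools the angular speeds with their additive inverses,
    which brings the magnitude of the turning into the index: a block
    turning at a constant nonzero rate scores 1 (perfect circle), while
    sign-balanced or near-zero turning scores ≈0.  NaN when fewer than 2
    angular speeds are defined or when the pooled circular variance is 0
    (no turning at all — the index is undefined, not 1).
    """
    w = np.asarray(angular_speeds, dtype=float)
    w = w[~np.isnan(w)]
    if w.size < 2:
        return np.nan
    cv = circular_variance(w)
    cv_sym = circular_variance(np.concatenate([w, -w]))
    if cv_sym == 0.0:
        return np.nan
    return 1.0 - cv / cv_sym


def block_prediction_error(
    block: BehaviorBlock,
    path_floor_um: float = 1e-6,
    sentinel: float = 10.0,
) -> float:
    """Dead-reckoning prediction error normalized by block path length.

    At each interior position with defined speed, heading and angular speed,
    the next position is predicted as the current one displaced by
    ``v·dt`` along the turned heading ``θ + ω·dt``; the error is the
    Euclidean distance between prediction and observation.  The summed error
    is divided by the total path length of the block, which de-amplifies the
    error of fast bots.  A block whose path length falls below
    ``path_floor_um`` (stationary) returns ``sentinel`` and sets
    ``block.flags['stationary']``.
    """
    s = block.samples
    t = s["t_s"].to_numpy()
    x = s["x_um"].to_numpy()
    y = s["y_um"].to_numpy()
    v = s["speed"].to_numpy()
    th = s["heading"].to_numpy()
    w = s["ang_speed"].to_numpy()
    path = np.nansum(s["step_um"].to_numpy()[1:])
    if path < path_floor_um:
        block.flags["stationary"] = True
        return sentinel
    total = 0.0
    n_pred = 0
    for i in range(len(s) - 1):
        dt_next = t[i + 1] - t[i]
        if np.isnan(v[i]) or np.isnan(w[i]) or np.isnan(th[i]):
            continue
        th_pred = th[i] + w[i] * dt_next
        px = x[i] + v[i] * dt_next * np.cos(th_pred)
        py = y[i] + v[i] * dt_next * np.sin(th_pred)
        total += float(np.hypot(px - x[i + 1], py - y[i + 1]))
        n_pred += 1
    if n_pred == 0:
        # jitter blocks: steps exist but headings/ω undefined at times;
        # fall back to a zero-motion predictor over all steps
        total = float(path)
    return total / path


def block_table(blocks: list[BehaviorBlock]) -> pd.DataFrame:
    """Flatten blocks into one metrics row per block."""
    return pd.DataFrame(
        {
            "bot_id": [b.bot_id for b in blocks],
            "block_index": [b.block_index for b in blocks],
            "straightness": [b.straightness for b in blocks],
            "gyration": [b.gyration for b in blocks],
            "normalized_error": [b.normalized_error for b in blocks],
            "active": [b.active for b in blocks],
            "class_label": [b.class_label for b in blocks],
        }
    )
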