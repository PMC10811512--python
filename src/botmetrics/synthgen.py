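"""Seeded synthetic data with known ground truth.

Three generators emulate the data the analysis pipelines consume:

* :func:`simulate_trajectory` — 2D bot tracks sampled at a fixed interval
  (2.5 s default) built from a constant-speed, constant-turn process with
  per-step Gaussian heading noise.  Movement classes: ``circular`` (fast
  consistent turning), ``linear`` (no turning), ``curvilinear`` (gentle
  arcs), ``eclectic`` (regime switching between the other classes at block
  boundaries, driven by a Markov switch matrix) and ``inactive`` (isotropic
  positional jitter far smaller than a bot length).
* :func:`generate_bot_cloud` — 3D spheroid surface point clouds (body) with
  cilia placed either uniformly or polarized (von Mises–Fisher around a
  random pole), in locally clumped patches, plus a controlled fraction of
  isolated "noise" cilia and axis anchor points for symmetry analysis.
* :func:`generate_scratch_scene` — a wiggly scratch channel bounded by two
  edge polylines, a binary tissue mask, a bot track with a requested
  rotational tendency, and optionally a binary "bridge" image with known
  regional pixel densities.

All geometry is in µm with the origin at the image corner and y increasing
downward (image convention).  Every generator is a pure function of its
spec (including the seed): identical inputs reproduce identical outputs.
The emitted ground truth (per-block class labels, cilia pole, noise-cilium
indices, edge polylines, region densities) is sufficient to score every
downstream recovery test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from botmetrics.kinematics import Trajectory

__all__ = [
    "TrajectorySpec",
    "BotCloudSpec",
    "ScratchSceneSpec",
    "BotCloud",
    "ScratchScene",
    "simulate_trajectory",
    "generate_bot_cloud",
    "generate_scratch_scene",
    "class_preset",
]

MOVEMENT_CLASSES = ("circular", "linear", "curvilinear", "eclectic", "inactive")

# Default regime-switch matrix for eclectic bots over the three active
# classes (rows/cols: circular, linear, curvilinear).  Moderately sticky so
# blocks of each regime occur in runs, as mixed-behavior bots show.
DEFAULT_SWITCH_MATRIX = np.array(
    [
        [0.50, 0.30, 0.20],
        [0.25, 0.55, 0.20],
        [0.25, 0.25, 0.50],
    ]
)
SWITCH_STATES = ("circular", "linear", "curvilinear")


def class_preset(movement_class: str) -> dict:
    """Per-class kinematic presets.

    Speeds span the 5–50 µm/s range typical of these bots; the circular
    angular speed (0.35 rad/s) completes more than one full turn per 30-s
    block, the curvilinear one (0.08 rad/s) a gentle arc.  The inactive
    class is pure positional jitter with displacement far below one bot
    length (≈100 µm) per block.
    """
    presets = {
        "circular": dict(speed_mean=10.0, angular_speed=0.35, heading_noise_sd=0.04),
        "linear": dict(speed_mean=25.0, angular_speed=0.0, heading_noise_sd=0.05),
        "curvilinear": dict(speed_mean=18.0, angular_speed=0.08, heading_noise_sd=0.04),
        "eclectic": dict(speed_mean=15.0, angular_speed=0.0, heading_noise_sd=0.04),
        "inactive": dict(speed_mean=0.0, angular_speed=0.0, heading_noise_sd=0.0),
    }
    if movement_class not in presets:
        raise ValueError(f"unknown movement class {movement_class!r}")
    return presets[movement_class]


@dataclass
class TrajectorySpec:
    movement_class: str
    speed_mean: float | None = None
    angular_speed: float | None = None
    heading_noise_sd: float | None = None
    switch_matrix: np.ndarray | None = None
    duration_s: float = 18000.0  # 5 h
    dt_s: float = 2.5
    block_s: float = 30.0
    jitter_sd_um: float = 0.3  # inactive-class per-step positional jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.movement_class not in MOVEMENT_CLASSES:
            raise ValueError(f"unknown movement class {self.movement_class!r}")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.duration_s < self.dt_s:
            raise ValueError("duration_s must be at least dt_s")
        preset = class_preset(self.movement_class)
        for k, v in preset.items():
            if getattr(self, k) is None:
                setattr(self, k, v)
        if self.movement_class == "eclectic":
            if self.switch_matrix is None:
                self.switch_matrix = DEFAULT_SWITCH_MATRIX.copy()
            self.switch_matrix = np.asarray(self.switch_matrix, dtype=float)
            rows = self.switch_matrix.sum(axis=1)
            if not np.allclose(rows, 1.0):
                raise ValueError("switch_matrix rows must sum to 1")


def simulate_trajectory(spec: TrajectorySpec) -> tuple[Trajectory, dict]:
    """Simulate one bot track; returns (trajectory, truth).

    ``truth`` holds ``block_labels`` (the generating class of every full
    block, aligned with block index), the spec parameters and, for eclectic
    bots, the realized regime sequence.  Regime switches happen exactly at
    block boundaries, so each block is purely one base class.
    """
    n_steps = int(np.floor(spec.duration_s / spec.dt_s))
    steps_per_block = int(round(spec.block_s / spec.dt_s))
    if n_steps + 1 < steps_per_block:
        raise ValueError(
            f"duration {spec.duration_s} s is shorter than one "
            f"{spec.block_s} s block (minimum {spec.block_s} s)"
        )
    rng = np.random.default_rng(spec.seed)
    n = n_steps + 1
    t = np.arange(n) * spec.dt_s
    n_blocks = n // steps_per_block

    if spec.movement_class == "inactive":
        x = rng.normal(0.0, spec.jitter_sd_um, n).cumsum()
        y = rng.normal(0.0, spec.jitter_sd_um, n).cumsum()
        labels = ["inactive"] * n_blocks
        regimes = None
    else:
        if spec.movement_class == "eclectic":
            states = list(SWITCH_STATES)
            regime_idx = [rng.integers(len(states))]
            for _ in range(n_blocks - 1):
                p = spec.switch_matrix[regime_idx[-1]]
                regime_idx.append(rng.choice(len(states), p=p))
            regimes = [states[i] for i in regime_idx]
        else:
            regimes = [spec.movement_class] * n_blocks
        # per-step regime (steps beyond the last full block reuse the last)
        heading = rng.uniform(-np.pi, np.pi)
        turn_sign = rng.choice([-1.0, 1.0])
        x = np.empty(n)
        y = np.empty(n)
        x[0] = y[0] = 0.0
        for i in range(1, n):
            block = min((i - 1) // steps_per_block, n_blocks - 1)
            preset = class_preset(regimes[block])
            speed = preset["speed_mean"] if spec.movement_class == "eclectic" else spec.speed_mean
            omega = preset["angular_speed"] if spec.movement_class == "eclectic" else spec.angular_speed
            noise = preset["heading_noise_sd"] if spec.movement_class == "eclectic" else spec.heading_noise_sd
            heading += turn_sign * omega * spec.dt_s + rng.normal(0.0, noise)
            x[i] = x[i - 1] + speed * spec.dt_s * np.cos(heading)
            y[i] = y[i - 1] + speed * spec.dt_s * np.sin(heading)
        labels = list(regimes)

    traj = Trajectory(
        bot_id=f"{spec.movement_class}-{spec.seed}",
        frame=np.arange(n),
        t=t,
        x=x,
        y=y,
    )
    truth = {
        "movement_class": spec.movement_class,
        "block_labels": labels,
        "steps_per_block": steps_per_block,
        "seed": spec.seed,
    }
    if regimes is not None and spec.movement_class == "eclectic":
        truth["regimes"] = regimes
    return traj, truth


# ---------------------------------------------------------------------------
# spheroid point clouds


@dataclass
class BotCloudSpec:
    base_radius: float = 75.0
    axis_scales: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bump_amplitude: float = 0.0
    n_body_points: int = 600
    n_cilia: int = 150
    cilia_mode: str = "uniform"  # or "polarized"
    polar_concentration: float = 20.0  # von Mises–Fisher κ
    noise_fraction: float = 0.0
    cluster_scatter_rad: float = 0.06  # angular sd of cilia patch members
    n_patches: int | None = None  # default n_cilia // 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if any(s <= 0 for s in self.axis_scales):
            raise ValueError("axis_scales must all be positive")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must be in [0, 1]")
        if self.n_body_points < 50:
            raise ValueError("n_body_points must be at least 50")
        if self.cilia_mode not in ("uniform", "polarized"):
            raise ValueError(f"unknown cilia_mode {self.cilia_mode!r}")


@dataclass
class BotCloud:
    """3D body and cilia point sets for one bot (µm).

    ``anchors``, when present, holds the ``center``, ``front`` and ``back``
    points defining the movement axis for symmetry analysis.  ``truth`` is
    generator metadata (pole direction, noise-cilium indices, ...), absent
    for real data.
    """

    bot_id: str
    body_points: np.ndarray
    cilia_points: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    anchors: dict | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.body_points = np.atleast_2d(np.asarray(self.body_points, dtype=float))
        self.cilia_points = np.asarray(self.cilia_points, dtype=float).reshape(-1, 3)
        if len(self.body_points) < 50:
            raise ValueError("at least 50 body points required")
        if not np.isfinite(self.body_points).all() or not np.isfinite(self.cilia_points).all():
            raise ValueError("points must be finite")


def _uniform_sphere(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _sample_vmf(rng: np.random.Generator, mu: np.ndarray, kappa: float, n: int) -> np.ndarray:
    """von Mises–Fisher draws on S² around unit vector mu (Wood 1994)."""
    if kappa < 1e-8:
        return _uniform_sphere(rng, n)
    u = rng.uniform(size=n)
    # inverse-CDF of cos(angle) for vMF on the 2-sphere
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(np.clip(1.0 - w**2, 0.0, None))
    local = np.column_stack([s * np.cos(phi), s * np.sin(phi), w])
    # rotate z-axis onto mu
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, mu)
    c = float(z @ mu)
    if np.linalg.norm(v) < 1e-12:
        return local if c > 0 else -local
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return local @ rot.T


def _bump_field(rng: np.random.Generator, n_lobes: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Random smooth lobes on the sphere: directions and amplitudes."""
    dirs = _uniform_sphere(rng, n_lobes)
    amps = rng.uniform(0.5, 1.0, n_lobes) * rng.choice([-1.0, 1.0], n_lobes)
    return dirs, amps


def _radial_perturbation(u: np.ndarray, dirs: np.ndarray, amps: np.ndarray) -> np.ndarray:
    """Smooth surface perturbation in [−1, 1] evaluated at directions u."""
    f = np.zeros(len(u))
    for d, a in zip(dirs, amps):
        f += a * np.exp((u @ d - 1.0) / 0.25)
    m = np.abs(f).max()
    return f / m if m > 0 else f


def generate_bot_cloud(spec: BotCloudSpec) -> BotCloud:
    """Generate a spheroid body cloud with cilia and known ground truth.

    Body points sit on a radially perturbed ellipsoid surface.  Non-noise
    cilia are placed in small patches (a Thomas-like parent/offspring
    process) whose parents are uniform or von Mises–Fisher distributed;
    ``noise_fraction`` of the cilia are isolated singletons placed farther
    than the downstream clustering radius from any other cilium.
    """
    rng = np.random.default_rng(spec.seed)
    scales = np.asarray(spec.axis_scales, dtype=float)

    dirs, amps = _bump_field(rng)

    def surface_point(u: np.ndarray) -> np.ndarray:
        r = spec.base_radius * (
            1.0 + spec.bump_amplitude * _radial_perturbation(u, dirs, amps)
        )
        return (r[:, None] * u) * scales[None, :]

    u_body = _uniform_sphere(rng, spec.n_body_points)
    body = surface_point(u_body)

    n_noise = int(round(spec.noise_fraction * spec.n_cilia))
    n_main = spec.n_cilia - n_noise
    pole = _uniform_sphere(rng, 1)[0]

    n_patches = spec.n_patches or max(1, spec.n_cilia // 30)
    if spec.cilia_mode == "polarized":
        parents = _sample_vmf(rng, pole, spec.polar_concentration, n_patches)
    else:
        parents = _uniform_sphere(rng, n_patches)
    members = parents[rng.integers(n_patches, size=n_main)]
    scatter = rng.normal(0.0, spec.cluster_scatter_rad, size=(n_main, 3))
    u_cilia = members + scatter
    u_cilia /= np.linalg.norm(u_cilia, axis=1, keepdims=True)
    cilia_main = surface_point(u_cilia) if n_main else np.empty((0, 3))

    # isolated singletons: rejection-sample directions away from the patch
    # cilia.  The downstream clustering radius is data-driven (a few body
    # grid cells after projection), so the margin is set in units of the
    # body-point spacing; singletons need no margin from each other because
    # sub-min_pts groups stay noise under density-based clustering.
    noise_pts = []
    if n_noise:
        r_eff = spec.base_radius * (1.0 + spec.bump_amplitude) * max(spec.axis_scales)
        spacing = np.sqrt(4.0 * np.pi * r_eff**2 / spec.n_body_points)
        sep_patch = 3.0 * spacing  # clear of patch cilia after projection
        sep_single = 2.0 * spacing  # keep singletons from chaining together
        for _ in range(n_noise):
            cand = surface_point(_uniform_sphere(rng, 1))[0]
            for _attempt in range(300):
                ok = n_main == 0 or (
                    np.min(np.linalg.norm(cilia_main - cand, axis=1)) > sep_patch
                )
                if ok and noise_pts:
                    ok = (
                        np.min(np.linalg.norm(np.asarray(noise_pts) - cand, axis=1))
                        > sep_single
                    )
                if ok:
                    break
                cand = surface_point(_uniform_sphere(rng, 1))[0]
            noise_pts.append(cand)
    cilia = np.vstack([cilia_main, np.array(noise_pts).reshape(-1, 3)])
    noise_idx = list(range(n_main, n_main + n_noise))

    # axis anchors: movement axis along +x through the center
    ex = np.array([1.0, 0.0, 0.0])
    front = surface_point(ex[None])[0]
    back = surface_point(-ex[None])[0]
    anchors = {"center": np.zeros(3), "front": front, "back": back}

    truth = {
        "pole": pole,
        "noise_indices": noise_idx,
        "n_noise": n_noise,
        "cilia_mode": spec.cilia_mode,
        "polar_concentration": spec.polar_concentration,
        "seed": spec.seed,
    }
    return BotCloud(
        bot_id=f"bot-{spec.seed}",
        body_points=body,
        cilia_points=cilia,
        anchors=anchors,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# scratch scenes


@dataclass
class ScratchSceneSpec:
    scratch_width: float = 600.0
    edge_wiggle_amplitude: float = 60.0
    edge_wiggle_period: float = 500.0
    edge_walk_sd: float = 0.0  # µm random-walk roughness added per vertex
    channel_length: float = 2000.0
    bot_radius: float = 50.0
    follow_gyration: float = 0.5
    bot_speed: float = 15.0
    duration_s: float = 600.0
    dt_s: float = 2.5
    um_per_px: float = 4.0
    track_mode: str = "follow"  # "follow" | "midline" | "trace_edge"
    bridge: bool = False
    bridge_density: float = 0.8
    native_density: float = 0.8
    scratch_density: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scratch_width <= 2 * self.edge_wiggle_amplitude:
            raise ValueError(
                "scratch_width must exceed twice edge_wiggle_amplitude "
                "(channel edges would cross)"
            )
        if self.bot_radius <= 0:
            raise ValueError("bot_radius must be positive")
        if self.track_mode not in ("follow", "midline", "trace_edge"):
            raise ValueError(f"unknown track_mode {self.track_mode!r}")


@dataclass
class ScratchScene:
    """Scratch channel geometry plus a bot track.

    ``tissue_mask`` is True where native tissue is present (outside the
    channel); coordinates are µm, image convention (y down).
    """

    edge_a: np.ndarray  # upper edge polyline (n, 2)
    edge_b: np.ndarray  # lower edge polyline (n, 2)
    tissue_mask: np.ndarray
    um_per_px: float
    track: Trajectory
    bot_radius: float
    viable: bool = True
    bridge_image: np.ndarray | None = None
    truth: dict | None = None


def generate_scratch_scene(spec: ScratchSceneSpec) -> ScratchScene:
    """Build a wiggly scratch channel, its mask, a bot track and truth.

    The two edges are a sinusoid (amplitude/period from the spec) plus an
    optional small random walk, offset by the channel width.  The track
    follows the upper edge at one bot radius inside the channel with
    superimposed circular looping whose strength is set by
    ``follow_gyration`` (0 → straight drift, 1 → tight persistent loops);
    ``midline`` places the bot on the channel center line and
    ``trace_edge`` makes the track an exact copy of the upper edge shape.
    """
    rng = np.random.default_rng(spec.seed)
    # bridge scenes carry tall native-tissue margins so the six density
    # ROIs (one and two bridge lengths out) fit inside the image
    margin = 2.0 * spec.scratch_width if spec.bridge else 0.5 * spec.scratch_width
    h_um = spec.scratch_width + 2.0 * margin + 2.0 * spec.edge_wiggle_amplitude
    w_um = spec.channel_length
    y_mid = h_um / 2.0

    xs = np.arange(0.0, w_um + 1e-9, spec.um_per_px * 2)
    wig = spec.edge_wiggle_amplitude * np.sin(2 * np.pi * xs / spec.edge_wiggle_period)
    if spec.edge_walk_sd > 0:
        wig = wig + rng.normal(0, spec.edge_walk_sd, len(xs)).cumsum()
    y_top = y_mid - spec.scratch_width / 2.0 + wig
    y_bot = y_mid + spec.scratch_width / 2.0 + wig
    if np.any(y_bot - y_top <= 2 * spec.bot_radius):
        raise ValueError("channel narrower than the bot diameter somewhere")
    edge_a = np.column_stack([xs, y_top])
    edge_b = np.column_stack([xs, y_bot])

    # binary tissue mask: tissue outside the channel
    ny = int(round(h_um / spec.um_per_px))
    nx = int(round(w_um / spec.um_per_px))
    px_x = (np.arange(nx) + 0.5) * spec.um_per_px
    px_y = (np.arange(ny) + 0.5) * spec.um_per_px
    top_at = np.interp(px_x, xs, y_top)
    bot_at = np.interp(px_x, xs, y_bot)
    inside = (px_y[:, None] > top_at[None, :]) & (px_y[:, None] < bot_at[None, :])
    tissue_mask = ~inside

    n = int(np.floor(spec.duration_s / spec.dt_s)) + 1
    t = np.arange(n) * spec.dt_s
    x_drift = np.linspace(
        spec.bot_radius * 2, min(w_um - spec.bot_radius * 2, spec.bot_radius * 2 + spec.bot_speed * spec.duration_s), n
    )
    if spec.track_mode == "midline":
        y_track = np.interp(x_drift, xs, (y_top + y_bot) / 2.0)
        x_track = x_drift
    elif spec.track_mode == "trace_edge":
        # exact copy of the upper-edge polyline, vertex for vertex
        n = len(xs)
        t = np.arange(n) * spec.dt_s
        x_track = xs.copy()
        y_track = y_top.copy()
    else:
        # wall-following heading walk with biased turn direction: each step
        # turns ±ω0·dt with P(+) = q; the resulting gyration index is
        # ≈ (2q−1)² = follow_gyration, modulated by the weak steering that
        # keeps the bot near the upper wall
        q = 0.5 * (1.0 + np.sqrt(np.clip(spec.follow_gyration, 0.0, 1.0)))
        signs = np.where(rng.uniform(size=n - 1) < q, 1.0, -1.0)
        omega0 = 0.35  # rad/s looping rate
        kappa = 0.08  # steering gain toward the wall anchor, rad/s per rad
        anchor_y = np.interp(x_drift, xs, y_top) + spec.bot_radius * 1.2
        x_track = np.empty(n)
        y_track = np.empty(n)
        x_track[0], y_track[0] = x_drift[0], anchor_y[0]
        theta = 0.0
        for i in range(1, n):
            ahead = min(i + 4, n - 1)
            psi = np.arctan2(
                anchor_y[ahead] - y_track[i - 1], x_drift[ahead] - x_track[i - 1]
            )
            err = np.arctan2(np.sin(psi - theta), np.cos(psi - theta))
            theta += (signs[i - 1] * omega0 + kappa * err) * spec.dt_s
            x_track[i] = x_track[i - 1] + spec.bot_speed * spec.dt_s * np.cos(theta)
            y_track[i] = y_track[i - 1] + spec.bot_speed * spec.dt_s * np.sin(theta)
    track = Trajectory(
        bot_id=f"scratch-bot-{spec.seed}", frame=np.arange(n), t=t, x=x_track, y=y_track
    )

    bridge_image = None
    truth = {
        "edge_a": edge_a,
        "edge_b": edge_b,
        "follow_gyration": spec.follow_gyration,
        "seed": spec.seed,
    }
    if spec.bridge:
        bridge_image, bridge_truth = _bridge_image(
            spec, rng, nx, ny, top_at, bot_at
        )
        truth.update(bridge_truth)
    return ScratchScene(
        edge_a=edge_a,
        edge_b=edge_b,
        tissue_mask=tissue_mask,
        um_per_px=spec.um_per_px,
        track=track,
        bot_radius=spec.bot_radius,
        bridge_image=bridge_image,
        truth=truth,
    )


def _bridge_image(spec, rng, nx, ny, top_at, bot_at):
    """Binary bridge image: dense native tissue, sparse scratch, and a
    dense gap-closure band spanning the channel at the image center."""
    px_y = (np.arange(ny) + 0.5) * spec.um_per_px
    inside = (px_y[:, None] > top_at[None, :]) & (px_y[:, None] < bot_at[None, :])
    density = np.where(inside, spec.scratch_density, spec.native_density)
    # bridge band: vertical strip spanning the channel, centered in x
    band_w_px = max(4, int(round(spec.scratch_width / 3 / spec.um_per_px)))
    x0 = nx // 2 - band_w_px // 2
    band_cols = slice(x0, x0 + band_w_px)
    density[:, band_cols] = np.where(
        inside[:, band_cols], spec.bridge_density, density[:, band_cols]
    )
    img = rng.uniform(size=(ny, nx)) < density
    # bridge ROI box in pixels: the band clipped to the channel rows
    rows = np.nonzero(inside[:, x0 + band_w_px // 2])[0]
    box = (x0, int(rows.min()), band_w_px, int(rows.max() - rows.min() + 1))
    return img, {
        "bridge_box": box,
        "scratch_band": (int(rows.min()), int(rows.max() + 1)),
        "bridge_density": spec.bridge_density,
        "native_density": spec.native_density,
        "scratch_density": spec.scratch_density,
    }


# ---------------------------------------------------------------------------
# on-disk formats (CSV / JSON / PNG; see io module for readers)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    traj.to_dataframe().to_csv(path, index=False)


def write_bot_cloud(cloud: BotCloud, directory: str | Path, stem: str | None = None) -> None:
    """Write body/cilia CSV point lists plus a JSON truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or cloud.bot_id
    for name, pts in (("body", cloud.body_points), ("cilia", cloud.cilia_points)):
        pd.DataFrame(pts, columns=["x_um", "y_um", "z_um"]).to_csv(
            directory / f"{stem}_{name}.csv", index=False
        )
    side = {"voxel_spacing": list(cloud.voxel_spacing)}
    if cloud.anchors is not None:
        side["anchors"] = {k: np.asarray(v).tolist() for k, v in cloud.anchors.items()}
    if cloud.truth is not None:
        side["truth"] = {
            k: (np.asarray(v).tolist() if isinstance(v, np.ndarray) else v)
            for k, v in cloud.truth.items()
        }
    (directory / f"{stem}_meta.json").write_text(json.dumps(side, indent=1))


def write_scratch_scene(scene: ScratchScene, directory: str | Path, stem: str = "scene") -> None:
    """Write PNG mask(s) + CSV polylines + CSV track."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(
        directory / f"{stem}_mask.png",
        (scene.tissue_mask.astype(np.uint8) * 255),
    )
    if scene.bridge_image is not None:
        iio.imwrite(
            directory / f"{stem}_bridge.png",
            (scene.bridge_image.astype(np.uint8) * 255),
        )
    for name, poly in (("edge_a", scene.edge_a), ("edge_b", scene.edge_b)):
        pd.DataFrame(poly, columns=["x_um", "y_um"]).to_csv(
            directory / f"{stem}_{name}.csv", index=False
        )
    write_trajectory(scene.track, directory / f"{stem}_track.csv")
    meta = {"um_per_px": scene.um_per_px, "bot_radius": scene.bot_radius}
    if scene.truth and "bridge_box" in scene.truth:
        meta["bridge_box"] = list(scene.truth["bridge_box"])
        meta["scratch_band"] = list(scene.truth.get("scratch_band", ()))
    (directory / f"{stem}_meta.json").write_text(json.dumps(meta, indent=1))
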