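"""File formats, run configuration and the staged pipeline runner.

Tables are CSV (comma-separated, UTF-8, mandatory header, '.' decimal),
coordinates in µm with image-convention y (down).  Every pipeline run
writes a ``provenance.json`` recording the package version, timestamp,
seed and a hash of the configuration, so each number in a report is
traceable to a stage, parameter set and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

import botmetrics
from botmetrics import ethogram, kinematics, morpho, symmetry, synthgen, traversal

__all__ = ["RunConfig", "read_tracks", "write_tracks", "run_pipeline"]

TRACK_COLUMNS = ["id", "frame", "t_s", "x_um", "y_um"]

STAGES = ("simulate", "ethogram", "morpho", "symmetry", "traversal", "density", "all")


@dataclass
class RunConfig:
    """Parameters for a full synthetic-bundle pipeline run."""

    seed: int = 0
    out_dir: str = "botmetrics_out"
    # simulate
    n_bots_per_class: int = 10
    duration_s: float = 1800.0
    dt_s: float = 2.5
    block_s: float = 30.0
    n_clouds_per_population: int = 15
    n_scenes: int = 8
    # ethogram
    k_init: int = 6
    cluster_method: str = "cross-entropy"
    # morpho
    k_morphotypes: int = 3
    min_pts: int = 4
    n_boot: int = 10
    # symmetry / traversal defaults are module defaults
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs["extras"] = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_tracks(path: str | Path) -> list[kinematics.Trajectory]:
    """Read a tracker-style CSV (id, frame, t_s, x_um, y_um) into
    trajectories grouped by id and sorted by time."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column {missing[0]}")
    out = []
    for bot_id, sub in df.groupby("id", sort=True):
        sub = sub.sort_values("t_s")
        out.append(kinematics.Trajectory.from_dataframe(sub, bot_id=str(bot_id)))
    return out


def write_tracks(trajectories: list[kinematics.Trajectory], path: str | Path) -> None:
    pd.concat([t.to_dataframe() for t in trajectories]).to_csv(path, index=False)


def read_volume_pair(
    body_path: str | Path, cilia_path: str | Path | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Read aligned body/cilia intensity volumes from TIFF stacks.

    Accepts either two single-channel Z-stacks or one two-channel stack
    (axes Z×C×Y×X or C×Z×Y×X; the channel axis is the one of length 2).
    Returns float arrays indexed (z, y, x).
    """
    import tifffile

    body = np.asarray(tifffile.imread(str(body_path)), dtype=float)
    if cilia_path is not None:
        cilia = np.asarray(tifffile.imread(str(cilia_path)), dtype=float)
        if body.shape != cilia.shape:
            raise ValueError("body and cilia stacks have different shapes")
        return body, cilia
    if body.ndim != 4 or 2 not in body.shape[:2]:
        raise ValueError(
            "single-file input must be a two-channel stack (Z×C×Y×X or C×Z×Y×X)"
        )
    axis = int(body.shape[0] != 2)  # channel axis: 0 or 1
    ch = np.moveaxis(body, axis, 0)
    return ch[0], ch[1]


def _provenance(config: RunConfig, stage: str) -> dict:
    return {
        "package": "botmetrics",
        "version": botmetrics.__version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "stage": stage,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
    }


def run_pipeline(config: RunConfig, stage: str = "all") -> dict:
    """Execute the requested stage(s) in dependency order.

    Stages consume the artifacts of earlier stages from ``config.out_dir``
    (``simulate`` writes the synthetic bundle; the analysis stages read
    it).  A missing upstream artifact raises with its name.  Returns a
    dict of the main in-memory results per executed stage.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = (
        ["simulate", "ethogram", "morpho", "symmetry", "traversal", "density"]
        if stage == "all"
        else [stage]
    )
    results: dict = {}
    for st in stages:
        results[st] = _STAGE_FUNCS[st](config, out)
        (out / f"provenance_{st}.json").write_text(
            json.dumps(_provenance(config, st), indent=1)
        )
    return results


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path.name}; run the {produced_by!r} stage first"
        )
    return path


def _stage_simulate(config: RunConfig, out: Path) -> dict:
    rng = np.random.default_rng(config.seed)
    trajs = []
    for cls in synthgen.MOVEMENT_CLASSES:
        for i in range(config.n_bots_per_class):
            spec = synthgen.TrajectorySpec(
                movement_class=cls,
                duration_s=config.duration_s,
                dt_s=config.dt_s,
                block_s=config.block_s,
                seed=int(rng.integers(2**31)),
            )
            traj, truth = synthgen.simulate_trajectory(spec)
            traj.bot_id = f"{cls}-{i}"
            trajs.append((traj, truth))
    write_tracks([t for t, _ in trajs], out / "tracks.csv")
    truth_blob = {
        t.bot_id: {"class": tr["movement_class"], "block_labels": tr["block_labels"]}
        for t, tr in trajs
    }
    (out / "tracks_truth.json").write_text(json.dumps(truth_blob, indent=0))

    cloud_dir = out / "clouds"
    populations = {
        "smooth-uniform": dict(base_radius=40.0, bump_amplitude=0.03,
                               n_cilia=80, cilia_mode="uniform"),
        "large-dense": dict(base_radius=120.0, bump_amplitude=0.25,
                            n_cilia=250, cilia_mode="uniform"),
        "large-polarized": dict(base_radius=110.0, bump_amplitude=0.25,
                                n_cilia=120, cilia_mode="polarized",
                                polar_concentration=20.0),
    }
    manifest = []
    for pop, kw in populations.items():
        for i in range(config.n_clouds_per_population):
            spec = synthgen.BotCloudSpec(seed=int(rng.integers(2**31)),
                                         noise_fraction=0.05, **kw)
            cloud = synthgen.generate_bot_cloud(spec)
            cloud.bot_id = f"{pop}-{i}"
            synthgen.write_bot_cloud(cloud, cloud_dir)
            manifest.append({"bot_id": cloud.bot_id, "population": pop})
    pd.DataFrame(manifest).to_csv(out / "clouds_manifest.csv", index=False)

    scene_dir = out / "scenes"
    for i in range(config.n_scenes):
        g = 0.2 + 0.6 * i / max(config.n_scenes - 1, 1)
        spec = synthgen.ScratchSceneSpec(
            follow_gyration=g, seed=int(rng.integers(2**31)),
            bridge=(i == 0),
        )
        scene = synthgen.generate_scratch_scene(spec)
        synthgen.write_scratch_scene(scene, scene_dir, stem=f"scene-{i}")
    return {"n_tracks": len(trajs), "n_clouds": len(manifest), "n_scenes": config.n_scenes}


def _stage_ethogram(config: RunConfig, out: Path) -> dict:
    tracks = read_tracks(_require(out / "tracks.csv", "simulate"))
    blocks = []
    for traj in tracks:
        blocks.extend(kinematics.segment_blocks(traj, block_s=config.block_s))
    table = kinematics.block_table(blocks)
    table, summary = ethogram.classify_blocks(
        table, k_init=config.k_init, method=config.cluster_method, seed=config.seed
    )
    table.to_csv(out / "block_classes.csv", index=False)
    chain = summary["markov"]
    if chain is not None:
        chain.to_frame().to_csv(out / "transition_matrix.csv")
    (out / "ethogram_summary.json").write_text(
        json.dumps(
            {
                "n_active": summary["n_active"],
                "n_inactive": summary["n_inactive"],
                "cluster_names": {str(k): v for k, v in summary["cluster_names"].items()},
                "dissimilarity": {
                    str(k): v
                    for k, v in summary["dissimilarity"].items()
                    if k != "singletons"
                },
            },
            indent=1,
        )
    )
    return {"table": table, "summary": summary}


def _read_cloud(cloud_dir: Path, bot_id: str) -> synthgen.BotCloud:
    body = pd.read_csv(cloud_dir / f"{bot_id}_body.csv").to_numpy()
    cilia = pd.read_csv(cloud_dir / f"{bot_id}_cilia.csv").to_numpy()
    meta = json.loads((cloud_dir / f"{bot_id}_meta.json").read_text())
    anchors = None
    if "anchors" in meta:
        anchors = {k: np.asarray(v) for k, v in meta["anchors"].items()}
    return synthgen.BotCloud(
        bot_id=bot_id,
        body_points=body,
        cilia_points=cilia,
        voxel_spacing=tuple(meta.get("voxel_spacing", (1, 1, 3))),
        anchors=anchors,
        truth=meta.get("truth"),
    )


def _stage_morpho(config: RunConfig, out: Path) -> dict:
    manifest = pd.read_csv(_require(out / "clouds_manifest.csv", "simulate"))
    cloud_dir = out / "clouds"
    records = []
    for bot_id in manifest["bot_id"]:
        cloud = _read_cloud(cloud_dir, bot_id)
        cfg = morpho.MorphoConfig(min_pts=config.min_pts, seed=config.seed)
        records.append(morpho.compute_morpho_indices(cloud, cfg))
    table = morpho.MorphoIndices.table(records)
    table.to_csv(out / "morpho_indices.csv")
    result = morpho.cluster_morphotypes(table, k=config.k_morphotypes)
    result.labels.rename("morphotype").to_csv(out / "morphotype_labels.csv")
    result.scores.to_csv(out / "pca_scores.csv")
    result.loadings.to_csv(out / "pca_loadings.csv")
    n_boot_rows = min(config.n_boot and len(table) * 5 // 7, len(table))
    ranks = morpho.bootstrap_loading_ranks(
        table, n_boot=config.n_boot, subsample=max(2, n_boot_rows), seed=config.seed
    )
    ranks.to_csv(out / "loading_ranks.csv", index=False)
    return {"table": table, "result": result, "ranks": ranks}


def _stage_symmetry(config: RunConfig, out: Path) -> dict:
    manifest = pd.read_csv(_require(out / "clouds_manifest.csv", "simulate"))
    cloud_dir = out / "clouds"
    rows = []
    for bot_id in manifest["bot_id"]:
        cloud = _read_cloud(cloud_dir, bot_id)
        if not cloud.anchors:
            continue
        plane0 = symmetry.define_movement_plane(
            cloud.anchors["center"], cloud.anchors["front"], cloud.anchors["back"]
        )
        for offset in (0, 45, 90, 135):
            plane = symmetry.rotate_plane(plane0, offset) if offset else plane0
            st = symmetry.symmetry_stats(plane, cloud.cilia_points, cloud.body_points)
            rows.append(
                {
                    "bot_id": bot_id,
                    "axis_offset_deg": offset,
                    "tot": st.tot,
                    "diff": st.diff,
                    "difftot": st.difftot,
                    "chamfer_mean": st.chamfer_mean,
                    "chamfer_median": st.chamfer_median,
                    "body_ks_D": st.body_ks_D,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(out / "symmetry_stats.csv", index=False)
    return {"table": table}


def _stage_traversal(config: RunConfig, out: Path) -> dict:
    scene_dir = _require(out / "scenes", "simulate")
    rows = []
    for meta_path in sorted(scene_dir.glob("scene-*_meta.json")):
        stem = meta_path.name.replace("_meta.json", "")
        scene = _read_scene(scene_dir, stem)
        stats_ = traversal.traversal_stats(scene)
        rows.append(stats_.row())
    table = pd.DataFrame(rows)
    table.to_csv(out / "traversal_stats.csv", index=False)
    kept, excluded = traversal.filter_tracks(table)
    excluded.to_csv(out / "traversal_exclusions.csv", index=False)
    models = traversal.fit_contact_models(kept) if len(kept) >= 5 else {"skipped": "too few tracks"}
    report = {
        k: (
            {kk: vv for kk, vv in v.items() if kk != "residuals"}
            if isinstance(v, dict)
            else v
        )
        for k, v in models.items()
    }
    (out / "traversal_models.json").write_text(json.dumps(report, indent=1, default=str))
    return {"table": table, "kept": kept, "models": models}


def _read_scene(scene_dir: Path, stem: str) -> synthgen.ScratchScene:
    import imageio.v3 as iio

    meta = json.loads((scene_dir / f"{stem}_meta.json").read_text())
    mask = iio.imread(scene_dir / f"{stem}_mask.png") > 127
    edge_a = pd.read_csv(scene_dir / f"{stem}_edge_a.csv").to_numpy()
    edge_b = pd.read_csv(scene_dir / f"{stem}_edge_b.csv").to_numpy()
    track = read_tracks(scene_dir / f"{stem}_track.csv")[0]
    bridge = None
    bridge_path = scene_dir / f"{stem}_bridge.png"
    if bridge_path.exists():
        bridge = iio.imread(bridge_path) > 127
    truth = None
    if "bridge_box" in meta:
        truth = {"bridge_box": tuple(meta["bridge_box"])}
        if meta.get("scratch_band"):
            truth["scratch_band"] = tuple(meta["scratch_band"])
    return synthgen.ScratchScene(
        edge_a=edge_a,
        edge_b=edge_b,
        tissue_mask=mask,
        um_per_px=meta["um_per_px"],
        track=track,
        bot_radius=meta["bot_radius"],
        bridge_image=bridge,
        truth=truth,
    )


def _stage_density(config: RunConfig, out: Path) -> dict:
    scene_dir = _require(out / "scenes", "simulate")
    bridge_scenes = [
        p for p in sorted(scene_dir.glob("scene-*_bridge.png"))
    ]
    if not bridge_scenes:
        raise FileNotFoundError(
            "missing upstream artifact: no bridge image; run 'simulate' with bridge scenes"
        )
    reports = {}
    for p in bridge_scenes:
        stem = p.name.replace("_bridge.png", "")
        scene = _read_scene(scene_dir, stem)
        box = scene.truth["bridge_box"]
        rois = traversal.density_rois(
            box, scene.bridge_image.shape,
            scratch_band=scene.truth.get("scratch_band"),
        )
        reports[stem] = traversal.density_compare(scene.bridge_image, rois, box)
    (out / "density_report.json").write_text(json.dumps(reports, indent=1, default=str))
    return {"reports": reports}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "ethogram": _stage_ethogram,
    "morpho": _stage_morpho,
    "symmetry": _stage_symmetry,
    "traversal": _stage_traversal,
    "density": _stage_density,
}
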