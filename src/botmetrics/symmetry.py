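"""Bilateral-asymmetry analysis across the movement axis and control axes.

The movement axis of a bot (front/back anchor points through its center)
defines a vertical plane of symmetry: the plane containing the movement
axis and the imaging z-axis.  Cilia are split into the two hemispheres by
the sign of the dot product between the plane normal and the center→point
vector, and asymmetry is scored by:

* ``tot`` / ``diff`` / ``difftot`` — total cilia, absolute hemisphere count
  difference, and their ratio;
* the **modified Chamfer distance** — project all cilia onto the plane,
  then sum the mean (or median) of the unsquared nearest-neighbor distances
  A→B and B→A between the two projected hemisphere sets (0 for a perfectly
  mirror-symmetric pattern);
* the **body KS D** — two-sample Kolmogorov–Smirnov statistic between the
  center-distance distributions of the two body hemispheres.

Control planes are produced by rotating the normal with Rodrigues' formula
about the z-axis through the bot center (45°, 90°, 135° offsets), and the
per-bot contrast (asymmetry at ≈90° offset minus asymmetry at the movement
axis) is tested against zero per movement class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "SymmetryPlane",
    "SymmetryStats",
    "define_movement_plane",
    "hemisphere_stats",
    "chamfer_asymmetry",
    "rotate_plane",
    "body_asymmetry_ks",
    "axis_contrast_tests",
    "symmetry_stats",
]

ON_PLANE_TOL = 1e-9  # µm


@dataclass
class SymmetryPlane:
    point: np.ndarray  # bot center
    normal: np.ndarray  # unit vector
    triplet: tuple | None = None  # (center, front, back) if constructed

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise ValueError("zero normal")
        self.normal = self.normal / n

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.point) @ self.normal

    def project(self, points: np.ndarray) -> np.ndarray:
        """Orthogonal projection of points onto the plane."""
        pts = np.atleast_2d(points)
        return pts - np.outer(self.signed_distance(pts), self.normal)


@dataclass
class SymmetryStats:
    tot: int
    diff: int
    difftot: float
    chamfer_mean: float
    chamfer_median: float
    body_ks_D: float | None = None
    n_on_plane_remainder: int = 0


def define_movement_plane(
    center: np.ndarray, front: np.ndarray, back: np.ndarray
) -> SymmetryPlane:
    """Vertical symmetry plane through the movement axis.

    The plane contains the front−back axis and the imaging z-axis; its
    unit normal is perpendicular to both.  Raises when front equals back
    or the axis is (numerically) parallel to z.
    """
    center = np.asarray(center, dtype=float)
    front = np.asarray(front, dtype=float)
    back = np.asarray(back, dtype=float)
    axis = front - back
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("front and back coincide; movement axis undefined")
    axis = axis / norm
    z = np.array([0.0, 0.0, 1.0])
    normal = np.cross(z, axis)
    if np.linalg.norm(normal) < 1e-9:
        raise ValueError("movement axis parallel to the imaging z-axis")
    return SymmetryPlane(point=center, normal=normal, triplet=(center, front, back))


def _split_sides(plane: SymmetryPlane, points: np.ndarray, tol: float = ON_PLANE_TOL):
    s = plane.signed_distance(points)
    return s > tol, s < -tol, np.abs(s) <= tol


def hemisphere_stats(
    plane: SymmetryPlane, cilia_points: np.ndarray, tol: float = ON_PLANE_TOL
) -> tuple[int, int, float, int]:
    """(tot, diff, difftot, on-plane remainder) for a cilia set.

    Side membership is the sign of normal·(p − center).  Points on the
    plane (|dot| ≤ tol) are split evenly between the sides; an odd
    remainder is reported and contributes to neither count.
    """
    cilia = np.asarray(cilia_points, dtype=float).reshape(-1, 3)
    if len(cilia) == 0:
        raise ValueError("at least one cilium required")
    a, b, on = _split_sides(plane, cilia, tol)
    n_on = int(on.sum())
    na = int(a.sum()) + n_on // 2
    nb = int(b.sum()) + n_on // 2
    tot = len(cilia)
    diff = abs(na - nb)
    return tot, diff, diff / tot, n_on % 2


def chamfer_asymmetry(
    plane: SymmetryPlane,
    cilia_points: np.ndarray,
    stat: str = "mean",
    mode: str = "3d",
    tol: float = ON_PLANE_TOL,
    empty_side_sentinel: float | None = None,
) -> float:
    """Modified (unsquared) Chamfer distance between projected hemispheres.

    All cilia are projected orthogonally onto the plane; sets A and B are
    the projections originating from each side.  Returns
    ``stat(NN distances A→B) + stat(NN distances B→A)`` with ``stat`` the
    mean or the median of the unsquared distances.  ``mode='2d'`` first
    maps the in-plane points to 2D through a PCA-derived rotation (this
    preserves in-plane distances exactly, so the value matches 3D).  An
    empty hemisphere yields NaN, or ``empty_side_sentinel`` when given.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    cilia = np.asarray(cilia_points, dtype=float).reshape(-1, 3)
    a, b, _on = _split_sides(plane, cilia, tol)
    A = plane.project(cilia[a])
    B = plane.project(cilia[b])
    if len(A) == 0 or len(B) == 0:
        return np.nan if empty_side_sentinel is None else float(empty_side_sentinel)
    if mode == "2d":
        both = np.vstack([A, B])
        centered = both - both.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        flat = centered @ vt[:2].T
        A, B = flat[: len(A)], flat[len(A):]
    elif mode != "3d":
        raise ValueError("mode must be '3d' or '2d'")
    d_ab, _ = cKDTree(B).query(A)
    d_ba, _ = cKDTree(A).query(B)
    f = np.mean if stat == "mean" else np.median
    return float(f(d_ab) + f(d_ba))


def rotate_plane(
    plane: SymmetryPlane,
    angle_deg: float,
    rotation_axis: np.ndarray = (0.0, 0.0, 1.0),
) -> SymmetryPlane:
    """Rotate the plane normal by Rodrigues' formula about an axis through
    the bot center; the plane point is unchanged."""
    k = np.asarray(rotation_axis, dtype=float)
    nk = np.linalg.norm(k)
    if nk == 0:
        raise ValueError("zero rotation axis")
    k = k / nk
    th = np.deg2rad(angle_deg)
    v = plane.normal
    rotated = (
        v * np.cos(th)
        + np.cross(k, v) * np.sin(th)
        + k * (k @ v) * (1.0 - np.cos(th))
    )
    return SymmetryPlane(point=plane.point.copy(), normal=rotated)


def body_asymmetry_ks(
    plane: SymmetryPlane,
    body_points: np.ndarray,
    center: np.ndarray | None = None,
    tol: float = ON_PLANE_TOL,
) -> float:
    """Two-sample KS D between hemisphere center-distance distributions.

    Distances are measured from the bot center (the plane point unless
    ``center`` is given).  NaN when a hemisphere has fewer than 5 points.
    """
    body = np.asarray(body_points, dtype=float).reshape(-1, 3)
    c = plane.point if center is None else np.asarray(center, dtype=float)
    a, b, _ = _split_sides(plane, body, tol)
    if a.sum() < 5 or b.sum() < 5:
        return np.nan
    da = np.linalg.norm(body[a] - c, axis=1)
    db = np.linalg.norm(body[b] - c, axis=1)
    return float(stats.ks_2samp(da, db).statistic)


def symmetry_stats(
    plane: SymmetryPlane,
    cilia_points: np.ndarray,
    body_points: np.ndarray | None = None,
) -> SymmetryStats:
    """All per-axis asymmetry statistics for one bot at one plane."""
    tot, diff, difftot, rem = hemisphere_stats(plane, cilia_points)
    return SymmetryStats(
        tot=tot,
        diff=diff,
        difftot=difftot,
        chamfer_mean=chamfer_asymmetry(plane, cilia_points, stat="mean"),
        chamfer_median=chamfer_asymmetry(plane, cilia_points, stat="median"),
        body_ks_D=(
            body_asymmetry_ks(plane, body_points) if body_points is not None else None
        ),
        n_on_plane_remainder=rem,
    )


def axis_contrast_tests(
    per_bot: pd.DataFrame,
    value_col: str = "chamfer_mean",
    group_col: str = "movement_class",
    axis_col: str = "axis_offset_deg",
) -> dict:
    """Per-class tests of the 90°-offset vs movement-axis asymmetry contrast.

    ``per_bot`` holds one row per (bot, axis) with the asymmetry value; the
    contrast per bot is value(≈90°) − value(0°).  Per movement class the
    contrast is tested against 0 with a two-sided one-sample t-test and
    with one-sided Wilcoxon signed-rank tests (alternative 'greater' for
    circulars — more asymmetric off-axis — and 'less' for linears).
    Classes with n < 3 are skipped with a reason.  Also returns a PCA +
    Ward.D2 clustering of the movement-axis (tot, diff, difftot, chamfer)
    stats when those columns are present.
    """
    wide = per_bot.pivot_table(
        index=["bot_id", group_col], columns=axis_col, values=value_col
    )
    if 0 not in wide.columns or 90 not in wide.columns:
        raise ValueError("need axis offsets 0 and 90 in the table")
    contrast = (wide[90] - wide[0]).rename("asymmetry_difference").reset_index()
    out = {"contrast": contrast, "tests": {}}
    for cls, sub in contrast.groupby(group_col):
        d = sub["asymmetry_difference"].dropna().to_numpy()
        if len(d) < 3:
            out["tests"][cls] = {"skipped": f"n={len(d)} < 3"}
            continue
        entry = {"n": len(d), "mean": float(d.mean())}
        if np.allclose(d, d[0]) and abs(d[0]) < 1e-12:
            entry["degenerate"] = "all differences are 0"
            entry["t_p"] = 1.0
        else:
            t = stats.ttest_1samp(d, 0.0)
            entry["t_stat"], entry["t_p"] = float(t.statistic), float(t.pvalue)
            alt = "greater" if cls == "circular" else "less"
            try:
                w = stats.wilcoxon(d, alternative=alt)
                entry["wilcoxon_p"] = float(w.pvalue)
                entry["wilcoxon_alternative"] = alt
            except ValueError as e:  # all-zero differences
                entry["wilcoxon_skipped"] = str(e)
        out["tests"][cls] = entry

    stat_cols = [c for c in ("tot", "diff", "difftot", "chamfer_mean") if c in per_bot.columns]
    axis_rows = per_bot[per_bot[axis_col] == 0]
    if len(stat_cols) >= 2 and len(axis_rows) >= 6:
        from scipy.cluster.hierarchy import fcluster, linkage
        from sklearn.decomposition import PCA

        X = axis_rows[stat_cols].to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if keep.sum() >= 2:
            Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
            scores = PCA(n_components=2).fit_transform(Xs)
            labels = fcluster(linkage(Xs, method="ward"), t=2, criterion="maxclust")
            out["axis_pca"] = {
                "scores": scores,
                "labels": labels,
                "bot_id": axis_rows["bot_id"].to_numpy(),
                "columns": [c for c, k in zip(stat_cols, keep) if k],
            }
    return out
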