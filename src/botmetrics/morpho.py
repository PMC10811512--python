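"""Eight-index 3D morphometrics of ciliated spheroids and morphotype clustering.

Starting from binarized body and cilia point clouds (µm), the pipeline
computes per bot:

======================  =====================================================
index                   definition
======================  =====================================================
cilia_points            unique body points hit by nearest-neighbor
                        projection of the cilia ("shadow" of the cilia)
noise_points            projected cilia labeled noise by DBSCAN
max_radius              largest semi-axis of the minimum-volume enclosing
                        (spanning) ellipsoid of the body
aspect                  largest / smallest spanning-ellipsoid semi-axis
shape_smoothness        alpha-hull volume / spanning-ellipsoid volume
cilia_per_area          cilia_points / alpha-hull surface area
polarity                ‖Σ vᵢ‖ / Σ ‖vᵢ‖ for vᵢ = cilium − body center
                        (resultant-length ratio; 1 = all cilia at one pole)
homogeneity             1 − two-sample KS D between observed cilia 1NN
                        distances and those of an equal-count area-uniform
                        surface sample
======================  =====================================================

The body center is the area-weighted centroid of the alpha-hull triangles.
Morphotypes are found by z-scaling the index table, PCA (for scores and
loadings) and Ward.D2 hierarchical clustering cut at k clusters; loading
stability is assessed by bootstrap over bots, and morphotype–behavior
overlap by 2×2 Fisher exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree

from botmetrics._geometry import (
    AlphaSurface,
    Ellipsoid,
    alpha_shape,
    min_volume_ellipsoid,
    nn_distances,
)
from botmetrics.synthgen import BotCloud

__all__ = [
    "MorphoIndices",
    "MorphoConfig",
    "binarize_channels",
    "renyi_entropy_threshold",
    "slice_outlines",
    "project_cilia",
    "count_noise_points",
    "spanning_ellipsoid",
    "alpha_surface",
    "polarity",
    "cilia_homogeneity",
    "compute_morpho_indices",
    "cluster_morphotypes",
    "bootstrap_loading_ranks",
    "overlap_fisher",
]


@dataclass
class MorphoIndices:
    bot_id: str
    cilia_points: int
    noise_points: int
    max_radius: float
    aspect: float
    shape_smoothness: float
    cilia_per_area: float
    polarity: float
    homogeneity: float

    INDEX_COLUMNS = (
        "cilia_points",
        "noise_points",
        "max_radius",
        "aspect",
        "shape_smoothness",
        "cilia_per_area",
        "polarity",
        "homogeneity",
    )

    def __post_init__(self) -> None:
        if self.aspect < 1.0 - 1e-9:
            raise ValueError("aspect must be ≥ 1")
        if self.noise_points > self.cilia_points:
            raise ValueError("noise_points cannot exceed cilia_points")

    @staticmethod
    def table(records: list["MorphoIndices"]) -> pd.DataFrame:
        rows = [
            {f.name: getattr(r, f.name) for f in fields(MorphoIndices)}
            for r in records
        ]
        return pd.DataFrame(rows).set_index("bot_id")


@dataclass
class MorphoConfig:
    """Tunable parameters of the morphometric pipeline.

    ``eps``/``alpha`` default to data-driven values when left as ``None``:
    eps = 3.5× the median 1NN distance of the body points (enough to
    bridge adjacent sites of the projection grid the cilia are snapped to), alpha = the smallest
    value giving a single connected alpha complex covering the body cloud
    (see :func:`botmetrics._geometry.auto_alpha`).
    """

    eps_um: float | None = None
    min_pts: int = 4
    alpha_um: float | None = None
    mvee_tol: float = 1e-7
    n_reference_draws: int = 1
    seed: int = 0
    reduce_body: bool = False  # run per-slice concave outlines first
    concave_ratio: float = 0.4


# ---------------------------------------------------------------------------
# binarization

def _logistic_standardize(vol: np.ndarray) -> np.ndarray:
    mu, sd = float(vol.mean()), float(vol.std())
    return 1.0 / (1.0 + np.exp(-(vol - mu) / sd))


def binarize_channels(
    body_volume: np.ndarray,
    cilia_volume: np.ndarray,
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 3.0),
    snr_factor: float = 5.0,
    median_size: int = 3,
    bot_id: str = "bot",
) -> BotCloud:
    """Binarize aligned body/cilia intensity volumes into a point cloud.

    Body: intensities are passed through a logistic transform (sigmoid of
    the standardized voxel values), median-filtered to estimate the
    noise-free signal, and thresholded where the denoised signal exceeds
    the background by ``snr_factor`` times the noise scale (the standard
    deviation of the median-filter residual).  Cilia: Rényi-entropy
    automatic threshold on the raw channel.  Volumes are indexed (z, y, x);
    output points are (x, y, z) in µm via ``voxel_spacing``.
    """
    body_volume = np.asarray(body_volume, dtype=float)
    cilia_volume = np.asarray(cilia_volume, dtype=float)
    if body_volume.shape != cilia_volume.shape:
        raise ValueError("body and cilia volumes must be aligned (same shape)")
    for name, vol in (("body", body_volume), ("cilia", cilia_volume)):
        if vol.std() == 0:
            raise ValueError(f"{name} volume has constant intensity; cannot threshold")

    logi = _logistic_standardize(body_volume)
    signal = ndimage.median_filter(logi, size=median_size)
    noise_sd = float((logi - signal).std())
    background = float(np.median(signal))
    body_mask = signal > background + snr_factor * noise_sd

    thr = renyi_entropy_threshold(cilia_volume)
    cilia_mask = cilia_volume > thr

    sp = np.asarray(voxel_spacing, dtype=float)

    def to_points(mask):
        zyx = np.argwhere(mask).astype(float)
        return zyx[:, ::-1] * sp[None, :]  # (x, y, z) µm

    return BotCloud(
        bot_id=bot_id,
        body_points=to_points(body_mask),
        cilia_points=to_points(cilia_mask),
        voxel_spacing=tuple(sp),
    )


def renyi_entropy_threshold(volume: np.ndarray, n_bins: int = 256) -> float:
    """Automatic threshold by the Rényi-entropy criterion (Sahoo et al.).

    Combines the maximum-entropy thresholds at Rényi orders 1/2, 1 (Shannon
    limit) and 2 with the weighting rule of the classic implementation.
    Returns a threshold on the intensity scale of ``volume``.
    """
    v = np.asarray(volume, dtype=float).ravel()
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise ValueError("constant volume")
    hist, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    p = hist.astype(float) / hist.sum()
    P1 = np.cumsum(p)
    valid = (P1 > 1e-12) & (P1 < 1 - 1e-12)

    def t_star(alpha: float) -> int:
        with np.errstate(divide="ignore", invalid="ignore"):
            if alpha == 1.0:
                # Shannon limit (Kapur): H_below/P + ln P + H_above/(1−P) + ln(1−P)
                pn = np.where(p > 0, p, 1.0)
                Hb = np.cumsum(-p * np.log(pn))
                crit = np.where(
                    valid,
                    Hb / P1
                    + np.log(P1)
                    + (Hb[-1] - Hb) / (1 - P1)
                    + np.log(1 - P1),
                    -np.inf,
                )
            else:
                s1 = np.cumsum(p**alpha)
                s2 = s1[-1] - s1
                crit = np.where(
                    valid,
                    (np.log(s1 / P1**alpha) + np.log(s2 / (1 - P1) ** alpha))
                    / (1 - alpha),
                    -np.inf,
                )
        return int(np.argmax(crit))

    t1, t2, t3 = sorted([t_star(0.5), t_star(1.0), t_star(2.0)])
    # weighting rule of the Sahoo/ImageJ RenyiEntropy combination
    if abs(t1 - t2) <= 5 and abs(t2 - t3) <= 5:
        beta1, beta2, beta3 = 1, 2, 1
    elif abs(t1 - t2) <= 5:
        beta1, beta2, beta3 = 0, 1, 3
    elif abs(t2 - t3) <= 5:
        beta1, beta2, beta3 = 3, 1, 0
    else:
        beta1, beta2, beta3 = 1, 2, 1
    w = P1[t3] - P1[t1]
    t_idx = (
        t1 * (P1[t1] + 0.25 * w * beta1)
        + 0.25 * t2 * w * beta2
        + t3 * (1 - P1[t3] + 0.25 * w * beta3)
    )
    return float(edges[int(round(t_idx))])


def slice_outlines(
    body_points: np.ndarray,
    concave_ratio: float = 0.4,
    z_tol: float = 1e-6,
) -> tuple[np.ndarray, int]:
    """Reduce a dense body cloud to per-Z-slice concave-hull outlines.

    Points are grouped by z value; each slice's 2D outline is the concave
    hull of its (x, y) points and its vertices are emitted as 3D points at
    the slice z.  Slices with fewer than 3 points are skipped; the skip
    count is returned alongside the reduced point set.
    """
    from shapely import MultiPoint, concave_hull

    pts = np.atleast_2d(np.asarray(body_points, dtype=float))
    if len(pts) == 0:
        raise ValueError("empty body point set")
    zs = pts[:, 2]
    slot = np.round(zs / max(z_tol, 1e-12)).astype(np.int64)
    out = []
    skipped = 0
    for lv in np.unique(slot):
        sl = pts[slot == lv]
        if len(sl) < 3:
            skipped += 1
            continue
        hull = concave_hull(MultiPoint(sl[:, :2]), ratio=concave_ratio)
        if hull.geom_type != "Polygon":
            skipped += 1
            continue
        xy = np.asarray(hull.exterior.coords)[:-1]
        out.append(np.column_stack([xy, np.full(len(xy), sl[0, 2])]))
    if not out:
        raise ValueError("no slice produced a valid outline")
    return np.vstack(out), skipped


# ---------------------------------------------------------------------------
# index components

def project_cilia(
    cilia_points: np.ndarray, body_points: np.ndarray
) -> tuple[np.ndarray, int]:
    """Project each cilium onto its nearest body point.

    Returns the projected points (one per cilium, duplicates possible) and
    the Cilia Points count: the number of *unique* body points hit.  An
    empty cilia set returns ``(empty, 0)``.
    """
    body = np.atleast_2d(np.asarray(body_points, dtype=float))
    if len(body) == 0:
        raise ValueError("empty body point set")
    cilia = np.asarray(cilia_points, dtype=float).reshape(-1, 3)
    if len(cilia) == 0:
        return np.empty((0, 3)), 0
    _, idx = cKDTree(body).query(cilia)
    return body[idx], int(len(np.unique(idx)))


def count_noise_points(
    projected: np.ndarray, eps: float, min_pts: int = 4
) -> int:
    """Number of projected cilia outside any DBSCAN cluster.

    Runs DBSCAN (radius ``eps``, core threshold ``min_pts`` including the
    point itself) on the projected points; cilia sharing a projection site
    count with their multiplicity, so a dense patch collapsing onto few
    body points still forms a cluster.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 2:
        raise ValueError("min_pts must be at least 2")
    pts = np.asarray(projected, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        return 0
    from sklearn.cluster import DBSCAN

    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(pts)
    return int((labels == -1).sum())


def spanning_ellipsoid(body_points: np.ndarray, tol: float = 1e-7) -> Ellipsoid:
    """Minimum-volume enclosing ellipsoid of the body points."""
    return min_volume_ellipsoid(body_points, tol=tol)


def alpha_surface(body_points: np.ndarray, alpha: float) -> AlphaSurface:
    """3D alpha hull of the body points (volume, area, weighted center)."""
    return alpha_shape(body_points, alpha)


def polarity(center: np.ndarray, cilia_points: np.ndarray) -> float:
    """Resultant-length ratio ‖Σ vᵢ‖ / Σ ‖vᵢ‖ of center→cilium vectors.

    1 when all cilia sit at one pole (parallel vectors), 0 when they
    balance; NaN when no cilium lies away from the center.
    """
    cilia = np.asarray(cilia_points, dtype=float).reshape(-1, 3)
    if len(cilia) == 0:
        raise ValueError("at least one cilium required")
    v = cilia - np.asarray(center, dtype=float)
    norms = np.linalg.norm(v, axis=1)
    denom = norms.sum()
    if denom == 0:
        return np.nan
    return float(np.linalg.norm(v.sum(axis=0)) / denom)


def cilia_homogeneity(
    cilia_points: np.ndarray,
    surface: AlphaSurface,
    n_reference_draws: int = 1,
    seed: int | np.random.Generator = 0,
) -> float:
    """1 − KS D between observed and surface-uniform cilia 1NN distances.

    The reference sample has the same count as the observed cilia and is
    drawn area-uniformly on the surface mesh; with ``n_reference_draws`` >
    1 the statistic is averaged over independent draws.  Near 1 for
    uniformly spread cilia, near 0 for strongly clumped ones.
    """
    cilia = np.asarray(cilia_points, dtype=float).reshape(-1, 3)
    if len(cilia) < 5:
        raise ValueError("at least 5 cilia required")
    if surface.area <= 0 or len(surface.faces) == 0:
        raise ValueError("degenerate surface mesh")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    obs = nn_distances(cilia)
    vals = []
    for _ in range(n_reference_draws):
        ref = surface.sample_surface(len(cilia), rng)
        d = stats.ks_2samp(obs, nn_distances(ref)).statistic
        vals.append(1.0 - d)
    return float(np.mean(vals))


def compute_morpho_indices(
    cloud: BotCloud, config: MorphoConfig | None = None
) -> MorphoIndices:
    """Compose the eight morphometric indices for one bot."""
    cfg = config or MorphoConfig()
    body = cloud.body_points
    if cfg.reduce_body:
        body, _ = slice_outlines(body, concave_ratio=cfg.concave_ratio,
                                 z_tol=cloud.voxel_spacing[2] / 2)
    if len(cloud.cilia_points) == 0:
        raise ValueError(f"{cloud.bot_id}: empty cilia set (flagged)")

    projected, n_cilia_pts = project_cilia(cloud.cilia_points, body)
    eps = cfg.eps_um
    if eps is None:
        # the projection quantizes cilia to the body grid, so the clustering
        # radius must resolve that grid, not the raw cilia spacing
        eps = 3.5 * float(np.median(nn_distances(body)))
    n_noise = count_noise_points(projected, eps=eps, min_pts=cfg.min_pts)

    try:
        ell = spanning_ellipsoid(body, tol=cfg.mvee_tol)
    except ValueError as e:
        raise ValueError(f"{cloud.bot_id}: spanning ellipsoid failed: {e}") from e

    alpha = cfg.alpha_um
    try:
        if alpha is None:
            from botmetrics._geometry import auto_alpha

            alpha = auto_alpha(body)
        surf = alpha_surface(body, alpha)
    except ValueError as e:
        raise ValueError(f"{cloud.bot_id}: alpha surface failed: {e}") from e

    pol = polarity(surf.weighted_center, cloud.cilia_points)
    homog = cilia_homogeneity(
        cloud.cilia_points, surf, cfg.n_reference_draws, cfg.seed
    )
    return MorphoIndices(
        bot_id=cloud.bot_id,
        cilia_points=n_cilia_pts,
        noise_points=n_noise,
        max_radius=float(ell.radii[0]),
        aspect=float(ell.radii[0] / ell.radii[-1]),
        shape_smoothness=float(surf.volume / ell.volume),
        cilia_per_area=float(n_cilia_pts / surf.area),
        polarity=pol,
        homogeneity=homog,
    )


# ---------------------------------------------------------------------------
# morphotype clustering and statistics

@dataclass
class MorphotypeResult:
    scaled: pd.DataFrame
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    linkage_matrix: np.ndarray
    labels: pd.Series
    silhouette: float


def _zscale(table: pd.DataFrame) -> pd.DataFrame:
    sd = table.std(ddof=1)
    const = sd[sd == 0].index.tolist()
    if const:
        raise ValueError(f"constant index column(s): {', '.join(map(str, const))}")
    return (table - table.mean()) / sd


def cluster_morphotypes(
    table: pd.DataFrame,
    k: int = 3,
    cluster_on: str = "scaled",  # or "scores"
) -> MorphotypeResult:
    """PCA (centered+scaled) then Ward.D2 hierarchical clustering cut at k.

    ``cluster_on='scaled'`` agglomerates the z-scaled index table (default);
    ``'scores'`` agglomerates the PC scores instead.  The silhouette at k
    is reported so alternative k values remain visible.
    """
    if table.isna().any().any():
        raise ValueError("index table contains missing values")
    if len(table) < k * 5:
        raise ValueError(f"need at least {k * 5} bots for k={k}")
    scaled = _zscale(table)
    from sklearn.decomposition import PCA

    pca = PCA()
    scores = pca.fit_transform(scaled.to_numpy())
    pc_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    scores_df = pd.DataFrame(scores, index=table.index, columns=pc_names)
    loadings = pd.DataFrame(pca.components_.T, index=table.columns, columns=pc_names)

    data = scaled.to_numpy() if cluster_on == "scaled" else scores
    Z = linkage(data, method="ward")  # Ward.D2 on Euclidean distances
    labels = pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=table.index)
    from sklearn.metrics import silhouette_score

    sil = float(silhouette_score(data, labels)) if labels.nunique() > 1 else np.nan
    return MorphotypeResult(
        scaled=scaled,
        scores=scores_df,
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        linkage_matrix=Z,
        labels=labels,
        silhouette=sil,
    )


def bootstrap_loading_ranks(
    table: pd.DataFrame,
    n_boot: int = 10,
    subsample: int = 250,
    seed: int = 0,
    components: tuple[str, ...] = ("PC1", "PC2"),
) -> pd.DataFrame:
    """Bootstrap absolute PCA loadings and rank variables per component.

    Per replicate, ``subsample`` bots are drawn without replacement, the
    table is re-scaled and the absolute PC loadings recorded (absolute
    values remove the PC sign ambiguity).  Per variable the mean and a 95%
    t-interval are reported.  Ranks follow the chain rule relative to the
    highest contributor: starting from the variable with the highest CI
    upper limit, any variable whose CI overlaps the current top's CI shares
    its rank; the remaining variables repeat the rule for the next rank.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if subsample > len(table):
        raise ValueError("subsample exceeds the number of rows")
    rng = np.random.default_rng(seed)
    from sklearn.decomposition import PCA

    reps = {c: [] for c in components}
    n_pc = max(int(c[2:]) for c in components)
    for _ in range(n_boot):
        idx = rng.choice(len(table), size=subsample, replace=False)
        sub = table.iloc[idx]
        scaled = _zscale(sub)
        pca = PCA(n_components=n_pc).fit(scaled.to_numpy())
        for c in components:
            reps[c].append(np.abs(pca.components_[int(c[2:]) - 1]))

    out = []
    tcrit = stats.t.ppf(0.975, n_boot - 1)
    for c in components:
        arr = np.array(reps[c])  # (n_boot, n_var)
        mean = arr.mean(axis=0)
        half = tcrit * arr.std(axis=0, ddof=1) / np.sqrt(n_boot)
        lo, hi = mean - half, mean + half
        ranks = _chain_ranks(lo, hi)
        for j, var in enumerate(table.columns):
            out.append(
                {
                    "component": c,
                    "variable": var,
                    "mean_abs_loading": mean[j],
                    "ci_low": lo[j],
                    "ci_high": hi[j],
                    "rank": ranks[j],
                }
            )
    return pd.DataFrame(out)


def _chain_ranks(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Rank CIs relative to the highest contributor; overlap shares rank."""
    n = len(lo)
    ranks = np.zeros(n, dtype=int)
    remaining = list(range(n))
    rank = 1
    while remaining:
        top = max(remaining, key=lambda j: hi[j])
        group = [j for j in remaining if hi[j] >= lo[top] and lo[j] <= hi[top]]
        for j in group:
            ranks[j] = rank
        remaining = [j for j in remaining if j not in group]
        rank += 1
    return ranks


def overlap_fisher(
    morphotype_labels: pd.Series,
    behavior_labels: pd.Series,
    mover_classes: tuple[str, ...] = ("circular", "linear", "curvilinear", "eclectic"),
) -> dict:
    """Morphotype–behavior overlap via 2×2 Fisher exact tests.

    Two families of comparisons are run between each pair of morphotype
    clusters: (a) non-mover vs mover counts, and (b) circular vs linear
    counts.  Comparisons with an empty margin are skipped with a reason.
    Returns ``{'nonmover': {...}, 'circular_linear': {...}}`` keyed by
    cluster pair, each holding the 2×2 table and the exact p-value.
    """
    df = pd.DataFrame(
        {"morph": morphotype_labels, "behav": behavior_labels}
    ).dropna()
    clusters = sorted(df["morph"].unique())
    out = {"nonmover": {}, "circular_linear": {}}
    for i, a in enumerate(clusters):
        for b in clusters[i + 1:]:
            sub_a = df[df["morph"] == a]["behav"]
            sub_b = df[df["morph"] == b]["behav"]
            tab_nm = np.array(
                [
                    [(sub_a == "nonmover").sum(), sub_a.isin(mover_classes).sum()],
                    [(sub_b == "nonmover").sum(), sub_b.isin(mover_classes).sum()],
                ]
            )
            out["nonmover"][(a, b)] = _fisher_or_skip(tab_nm)
            tab_cl = np.array(
                [
                    [(sub_a == "circular").sum(), (sub_a == "linear").sum()],
                    [(sub_b == "circular").sum(), (sub_b == "linear").sum()],
                ]
            )
            out["circular_linear"][(a, b)] = _fisher_or_skip(tab_cl)
    return out


def _fisher_or_skip(table: np.ndarray) -> dict:
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return {"table": table, "p": None, "skipped": "empty margin"}
    res = stats.fisher_exact(table)
    return {"table": table, "p": float(res.pvalue), "skipped": None}
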