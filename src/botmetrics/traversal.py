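"""Scratch-traversal metrics, contact models and gap-closure density analysis.

A scratch scene couples two digitized scratch-edge polylines, a binary
tissue mask (tissue outside the channel) and a tracked bot.  Per scene we
measure:

* ``proportion_on_tissue`` — the bot is modeled as a disc of its tracked
  radius; per frame the overlap of the disc with the tissue mask is rated
  on the pixel raster and averaged over the track;
* ``rotational_tendency`` — the gyration index of the whole track (not of
  30-s blocks);
* ``instantaneous_velocity`` — per-frame linear speed and its mean;
* ``scratch_similarity`` — for each edge, each track heading is paired
  with the (smoothed) heading of the edge at the foot of the perpendicular
  from the bot; the similarity is the larger of the two absolute Pearson
  correlations, undefined when either series has zero variance.

Tracks are filtered to rotational tendency within [0.33, 0.7], nonzero
scratch contact and a viable tracking flag; ordinary least squares models
then relate on-tissue proportion to rotational tendency and to mean speed,
and scratch similarity to a quadratic in rotational tendency, with a
residual-vs-fitted table for curvature inspection.

Bridge/gap-closure analysis places six equal ROI boxes around a bridge box
(above/below at one vertical bridge length, adjacent/far at one and two
horizontal bridge lengths, vertically aligned to the scratch band) and
compares foreground pixel proportions with Welch t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from botmetrics.kinematics import compute_kinematics, gyration_index
from botmetrics.synthgen import ScratchScene

__all__ = [
    "TraversalStats",
    "traversal_stats",
    "scratch_similarity",
    "filter_tracks",
    "fit_contact_models",
    "density_rois",
    "density_compare",
    "binarize_image",
]

ROTATION_MIN = 0.33
ROTATION_MAX = 0.70


@dataclass
class TraversalStats:
    bot_id: str
    rotational_tendency: float
    proportion_on_tissue: float
    per_frame_proportion: np.ndarray
    speed_mean: float
    speeds: np.ndarray
    scratch_similarity: float  # NaN = undefined (zero-variance headings)
    viable: bool = True

    def row(self) -> dict:
        return {
            "bot_id": self.bot_id,
            "rotational_tendency": self.rotational_tendency,
            "proportion_on_tissue": self.proportion_on_tissue,
            "speed_mean": self.speed_mean,
            "scratch_similarity": self.scratch_similarity,
            "viable": self.viable,
        }


def _disc_overlap(mask: np.ndarray, um_per_px: float, cx: float, cy: float, r: float) -> float:
    """Fraction of the disc area covered by True mask pixels (raster count)."""
    ny, nx = mask.shape
    r_px = r / um_per_px
    cx_px = cx / um_per_px - 0.5
    cy_px = cy / um_per_px - 0.5
    x0 = max(int(np.floor(cx_px - r_px)) - 1, 0)
    x1 = min(int(np.ceil(cx_px + r_px)) + 2, nx)
    y0 = max(int(np.floor(cy_px - r_px)) - 1, 0)
    y1 = min(int(np.ceil(cy_px + r_px)) + 2, ny)
    if x0 >= x1 or y0 >= y1:
        return np.nan  # disc fully outside the image
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    in_disc = (xs[None, :] - cx_px) ** 2 + (ys[:, None] - cy_px) ** 2 <= r_px**2
    n_disc = int(in_disc.sum())
    if n_disc == 0:
        return np.nan
    return float((mask[y0:y1, x0:x1] & in_disc).sum() / n_disc)


def traversal_stats(scene: ScratchScene, min_track_s: float = 120.0) -> TraversalStats:
    """Per-scene traversal metrics (disc model, time-averaged overlap)."""
    track = scene.track
    if track.t[-1] - track.t[0] < min_track_s:
        raise ValueError(f"track shorter than {min_track_s} s")
    props = np.array(
        [
            _disc_overlap(scene.tissue_mask, scene.um_per_px, x, y, scene.bot_radius)
            for x, y in zip(track.x, track.y)
        ]
    )
    if np.isnan(props).all():
        raise ValueError("track lies fully outside the image")
    kin = compute_kinematics(track)
    speeds = kin["speed"].to_numpy()
    rt = gyration_index(kin["ang_speed"].to_numpy())
    sim = scratch_similarity(scene)
    return TraversalStats(
        bot_id=track.bot_id,
        rotational_tendency=rt,
        proportion_on_tissue=float(np.nanmean(props)),
        per_frame_proportion=props,
        speed_mean=float(np.nanmean(speeds)),
        speeds=speeds,
        scratch_similarity=sim,
        viable=scene.viable,
    )


def _polyline_headings(poly: np.ndarray, smooth_window: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment cumulative arclength and smoothed segment headings."""
    seg = np.diff(poly, axis=0)
    headings = np.arctan2(seg[:, 1], seg[:, 0])
    if smooth_window > 1:
        # circular moving average over neighboring segments
        z = np.exp(1j * headings)
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        zp = np.pad(z, pad, mode="edge")
        sm = np.convolve(zp, kernel, mode="valid")[: len(z)]
        headings = np.angle(sm)
    arclen = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    return arclen, headings


def scratch_similarity(
    scene: ScratchScene, smooth_window: int = 5, min_headings: int = 10
) -> float:
    """Max over edges of |corr(track headings, edge headings at the foot)|.

    For each tracked position with a defined heading, the closest point on
    the edge polyline (foot of the perpendicular) selects the local edge
    segment; the segment headings are smoothed over ``smooth_window``
    vertices to suppress digitization noise.  Both angle series are
    unwrapped before the Pearson correlation.  Returns NaN (undefined)
    when either series has zero variance — e.g. a straight channel with a
    straight track.
    """
    import shapely
    from shapely import LineString

    kin = compute_kinematics(scene.track)
    th = kin["heading"].to_numpy()
    ok = ~np.isnan(th)
    if ok.sum() < min_headings:
        raise ValueError(f"need ≥{min_headings} defined track headings")
    # the heading at sample i belongs to the step (i−1, i); pair it with the
    # edge heading at the foot of the perpendicular from the step midpoint
    xy_all = kin[["x_um", "y_um"]].to_numpy()
    mid = 0.5 * (xy_all[1:] + xy_all[:-1])
    xy = np.vstack([xy_all[:1], mid])[ok]
    th = np.unwrap(th[ok])

    best = np.nan
    for poly in (scene.edge_a, scene.edge_b):
        line = LineString(poly)
        arclen, seg_headings = _polyline_headings(poly, smooth_window)
        s = shapely.line_locate_point(line, shapely.points(xy))
        idx = np.clip(np.searchsorted(arclen, s, side="right") - 1, 0, len(seg_headings) - 1)
        edge_th = np.unwrap(seg_headings[idx])
        if np.std(edge_th) < 1e-12 or np.std(th) < 1e-12:
            continue  # zero variance: correlation undefined for this edge
        r = abs(float(np.corrcoef(th, edge_th)[0, 1]))
        if np.isnan(best) or r > best:
            best = r
    return best


def filter_tracks(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep analyzable tracks; log every exclusion with its rule.

    Rules: rotational tendency in [0.33, 0.7] (below: unstable rotation;
    above: skidding), nonzero scratch contact (the bot must touch a wall at
    least once), and a viable tracking flag.
    """
    exclusions = []
    keep = np.ones(len(table), dtype=bool)
    for i, row in table.reset_index(drop=True).iterrows():
        rt = row["rotational_tendency"]
        if rt < ROTATION_MIN:
            exclusions.append({"bot_id": row["bot_id"], "rule": "low rotational tendency"})
            keep[i] = False
        elif rt > ROTATION_MAX:
            exclusions.append({"bot_id": row["bot_id"], "rule": "high rotational tendency"})
            keep[i] = False
        elif row["proportion_on_tissue"] <= 0:
            exclusions.append({"bot_id": row["bot_id"], "rule": "never touched the scratch wall"})
            keep[i] = False
        elif not row.get("viable", True):
            exclusions.append({"bot_id": row["bot_id"], "rule": "tracking not viable"})
            keep[i] = False
    return table.reset_index(drop=True)[keep], pd.DataFrame(
        exclusions, columns=["bot_id", "rule"]
    )


def fit_contact_models(table: pd.DataFrame, min_rows: int = 5) -> dict:
    """OLS models of scratch interaction, with slope t-tests.

    (a) proportion_on_tissue ~ rotational_tendency,
    (b) proportion_on_tissue ~ speed_mean,
    (c) scratch_similarity ~ rotational_tendency + rotational_tendency².

    Each entry reports coefficients, two-sided slope p-values and a
    residual-vs-fitted table; for model (a) a quadratic fit of the
    residuals on the fitted values flags curvature that calls for model
    (c)'s quadratic term.
    """
    import statsmodels.api as sm

    out = {}
    specs = {
        "on_tissue_vs_rotation": ("proportion_on_tissue", ["rotational_tendency"], False),
        "on_tissue_vs_speed": ("proportion_on_tissue", ["speed_mean"], False),
        "similarity_vs_rotation_quadratic": (
            "scratch_similarity",
            ["rotational_tendency"],
            True,
        ),
    }
    for name, (ycol, xcols, quadratic) in specs.items():
        sub = table.dropna(subset=[ycol] + xcols)
        if len(sub) < min_rows:
            out[name] = {"skipped": f"n={len(sub)} < {min_rows}"}
            continue
        X = sub[xcols].to_numpy(dtype=float)
        if quadratic:
            X = np.column_stack([X, X[:, 0] ** 2])
            names = xcols + [f"{xcols[0]}^2"]
        else:
            names = list(xcols)
        X = sm.add_constant(X)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"{name}: rank-deficient design matrix")
        fit = sm.OLS(sub[ycol].to_numpy(dtype=float), X).fit()
        entry = {
            "n": int(fit.nobs),
            "params": dict(zip(["const"] + names, fit.params)),
            "pvalues": dict(zip(["const"] + names, fit.pvalues)),
            "residuals": pd.DataFrame(
                {"fitted": fit.fittedvalues, "residual": fit.resid}
            ),
        }
        # curvature diagnostic: residual ~ fitted + fitted²
        f = fit.fittedvalues
        if np.std(f) > 1e-12 and len(sub) >= 4:
            Xc = sm.add_constant(np.column_stack([f, f**2]))
            if np.linalg.matrix_rank(Xc) == 3:
                cfit = sm.OLS(fit.resid, Xc).fit()
                entry["residual_curvature_p"] = float(cfit.pvalues[2])
        out[name] = entry
    return out


# ---------------------------------------------------------------------------
# bridge / gap-closure density analysis

ROI_NAMES = (
    "above_bridge",
    "below_bridge",
    "adjacent_left",
    "adjacent_right",
    "far_left",
    "far_right",
)


def density_rois(
    bridge_box: tuple[int, int, int, int],
    image_shape: tuple[int, int],
    bridge_length: tuple[int, int] | int | None = None,
    scratch_band: tuple[int, int] | None = None,
) -> dict:
    """Place the six equal ROI boxes around a bridge box.

    ``bridge_box`` is (x, y, w, h) in pixels.  All six boxes are the size
    of the bridge box.  The offset unit is the "bridge length"
    (horizontal, vertical), defaulting to the box's own (w, h); a smaller
    value may be passed when the image is too small for full-length
    offsets.  Above/below boxes sit one vertical bridge length from the
    bridge box; the adjacent boxes one horizontal bridge length away
    inside the scratch, the far boxes one bridge length beyond the
    adjacent ones.  When ``scratch_band`` (y0, y1) is given, adjacent/far
    boxes are shifted vertically to overlay the scratch band.  Raises when
    a required box leaves the image.
    """
    x, y, w, h = bridge_box
    ny, nx = image_shape
    if x < 0 or y < 0 or x + w > nx or y + h > ny:
        raise ValueError("bridge box outside the image")
    if bridge_length is None:
        bl_h, bl_v = w, h
    elif np.isscalar(bridge_length):
        bl_h = bl_v = int(bridge_length)
    else:
        bl_h, bl_v = bridge_length
    band_y = y
    if scratch_band is not None:
        y0, y1 = scratch_band
        band_y = int(round((y0 + y1) / 2 - h / 2))
        band_y = max(0, min(band_y, ny - h))
    rois = {
        "above_bridge": (x, y - bl_v - h, w, h),
        "below_bridge": (x, y + h + bl_v, w, h),
        "adjacent_left": (x - bl_h - w, band_y, w, h),
        "adjacent_right": (x + w + bl_h, band_y, w, h),
        "far_left": (x - 2 * bl_h - w, band_y, w, h),
        "far_right": (x + w + 2 * bl_h, band_y, w, h),
    }
    for name, (rx, ry, rw, rh) in rois.items():
        if rx < 0 or ry < 0 or rx + rw > nx or ry + rh > ny:
            raise ValueError(f"ROI {name!r} does not fit inside the image")
    return rois


def binarize_image(image: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Otsu auto-threshold with manual override; True = foreground tissue."""
    img = np.asarray(image)
    if img.dtype == bool:
        return img
    if threshold is None:
        from skimage.filters import threshold_otsu

        threshold = threshold_otsu(img)
    return img > threshold


def density_compare(
    binary_image: np.ndarray,
    rois: dict,
    bridge_box: tuple[int, int, int, int],
) -> dict:
    """Foreground proportions per ROI plus Welch t-tests between groups.

    The gap-closure sample is the bridge box itself; native tissue pools
    the above/below boxes, the scratch groups pool adjacent and far boxes.
    Pixels are treated as Bernoulli samples in Welch's unequal-variance
    t-test (closure vs native, closure vs adjacent, closure vs far).
    """
    img = np.asarray(binary_image)
    if img.dtype != bool:
        raise ValueError("image must be binarized first (see binarize_image)")

    def pixels(box):
        bx, by, bw, bh = box
        patch = img[by: by + bh, bx: bx + bw]
        if patch.size == 0:
            raise ValueError(f"empty ROI {box}")
        return patch.ravel().astype(float)

    proportions = {name: float(pixels(box).mean()) for name, box in rois.items()}
    proportions["bridge"] = float(pixels(bridge_box).mean())

    groups = {
        "closure": pixels(bridge_box),
        "native": np.concatenate([pixels(rois["above_bridge"]), pixels(rois["below_bridge"])]),
        "adjacent": np.concatenate(
            [pixels(rois["adjacent_left"]), pixels(rois["adjacent_right"])]
        ),
        "far": np.concatenate([pixels(rois["far_left"]), pixels(rois["far_right"])]),
    }
    tests = {}
    for other in ("native", "adjacent", "far"):
        a, b = groups["closure"], groups[other]
        if a.std() == 0 and b.std() == 0:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
            tests[f"closure_vs_{other}"] = {"t": t, "p": p, "degenerate": True}
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            tests[f"closure_vs_{other}"] = {
                "t": float(res.statistic),
                "p": float(res.pvalue),
                "degenerate": False,
            }
    return {"proportions": proportions, "tests": tests}
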