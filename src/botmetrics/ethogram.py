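"""Activity gating, behavior clustering and the Markov-chain ethogram.

The behavioral pipeline runs on the per-block metric table produced by
:mod:`botmetrics.kinematics`:

1. **Activity gate** — a two-component gamma mixture is fit by EM to the
   normalized prediction errors of all blocks; blocks assigned to the
   higher-mean component (unpredictable relative to distance covered) are
   inactive and excluded from classification.
2. **Clustering** — active blocks are clustered in the 2D
   (straightness, gyration) plane with cross-entropy clustering (CEC,
   full-covariance Gaussian family with cost-based cluster elimination, so
   the surviving cluster count can be below ``k_init``); a Gaussian-mixture
   fallback is available behind ``method="gaussian-mixture"``.
3. **Merging** — near-duplicate raw clusters are merged into the named
   movement classes; the merge report tracks the intra-cluster average
   dissimilarity before and after.
4. **Ethogram** — empirical transition proportions between consecutive
   blocks form a row-stochastic Markov matrix; transitions are never
   counted across bot boundaries or across inactive/excluded gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy.optimize import brentq
from scipy.spatial.distance import pdist

__all__ = [
    "ActivityGate",
    "MarkovChain",
    "fit_activity_gate",
    "cluster_behaviors",
    "merge_clusters",
    "average_dissimilarity",
    "estimate_markov",
    "name_clusters",
    "classify_blocks",
]


# ---------------------------------------------------------------------------
# gamma mixture activity gate

@dataclass
class ActivityGate:
    shapes: np.ndarray  # (2,)
    rates: np.ndarray  # (2,)
    weights: np.ndarray  # (2,)
    inactive_component: int  # index of the higher-mean component
    log_likelihood: float
    n_iter: int
    seed: int | None = None

    @property
    def means(self) -> np.ndarray:
        return self.shapes / self.rates

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """(n, 2) posterior responsibilities."""
        x = np.asarray(x, dtype=float)
        logp = np.column_stack(
            [
                np.log(self.weights[k])
                + _gamma_logpdf(x, self.shapes[k], self.rates[k])
                for k in range(2)
            ]
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def is_active(self, x: np.ndarray) -> np.ndarray:
        """Boolean mask: True for blocks gated as active."""
        post = self.posterior(np.asarray(x, dtype=float))
        return post.argmax(axis=1) != self.inactive_component


def _gamma_logpdf(x, shape, rate):
    return (
        shape * np.log(rate)
        - special.gammaln(shape)
        + (shape - 1) * np.log(x)
        - rate * x
    )


def _weighted_gamma_mle(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted gamma MLE via the digamma equation; returns (shape, rate)."""
    wsum = w.sum()
    mean = float((w * x).sum() / wsum)
    mean_log = float((w * np.log(x)).sum() / wsum)
    s = np.log(mean) - mean_log  # ≥ 0 by Jensen
    if s <= 0:
        return 1e6, 1e6 / mean  # degenerate: essentially a point mass
    # initial guess (Minka 2002), then solve log(k) − ψ(k) = s
    k0 = (3 - s + np.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)

    def f(k):
        return np.log(k) - special.digamma(k) - s

    lo, hi = k0 / 10, k0 * 10
    while f(lo) < 0:
        lo /= 10
    while f(hi) > 0:
        hi *= 10
    k = brentq(f, lo, hi)
    return float(k), float(k / mean)


def fit_activity_gate(
    errors: np.ndarray,
    seed: int | None = 0,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> tuple[ActivityGate, np.ndarray]:
    """EM fit of a 2-component gamma mixture to normalized block errors.

    Returns the fitted gate and the per-block active flags (blocks assigned
    by posterior to the higher-mean component are inactive).  Initialization
    is method-of-moments on a quantile split; restarts jitter the split
    quantile.  Raises on degenerate (near-zero-variance) data, for which a
    fixed threshold should be used instead.
    """
    x = np.asarray(errors, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise ValueError("at least 50 finite error values are required")
    if x.min() <= 0:
        x = np.clip(x, 1e-12, None)
    if np.std(x) < 1e-12 * max(1.0, abs(float(np.mean(x)))):
        raise ValueError(
            "error distribution is degenerate (zero variance); "
            "use a fixed activity threshold instead of the mixture gate"
        )
    rng = np.random.default_rng(seed)
    qs = np.concatenate([[0.5], rng.uniform(0.15, 0.85, max(0, n_restarts - 1))])

    best = None
    for q in qs:
        split = np.quantile(x, q)
        groups = [x[x <= split], x[x > split]]
        if min(len(g) for g in groups) < 5 or any(np.std(g) == 0 for g in groups):
            continue
        shapes = np.empty(2)
        rates = np.empty(2)
        for k, g in enumerate(groups):
            m, v = g.mean(), max(g.var(), 1e-12)
            shapes[k] = m * m / v
            rates[k] = m / v
        weights = np.array([len(groups[0]), len(groups[1])], dtype=float) / len(x)

        ll_old = -np.inf
        for it in range(max_iter):
            logp = np.column_stack(
                [np.log(weights[k]) + _gamma_logpdf(x, shapes[k], rates[k]) for k in range(2)]
            )
            m = logp.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
            ll = float(lse.sum())
            resp = np.exp(logp - lse[:, None])
            weights = resp.mean(axis=0)
            if weights.min() < 1e-6:
                break  # collapsed component; this restart failed
            try:
                for k in range(2):
                    shapes[k], rates[k] = _weighted_gamma_mle(x, resp[:, k])
            except ValueError:
                break
            if abs(ll - ll_old) < tol * (1 + abs(ll)):
                break
            ll_old = ll
        else:
            it = max_iter
        if best is None or ll > best[0]:
            best = (ll, shapes.copy(), rates.copy(), weights.copy(), it)
    if best is None:
        raise ValueError("gamma mixture EM failed on all restarts")
    ll, shapes, rates, weights, it = best
    inactive = int(np.argmax(shapes / rates))
    gate = ActivityGate(
        shapes=shapes,
        rates=rates,
        weights=weights,
        inactive_component=inactive,
        log_likelihood=ll,
        n_iter=it,
        seed=seed,
    )
    full = np.asarray(errors, dtype=float)
    active = np.zeros(len(full), dtype=bool)
    finite = np.isfinite(full)
    active[finite] = gate.is_active(np.clip(full[finite], 1e-12, None))
    return gate, active


# ---------------------------------------------------------------------------
# cross-entropy clustering (CEC), full-covariance Gaussian family

def _cec_energy(points, labels, card_min_n):
    """Total CEC cost and per-cluster parameters for a hard assignment."""
    d = points.shape[1]
    ks = np.unique(labels)
    energy = 0.0
    params = {}
    n = len(points)
    for k in ks:
        pts = points[labels == k]
        p = len(pts) / n
        mu = pts.mean(axis=0)
        cov = np.cov(pts.T, bias=True) + np.eye(d) * 1e-10
        sign, logdet = np.linalg.slogdet(cov)
        cost = p * (-np.log(p) + 0.5 * d * np.log(2 * np.pi * np.e) + 0.5 * logdet)
        energy += cost
        params[k] = (p, mu, cov)
    return energy, params


def cluster_behaviors(
    points: np.ndarray,
    method: str = "cross-entropy",
    k_init: int = 6,
    seed: int | None = 0,
    card_min: float = 0.05,
    n_restarts: int = 10,
    max_iter: int = 100,
) -> tuple[np.ndarray, dict]:
    """Cluster behavior blocks in the (straightness, gyration) plane.

    Cross-entropy clustering iterates hard assignment under per-cluster
    Gaussian cross-entropy cost and removes clusters whose weight drops
    below ``card_min`` (cost-based elimination), so the returned number of
    clusters may be smaller than ``k_init``.  Returns ``(labels, info)``
    where labels are 0-based consecutive integers and ``info`` carries
    cluster centers, weights and the final energy.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be 2D (n, d)")
    n, d = pts.shape
    if n < k_init * 10:
        raise ValueError(f"need at least {k_init * 10} points for k_init={k_init}")
    if np.allclose(pts, pts[0]):
        import warnings

        warnings.warn("all points identical; returning a single cluster", stacklevel=2)
        return np.zeros(n, dtype=int), {"centers": pts[:1], "weights": np.array([1.0])}

    if method == "gaussian-mixture":
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(n_components=k_init, random_state=seed, n_init=5).fit(pts)
        labels = gm.predict(pts)
        labels = _relabel(labels)
        centers = np.array([pts[labels == k].mean(axis=0) for k in np.unique(labels)])
        return labels, {"centers": centers, "weights": np.bincount(labels) / n}
    if method != "cross-entropy":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    card_min_n = max(int(np.ceil(card_min * n)), d + 2)
    best = None
    for _ in range(n_restarts):
        # k-means++-style center seeding
        centers = [pts[rng.integers(n)]]
        for _k in range(1, k_init):
            d2 = np.min(
                [((pts - c) ** 2).sum(axis=1) for c in centers], axis=0
            )
            probs = d2 / d2.sum() if d2.sum() > 0 else None
            centers.append(pts[rng.choice(n, p=probs)])
        labels = np.argmin(
            [((pts - c) ** 2).sum(axis=1) for c in centers], axis=0
        )
        labels = _drop_small(pts, labels, card_min_n)
        energy = np.inf
        for _it in range(max_iter):
            _, params = _cec_energy(pts, labels, card_min_n)
            # per-point cost under each surviving cluster
            ks = sorted(params)
            cost = np.empty((n, len(ks)))
            for j, k in enumerate(ks):
                p, mu, cov = params[k]
                diff = pts - mu
                sign, logdet = np.linalg.slogdet(cov)
                sol = np.linalg.solve(cov, diff.T).T
                maha = (diff * sol).sum(axis=1)
                cost[:, j] = (
                    -np.log(p) + 0.5 * (d * np.log(2 * np.pi) + logdet + maha)
                )
            new_labels = np.asarray(ks)[cost.argmin(axis=1)]
            new_labels = _drop_small(pts, new_labels, card_min_n)
            new_energy, _ = _cec_energy(pts, new_labels, card_min_n)
            if np.array_equal(new_labels, labels) or new_energy >= energy - 1e-12:
                labels, energy = new_labels, min(energy, new_energy)
                break
            labels, energy = new_labels, new_energy
        if best is None or energy < best[0]:
            best = (energy, labels.copy())
    energy, labels = best
    labels = _relabel(labels)
    centers = np.array([pts[labels == k].mean(axis=0) for k in np.unique(labels)])
    return labels, {
        "centers": centers,
        "weights": np.bincount(labels) / n,
        "energy": energy,
    }


def _drop_small(pts, labels, card_min_n):
    """Eliminate clusters below the cardinality floor; reassign members."""
    while True:
        ks, counts = np.unique(labels, return_counts=True)
        if len(ks) <= 1 or counts.min() >= card_min_n:
            return labels
        drop = ks[counts.argmin()]
        keep = ks[ks != drop]
        centers = {k: pts[labels == k].mean(axis=0) for k in keep}
        for i in np.nonzero(labels == drop)[0]:
            labels[i] = min(keep, key=lambda k: ((pts[i] - centers[k]) ** 2).sum())


def _relabel(labels):
    """Map labels to consecutive ints ordered by cluster size (desc)."""
    ks, counts = np.unique(labels, return_counts=True)
    order = ks[np.argsort(-counts)]
    mapping = {k: i for i, k in enumerate(order)}
    return np.array([mapping[k] for k in labels], dtype=int)


# ---------------------------------------------------------------------------
# merging, dissimilarity, Markov chain

def average_dissimilarity(points: np.ndarray, labels: np.ndarray) -> dict:
    """Mean pairwise Euclidean distance within each cluster.

    Singleton clusters return 0 and are flagged in the result under
    ``'singletons'``.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    out = {}
    singletons = []
    for k in np.unique(labels):
        pts = points[labels == k]
        if len(pts) == 0:
            raise ValueError(f"cluster {k} is empty")
        if len(pts) == 1:
            out[k] = 0.0
            singletons.append(k)
        else:
            out[k] = float(pdist(pts).mean())
    out["singletons"] = singletons
    return out


def merge_clusters(
    raw_labels: np.ndarray,
    merge_map: dict,
    points: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Relabel raw clusters through ``merge_map`` (e.g. {3: 1, 4: 2}).

    Labels absent from the map must map to themselves — an unmapped raw
    label raises.  When ``points`` is given, the report contains the
    per-cluster average dissimilarity before and after the merge.
    """
    raw_labels = np.asarray(raw_labels)
    present = {k.item() if hasattr(k, "item") else k for k in np.unique(raw_labels)}
    targets = set(merge_map.values())
    full_map = {}
    for k in present:
        if k in merge_map:
            full_map[k] = merge_map[k]
        elif not merge_map or k in targets:
            full_map[k] = k
        else:
            raise KeyError(f"raw label {k!r} is not covered by the merge map")
    merged = np.array([full_map[k.item() if hasattr(k, "item") else k] for k in raw_labels])
    report = {"map": full_map}
    if points is not None:
        report["dissimilarity_before"] = average_dissimilarity(points, raw_labels)
        report["dissimilarity_after"] = average_dissimilarity(points, merged)
    return merged, report


@dataclass
class MarkovChain:
    states: list
    P: np.ndarray  # row-stochastic; NaN rows flagged in absorbing_states
    counts: np.ndarray
    flagged_rows: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.states, columns=self.states)


def estimate_markov(sequences: list[list]) -> MarkovChain:
    """Empirical transition proportions between consecutive block labels.

    ``sequences`` is one label sequence per bot (or per contiguous active
    run); transitions are only counted within a sequence, never across bot
    boundaries or gaps.  ``None``/NaN entries split a sequence into
    separate runs.  A state with zero outgoing transitions keeps a NaN row
    and is listed in ``flagged_rows``.
    """
    runs = []
    for seq in sequences:
        cur = []
        for lab in seq:
            missing = lab is None or (isinstance(lab, float) and np.isnan(lab))
            if missing:
                if len(cur) >= 2:
                    runs.append(cur)
                cur = []
            else:
                cur.append(lab)
        if len(cur) >= 2:
            runs.append(cur)
    if not runs:
        raise ValueError("no sequence with at least 2 consecutive labels")
    states = sorted({lab for run in runs for lab in run}, key=str)
    idx = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)))
    for run in runs:
        for a, b in zip(run[:-1], run[1:]):
            counts[idx[a], idx[b]] += 1
    P = np.full_like(counts, np.nan)
    flagged = []
    for i, s in enumerate(states):
        tot = counts[i].sum()
        if tot > 0:
            P[i] = counts[i] / tot
        else:
            flagged.append(s)
    return MarkovChain(states=states, P=P, counts=counts, flagged_rows=flagged)


# ---------------------------------------------------------------------------
# end-to-end behavioral classification

CLASS_PROTOTYPES = {
    # (straightness, gyration) corners of the behavior plane
    "circular": (0.0, 1.0),
    "linear": (1.0, 0.0),
    "curvilinear": (1.0, 1.0),
    "eclectic": (0.5, 0.5),
}


def name_clusters(centers: np.ndarray, classes=("circular", "linear", "curvilinear")) -> dict:
    """Map cluster indices to movement-class names by nearest prototype."""
    names = {}
    for k, c in enumerate(np.atleast_2d(centers)):
        names[k] = min(
            classes,
            key=lambda cl: (c[0] - CLASS_PROTOTYPES[cl][0]) ** 2
            + (c[1] - CLASS_PROTOTYPES[cl][1]) ** 2,
        )
    return names


def classify_blocks(
    table: pd.DataFrame,
    k_init: int = 6,
    method: str = "cross-entropy",
    seed: int | None = 0,
) -> tuple[pd.DataFrame, dict]:
    """Full pipeline: gate → cluster → name/merge → Markov ethogram.

    ``table`` is the block-metric table from ``kinematics.block_table``
    (one row per complete block).  Returns the table with ``active`` and
    ``class_label`` columns filled, plus a summary dict (gate, cluster
    info, per-class dissimilarity, Markov chain over named classes).
    """
    table = table.copy()
    gate, active = fit_activity_gate(table["normalized_error"].to_numpy(), seed=seed)
    table["active"] = active
    ok = active & table["straightness"].notna() & table["gyration"].notna()
    pts = table.loc[ok, ["straightness", "gyration"]].to_numpy()
    raw, info = cluster_behaviors(pts, method=method, k_init=k_init, seed=seed)
    names = name_clusters(info["centers"])
    class_labels = np.array([names[k] for k in raw], dtype=object)
    table["class_label"] = None
    table.loc[ok, "class_label"] = class_labels
    table.loc[active & ~ok, "class_label"] = None
    diss = average_dissimilarity(pts, class_labels)

    seqs = []
    for _bot, sub in table.groupby("bot_id", sort=True):
        sub = sub.sort_values("block_index")
        labs = [
            lab if (act and lab is not None) else None
            for act, lab in zip(sub["active"], sub["class_label"])
        ]
        seqs.append(labs)
    try:
        chain = estimate_markov(seqs)
    except ValueError:
        chain = None
    summary = {
        "gate": gate,
        "cluster_info": info,
        "cluster_names": names,
        "dissimilarity": diss,
        "markov": chain,
        "n_active": int(active.sum()),
        "n_inactive": int((~active).sum()),
    }
    return table, summary
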