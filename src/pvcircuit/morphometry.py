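"""Morphometric feature extraction and two-cluster separation of SWC trees.

Extracts a registry of soma and dendritic-arbor features from validated SWC
reconstructions (lengths, axis spreads, convex hull, box-counting fractal
dimension, tortuosity) and reproduces the two-population K-means analysis
(k-means++ seeding, z-scored features) with contingency/purity reporting
and normality-screened two-group comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from sklearn.cluster import KMeans

from .reporting import ContingencyTable
from .swc import Morphology, read_swc, write_swc  # noqa: F401  (re-exported)

__all__ = [
    "FeatureVector",
    "ClusterResult",
    "GroupComparison",
    "extract_features",
    "feature_table",
    "kmeans_two",
    "contingency",
    "compare_groups",
    "read_swc",
    "write_swc",
    "Morphology",
]

FEATURE_NAMES = (
    "soma_volume",
    "soma_surface",
    "total_dendritic_length",
    "rc_dendritic_length",
    "dv_dendritic_length",
    "rc_spread",
    "dv_spread",
    "rc_dv_ratio",
    "convex_hull_volume",
    "n_branch_nodes",
    "n_trees",
    "max_branch_order",
    "fractal_dimension",
    "mean_tortuosity",
    "dendritic_surface",
    "dendritic_volume",
)


@dataclass
class FeatureVector:
    values: dict
    flags: list = field(default_factory=list)

    def __getitem__(self, key):
        return self.values[key]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values)


@dataclass
class ClusterResult:
    assignments: pd.Series  # cell -> {1, 2}
    centroids: pd.DataFrame  # cluster -> feature means (original units)
    seed: int
    standardization: str = "zscore"
    dropped_features: list = field(default_factory=list)


@dataclass
class GroupComparison:
    test: str  # "t" or "mann-whitney"
    statistic: float
    pvalue: float
    normal: tuple = (False, False)


# --------------------------------------------------------------------------
# feature extraction
# --------------------------------------------------------------------------


def _branch_segments(m: Morphology) -> list[np.ndarray]:
    """Paths between topological nodes (root/soma, branch points, tips),
    each as an index array of the traversed nodes."""
    idx = m.index_of()
    child_counts = m.children_counts()
    children: dict[int, list[int]] = {k: [] for k in range(m.n_nodes)}
    root = None
    for k, p in enumerate(m.parent):
        if p == -1:
            root = k
        else:
            children[idx[int(p)]].append(k)
    segments = []
    # start a segment below the root and below every branch point
    starts = []
    for k in range(m.n_nodes):
        if k == root or child_counts[k] > 1 or m.types[k] == 1:
            starts.extend(children[k])
    for s in starts:
        path = [idx[int(m.parent[s])], s]
        cur = s
        while child_counts[cur] == 1:
            cur = children[cur][0]
            path.append(cur)
        segments.append(np.asarray(path))
    return segments


def _fractal_dimension(points: np.ndarray, min_sizes: int = 5) -> float:
    """2-D box-counting dimension over >= 5 dyadic box sizes."""
    pts = points - points.min(axis=0)
    extent = pts.max()
    if extent <= 0:
        return 0.0
    pts = pts / extent
    ns, inv = [], []
    for k in range(1, min_sizes + 2):
        boxes = 2**k
        cells = np.unique(np.floor(pts * boxes * (1 - 1e-12)).astype(int), axis=0)
        ns.append(len(cells))
        inv.append(boxes)
    slope = np.polyfit(np.log(inv), np.log(ns), 1)[0]
    return float(slope)


def _resample_edges(m: Morphology, spacing: float = 1.0) -> np.ndarray:
    """Dense points along every edge (for box counting)."""
    e = m.edges()
    pts = [m.xyz]
    for c, p in e:
        a, b = m.xyz[p], m.xyz[c]
        ln = np.linalg.norm(b - a)
        k = int(ln / spacing)
        if k > 0:
            f = (np.arange(1, k + 1) / (k + 1))[:, None]
            pts.append(a + f * (b - a))
    return np.vstack(pts)


def extract_features(m: Morphology) -> FeatureVector:
    """Named morphometric features of one reconstruction.

    Soma volume/surface use a sphere model of the soma node radius; lengths
    are summed edge Euclidean (or per-axis projected) lengths; spreads are
    coordinate extents; the hull is the 3-D convex hull of dendritic nodes
    (volume 0, flagged, for degenerate point sets); fractal dimension is
    2-D box counting on the RC-DV projection; tortuosity is the mean
    path/chord ratio over inter-branch-point segments.
    """
    flags = []
    soma_i = m.soma_index()
    r = float(m.radius[soma_i])
    soma_volume = 4.0 / 3.0 * np.pi * r**3
    soma_surface = 4.0 * np.pi * r**2

    lengths = m.edge_lengths()
    total_len = float(lengths.sum())
    e = m.edges()
    rc_ax, dv_ax = m.axes["RC"], m.axes["DV"]
    if e.size:
        d = m.xyz[e[:, 0]] - m.xyz[e[:, 1]]
        rc_len = float(np.abs(d[:, rc_ax]).sum())
        dv_len = float(np.abs(d[:, dv_ax]).sum())
    else:
        rc_len = dv_len = 0.0
    rc = m.axis_coord("RC")
    dv = m.axis_coord("DV")
    rc_spread = float(rc.max() - rc.min())
    dv_spread = float(dv.max() - dv.min())
    rc_dv_ratio = rc_spread / dv_spread if dv_spread > 0 else float("nan")

    dend = m.xyz[m.types != 1]
    hull_volume = 0.0
    if dend.shape[0] >= 4:
        try:
            hull_volume = float(ConvexHull(dend).volume)
        except QhullError:
            flags.append("degenerate_hull")
    else:
        flags.append("degenerate_hull")

    child_counts = m.children_counts()
    non_soma = m.types != 1
    n_branch = int(np.sum((child_counts > 1) & non_soma))
    n_trees = int(child_counts[soma_i])

    # branch order: branch points crossed walking from the soma (independent
    # of node storage order)
    idx = m.index_of()
    max_order = 0
    for k in range(m.n_nodes):
        if child_counts[k] == 0 and non_soma[k]:  # tips only
            order, p = 0, m.parent[k]
            while p != -1:
                pi = idx[int(p)]
                if child_counts[pi] > 1 or m.types[pi] == 1:
                    order += 1
                p = m.parent[pi]
            max_order = max(max_order, order)

    segs = _branch_segments(m)
    torts = []
    for path in segs:
        xyz = m.xyz[path]
        plen = float(np.linalg.norm(np.diff(xyz, axis=0), axis=1).sum())
        chord = float(np.linalg.norm(xyz[-1] - xyz[0]))
        if chord > 1e-9:
            torts.append(plen / chord)
    mean_tort = float(np.mean(torts)) if torts else float("nan")

    if m.n_nodes > 1:
        proj = _resample_edges(m)[:, [rc_ax, dv_ax]]
        fractal = _fractal_dimension(proj)
    else:
        fractal = 0.0

    # dendritic cable surface / volume from per-edge cylinders
    if e.size:
        radii = 0.5 * (m.radius[e[:, 0]] + m.radius[e[:, 1]])
        dend_mask = m.types[e[:, 0]] != 1
        dend_surface = float(
            (2 * np.pi * radii * lengths)[dend_mask].sum()
        )
        dend_volume = float((np.pi * radii**2 * lengths)[dend_mask].sum())
    else:
        dend_surface = dend_volume = 0.0

    values = {
        "soma_volume": soma_volume,
        "soma_surface": soma_surface,
        "total_dendritic_length": total_len,
        "rc_dendritic_length": rc_len,
        "dv_dendritic_length": dv_len,
        "rc_spread": rc_spread,
        "dv_spread": dv_spread,
        "rc_dv_ratio": rc_dv_ratio,
        "convex_hull_volume": hull_volume,
        "n_branch_nodes": float(n_branch),
        "n_trees": float(n_trees),
        "max_branch_order": float(max_order),
        "fractal_dimension": fractal,
        "mean_tortuosity": mean_tort,
        "dendritic_surface": dend_surface,
        "dendritic_volume": dend_volume,
    }
    return FeatureVector(values=values, flags=flags)


def feature_table(morphologies: dict) -> pd.DataFrame:
    """Feature matrix (cells x features) from {cell_id: Morphology}."""
    rows = {cid: extract_features(m).values for cid, m in morphologies.items()}
    return pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_NAMES)]


# --------------------------------------------------------------------------
# clustering and group statistics
# --------------------------------------------------------------------------


def kmeans_two(features: pd.DataFrame, seed: int = 0) -> ClusterResult:
    """Two-cluster K-means (k-means++ seeding) on z-scored features.

    Constant (and all-NaN) feature columns are dropped with a warning.
    Cluster indices are relabelled so cluster 1 has the smaller centroid
    soma volume, matching the convention that the smaller-soma (excitatory)
    class lands in cluster 1.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 cells to cluster")
    X = features.copy()
    dropped = []
    for col in list(X.columns):
        v = X[col].to_numpy(dtype=float)
        if np.all(~np.isfinite(v)) or np.nanstd(v) == 0:
            dropped.append(col)
    if dropped:
        warnings.warn(
            f"dropping constant/empty feature columns: {dropped}", stacklevel=2
        )
        X = X.drop(columns=dropped)
    X = X.fillna(X.mean())
    Z = (X - X.mean()) / X.std(ddof=0)
    km = KMeans(
        n_clusters=2, init="k-means++", n_init=10, max_iter=300, tol=1e-8,
        random_state=seed % (2**32),
    )
    raw = km.fit_predict(Z.to_numpy())
    # orient clusters by centroid soma volume when available
    key = "soma_volume" if "soma_volume" in X.columns else X.columns[0]
    mean0 = X[key].to_numpy()[raw == 0].mean()
    mean1 = X[key].to_numpy()[raw == 1].mean()
    small_first = mean0 <= mean1
    labels = np.where(raw == (0 if small_first else 1), 1, 2)
    assignments = pd.Series(labels, index=features.index, name="cluster")
    centroids = X.groupby(assignments).mean()
    centroids.index.name = "cluster"
    return ClusterResult(
        assignments=assignments,
        centroids=centroids,
        seed=seed,
        dropped_features=dropped,
    )


def contingency(result: ClusterResult, labels) -> ContingencyTable:
    """Class x cluster counts with per-class purity percentages.

    ``labels`` maps every clustered cell to its class (e.g. excitatory /
    inhibitory); an unlabeled cell is an error.
    """
    lab = pd.Series(labels)
    missing = [c for c in result.assignments.index if c not in lab.index]
    if missing:
        raise ValueError(f"unlabeled cells: {missing[:5]}")
    df = pd.DataFrame(
        {
            "label": lab.loc[result.assignments.index],
            "cluster": result.assignments,
        }
    )
    return ContingencyTable.from_calls(df, "label", "cluster")


def compare_groups(a, b, alpha: float = 0.05) -> GroupComparison:
    """Two-sample comparison with a normality screen.

    Shapiro-Wilk on each sample; when both pass at ``alpha`` an unpaired
    t test is run, otherwise the Mann-Whitney rank-sum test. Zero-variance
    samples go straight to the rank-sum branch.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs >= 3 observations")

    def _normal(x):
        if np.std(x) == 0:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return stats.shapiro(x).pvalue > alpha

    na, nb = _normal(a), _normal(b)
    if na and nb:
        t, p = stats.ttest_ind(a, b)
        return GroupComparison(test="t", statistic=float(t), pvalue=float(p),
                               normal=(na, nb))
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        test="mann-whitney", statistic=float(u), pvalue=float(p), normal=(na, nb)
    )
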