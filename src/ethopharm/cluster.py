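"""Data-reduction pipeline: correlation matrix, 1-|r| distance, classical
multidimensional scaling, and k-means with a validity-index vote on k.

The goal is to group outcome measures by correlational proximity regardless
of sign: the pairwise Pearson matrix is converted elementwise to the
distance d = 1 - |r|, embedded in two dimensions by Torgerson (classical)
scaling, and the embedded points are k-means clustered.  The number of
clusters is chosen by majority vote of four internal validity indices
(mean silhouette, Calinski-Harabasz, Davies-Bouldin, Dunn) over a
configurable k range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .errors import ConfigError, DegenerateColumnError, InsufficientDataError
from .measures import MeasureTable
from .stats import p_from_r

__all__ = [
    "CorrelationResult", "MDSResult", "ClusterReport",
    "correlation_matrix", "aoe_order", "correlation_to_distance",
    "classical_mds", "kmeans_cluster", "select_k", "run_clustering",
]


@dataclass
class CorrelationResult:
    """Pairwise Pearson r and p matrices plus a display ordering."""

    names: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame               # per-pair complete sample size
    order: list[str] = field(default_factory=list)


@dataclass
class MDSResult:
    """2-D Torgerson-scaling coordinates, eigenvalues, reconstruction error."""

    coords: pd.DataFrame          # measures x retained axes
    eigenvalues: np.ndarray       # all eigenvalues, descending
    recon_error: float            # max |embedded - input| distance


@dataclass
class ClusterReport:
    """Chosen k, per-measure labels, per-k validity indices and votes."""

    k: int
    labels: dict[str, int]
    indices: pd.DataFrame         # index: k; columns: the four indices
    votes: dict[str, int]         # index name -> its preferred k
    k_range: tuple[int, int]


def correlation_matrix(table: MeasureTable | pd.DataFrame,
                       columns: list[str] | None = None) -> CorrelationResult:
    """Pairwise-complete Pearson correlations between measure columns.

    For every pair, the animals with both values present are used; the
    per-pair n is carried into the p computation, so a panel combining
    phases with attrition keeps correct degrees of freedom pair by pair.
    """
    data = table.data if isinstance(table, MeasureTable) else table
    cols = list(columns) if columns is not None else list(data.columns)
    unknown = [c for c in cols if c not in data.columns]
    if unknown:
        raise ConfigError(f"unknown measure columns {unknown}; "
                          f"valid: {list(data.columns)}")
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), float(len(data)))
    for i in range(k):
        xi = data[cols[i]].dropna().to_numpy()
        if xi.size < 3:
            raise InsufficientDataError(f"fewer than 3 values in {cols[i]!r}")
        if np.ptp(xi) == 0:
            raise DegenerateColumnError(cols[i])
        for j in range(i + 1, k):
            pair = data[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                raise InsufficientDataError(
                    f"fewer than 3 complete rows for ({cols[i]}, {cols[j]})")
            x = pair[cols[i]].to_numpy()
            y = pair[cols[j]].to_numpy()
            if np.ptp(x) == 0:
                raise DegenerateColumnError(cols[i])
            if np.ptp(y) == 0:
                raise DegenerateColumnError(cols[j])
            rij = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = p_from_r(rij, len(pair))
            n[i, j] = n[j, i] = len(pair)
    result = CorrelationResult(
        names=cols,
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        n=pd.DataFrame(n, index=cols, columns=cols),
    )
    result.order = aoe_order(result)
    return result


def aoe_order(corr: CorrelationResult) -> list[str]:
    """Display ordering by angular order of the eigenvectors.

    The two leading eigenvectors e1, e2 of the correlation matrix define an
    angle atan2(e2_i, e1_i) per measure; measures are sorted by that angle,
    so strongly correlated measures end up adjacent.  Determinism: each
    eigenvector is flipped if its entries sum to a negative value, and a
    fully diagonal matrix (no correlation information; the leading
    eigenspace is degenerate) keeps the input order.
    """
    r = corr.r.to_numpy()
    if np.allclose(r - np.diag(np.diag(r)), 0.0):
        return list(corr.names)
    vals, vecs = np.linalg.eigh(r)
    e1 = vecs[:, -1]
    e2 = vecs[:, -2]
    if e1.sum() < 0:
        e1 = -e1
    if e2.sum() < 0:
        e2 = -e2
    ang = np.mod(np.arctan2(e2, e1), 2 * np.pi)
    order = np.argsort(ang, kind="stable")
    return [corr.names[i] for i in order]


def correlation_to_distance(corr: CorrelationResult) -> pd.DataFrame:
    """Elementwise distance d = 1 - |r|; sign of the correlation discarded."""
    d = 1.0 - corr.r.abs()
    np.fill_diagonal(d.to_numpy(), 0.0)
    return d


def classical_mds(d: pd.DataFrame, dims: int = 2) -> MDSResult:
    """Torgerson scaling of a distance matrix.

    B = -1/2 J D^2 J with J the centering operator; the leading eigenpairs
    of B give coordinates sqrt(lambda) * v.  Negative eigenvalues (the
    matrix need not be Euclidean-embeddable) are dropped; if fewer than
    ``dims`` positive eigenvalues exist a warning is raised and fewer axes
    are returned.  Per-axis sign is fixed so the largest-magnitude
    coordinate is positive.  The maximum absolute difference between
    embedded and input distances is always reported, never hidden.
    """
    if dims < 1:
        raise ConfigError("dims must be >= 1")
    names = list(d.index)
    dm = d.to_numpy(dtype=float)
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    tol = 1e-10 * max(abs(vals).max(), 1.0)
    n_pos = int((vals > tol).sum())
    keep = min(dims, n_pos)
    if keep < dims:
        warnings.warn(f"only {keep} positive eigenvalues; returning {keep} axes",
                      stacklevel=2)
    coords = vecs[:, :keep] * np.sqrt(vals[:keep])
    for a in range(keep):
        if coords[np.argmax(np.abs(coords[:, a])), a] < 0:
            coords[:, a] = -coords[:, a]
    emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)) \
        if keep else np.zeros((n, n))
    return MDSResult(
        coords=pd.DataFrame(coords, index=names,
                            columns=[f"axis{a + 1}" for a in range(keep)]),
        eigenvalues=vals,
        recon_error=float(np.abs(emb - dm).max()),
    )


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by first appearance, so output is order-stable."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _lloyd(points: np.ndarray, centers: np.ndarray, max_iter: int = 200):
    """Lloyd iterations with a per-iteration monotone-descent check."""
    prev_inertia = np.inf
    labels = None
    for _ in range(max_iter):
        dist = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        new_labels = dist.argmin(axis=1)
        inertia = float(dist[np.arange(len(points)), new_labels].sum())
        if inertia > prev_inertia + 1e-9:
            raise AssertionError("k-means inertia increased across an iteration")
        if labels is not None and np.array_equal(new_labels, labels):
            return labels, inertia, centers
        labels, prev_inertia = new_labels, inertia
        for c in range(centers.shape[0]):
            mask = labels == c
            if mask.any():
                centers[c] = points[mask].mean(axis=0)
            else:  # re-seed an emptied cluster on the worst-fit point
                worst = dist[np.arange(len(points)), labels].argmax()
                centers[c] = points[worst]
    return labels, inertia, centers


def kmeans_cluster(points, k: int, seed: int = 0,
                   restarts: int = 10) -> tuple[np.ndarray, float]:
    """k-means via Lloyd's algorithm with greedy spread-out seeding.

    Each restart picks a random first center, then greedily adds the point
    farthest from the chosen set (ties to the lowest index); the best of
    ``restarts`` runs by within-cluster sum of squares wins.  Labels are
    canonicalised by first appearance; deterministic for a fixed seed.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if k > n:
        raise ConfigError(f"k = {k} exceeds number of points {n}")
    if restarts < 1:
        raise ConfigError("restarts must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        centers = [pts[rng.integers(n)]]
        while len(centers) < k:
            dist = np.min(((pts[:, None, :] - np.array(centers)[None, :, :]) ** 2
                           ).sum(-1), axis=1)
            centers.append(pts[int(dist.argmax())])
        labels, inertia, _ = _lloyd(pts, np.array(centers, dtype=float))
        if best is None or inertia < best[1] - 1e-12:
            best = (labels, inertia)
    return _canonical_labels(best[0]), best[1]


def _dunn(points: np.ndarray, labels: np.ndarray) -> float:
    """Dunn index: min inter-cluster distance / max intra-cluster diameter."""
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    same = labels[:, None] == labels[None, :]
    inter = dist[~same]
    intra = dist[same & ~np.eye(len(points), dtype=bool)]
    diameter = intra.max() if intra.size else 0.0
    if inter.size == 0:
        return 0.0
    if diameter == 0.0:
        return np.inf if inter.min() > 0 else 0.0
    return float(inter.min() / diameter)


#: name -> (scorer, higher_is_better)
_INDICES = {
    "silhouette": (lambda p, l: silhouette_score(p, l), True),
    "calinski_harabasz": (lambda p, l: calinski_harabasz_score(p, l), True),
    "davies_bouldin": (lambda p, l: davies_bouldin_score(p, l), False),
    "dunn": (lambda p, l: _dunn(p, l), True),
}


def select_k(points, k_min: int, k_max: int, seed: int = 0,
             restarts: int = 10) -> tuple[int, pd.DataFrame, dict[str, int]]:
    """Choose the cluster count by majority vote of four validity indices.

    For each k in [k_min, k_max] the k-means solution is scored by mean
    silhouette (max), Calinski-Harabasz (max), Davies-Bouldin (min) and
    Dunn (max).  Each index votes for its best k; the k with most votes
    wins, ties going to the smallest k.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if k_min < 2 or k_max > n - 1 or k_min > k_max:
        raise ConfigError(f"invalid k range [{k_min}, {k_max}] for {n} points")
    rows = {}
    for k in range(k_min, k_max + 1):
        labels, _ = kmeans_cluster(pts, k, seed=seed, restarts=restarts)
        vals = {}
        degenerate = len(np.unique(labels)) < 2
        for name, (scorer, _) in _INDICES.items():
            if degenerate:
                vals[name] = np.nan
            else:
                vals[name] = float(scorer(pts, labels))
        rows[k] = vals
    indices = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    votes = {}
    for name, (_, higher) in _INDICES.items():
        col = indices[name]
        if col.isna().all():
            continue
        votes[name] = int(col.idxmax() if higher else col.idxmin())
    if not votes:
        raise ConfigError("no validity index produced a vote")
    counts = pd.Series(list(votes.values())).value_counts()
    top = counts.max()
    chosen = int(min(k for k in counts.index if counts[k] == top))
    return chosen, indices, votes


def run_clustering(table: MeasureTable | pd.DataFrame,
                   columns: list[str] | None = None,
                   k_min: int = 2, k_max: int = 6, seed: int = 0,
                   restarts: int = 10
                   ) -> tuple[ClusterReport, MDSResult, CorrelationResult]:
    """Full measure-clustering pipeline with all intermediates returned.

    correlation -> 1-|r| distance -> 2-D classical MDS -> k selection by
    index vote -> k-means labels, deterministic for a fixed seed.
    """
    corr = correlation_matrix(table, columns)
    dist = correlation_to_distance(corr)
    mds = classical_mds(dist, dims=2)
    pts = mds.coords.to_numpy()
    k, indices, votes = select_k(pts, k_min, k_max, seed=seed, restarts=restarts)
    labels, _ = kmeans_cluster(pts, k, seed=seed, restarts=restarts)
    report = ClusterReport(
        k=k,
        labels={name: int(lab) for name, lab in zip(corr.names, labels)},
        indices=indices,
        votes=votes,
        k_range=(k_min, k_max),
    )
    return report, mds, corr
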