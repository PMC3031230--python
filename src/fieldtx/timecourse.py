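"""Phase structure of the weekly leaf time course.

The developmental time course (17 weekly leaf samples, 13-125 days
after transplanting) is segmented into contiguous growth phases from
the sample-by-sample Pearson-correlation (PCC) matrix: samples are
clustered on their correlation profiles (Euclidean distance, complete
linkage) and, when the cut is not contiguous in time, an exhaustive
search over contiguous boundary placements maximizes mean within-phase
PCC minus mean between-adjacent-phase PCC.  The module also provides
PCA, gene-level hierarchical clustering (including the uncentered-
correlation / centroid recipe), cluster-based refinement of transition
gene sets, and detection of one-timepoint transient spikes (pollen
contamination of leaf samples at flowering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "pcc_matrix",
    "segment_phases",
    "PhaseSegmentation",
    "pca",
    "PCAResult",
    "hclust_genes",
    "GeneClusterTree",
    "refine_de_by_cluster",
    "detect_transient_spike",
    "SpikeReport",
]


def pcc_matrix(mat: pd.DataFrame, samples: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlation between sample columns."""
    values = mat if samples is None else mat[samples]
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    if (sd == 0).any():
        bad = [values.columns[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant sample profile(s): {bad}")
    r = np.corrcoef(arr.T)
    r = (r + r.T) / 2.0  # exact symmetry
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=values.columns, columns=values.columns)


@dataclass(frozen=True)
class PhaseSegmentation:
    timepoints: list          # ordered timepoint labels (e.g. DAT)
    pcc: pd.DataFrame
    phase_labels: np.ndarray  # per-timepoint 1..k, non-decreasing
    boundaries: list[tuple]   # (label before, label after) pairs
    method: str               # "hclust" or "exhaustive"


def _labels_contiguous(labels: np.ndarray) -> bool:
    """True when each cluster occupies one run along the time axis."""
    seen: set[int] = set()
    prev = None
    for lab in labels:
        if lab != prev:
            if lab in seen:
                return False
            seen.add(lab)
            prev = lab
    return True


def _segmentation_score(r: np.ndarray, cuts: tuple[int, ...]) -> float:
    """Mean within-phase PCC minus mean between-adjacent-phase PCC for
    boundaries after the 0-based indices in ``cuts``."""
    n = r.shape[0]
    edges = [0, *[c + 1 for c in cuts], n]
    within: list[float] = []
    between: list[float] = []
    for s, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        for i in range(lo, hi):
            for j in range(i + 1, hi):
                within.append(r[i, j])
        if s + 2 < len(edges):
            nxt_hi = edges[s + 2]
            for i in range(lo, hi):
                for j in range(hi, nxt_hi):
                    between.append(r[i, j])
    w = float(np.mean(within)) if within else 0.0
    b = float(np.mean(between)) if between else 0.0
    return w - b


def segment_phases(pcc: pd.DataFrame, k: int = 3) -> PhaseSegmentation:
    """Cut the ordered time course into ``k`` contiguous phases.

    Samples (rows of the PCC matrix, assumed time-ordered) are first
    clustered on their correlation profiles with Euclidean distance and
    complete linkage.  If the k-cluster cut is contiguous in time it is
    kept; otherwise every contiguous placement of k-1 boundaries is
    scored (mean within-phase PCC minus mean between-adjacent-phase
    PCC) and the best one is returned.  ``method`` records which path
    was taken.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = pcc.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of timepoints ({n})")
    r = pcc.to_numpy(dtype=float)
    Z = hierarchy.linkage(r, method="complete", metric="euclidean")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    if _labels_contiguous(raw) and len(np.unique(raw)) == k:
        method = "hclust"
        labels = np.empty(n, dtype=int)
        phase = 0
        prev = None
        for i, lab in enumerate(raw):
            if lab != prev:
                phase += 1
                prev = lab
            labels[i] = phase
    else:
        method = "exhaustive"
        best = max(
            combinations(range(n - 1), k - 1),
            key=lambda cuts: _segmentation_score(r, cuts),
        )
        labels = np.empty(n, dtype=int)
        edges = [0, *[c + 1 for c in best], n]
        for s, (lo, hi) in enumerate(zip(edges[:-1], edges[1:]), start=1):
            labels[lo:hi] = s
    tps = list(pcc.index)
    boundaries = [
        (tps[i], tps[i + 1]) for i in range(n - 1) if labels[i] != labels[i + 1]
    ]
    return PhaseSegmentation(timepoints=tps, pcc=pcc, phase_labels=labels,
                             boundaries=boundaries, method=method)


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame     # samples x components
    loadings: pd.DataFrame   # genes x components
    variance_ratio: np.ndarray
    means: pd.Series         # per-gene centering means


def pca(mat: pd.DataFrame) -> PCAResult:
    """PCA of sample profiles by SVD of the gene-centered data.

    Samples are observations in gene space.  Variance fractions sum to
    1; the sign of each component is fixed so its largest-magnitude
    loading is positive.  ``scores @ loadings.T + means`` reproduces
    the input.
    """
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = mat.to_numpy(dtype=float).T  # samples x genes
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    for c in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[c]))
        if Vt[c, pivot] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    scores = U * s
    var = s ** 2
    ratio = var / var.sum() if var.sum() > 0 else var
    comp = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=mat.columns, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=mat.index, columns=comp),
        variance_ratio=ratio,
        means=pd.Series(mu, index=mat.index),
    )


@dataclass(frozen=True)
class GeneClusterTree:
    linkage: np.ndarray
    genes: pd.Index
    distance_name: str
    inversions: list[int] = field(default_factory=list)

    def cut(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=n_clusters,
                                    criterion="maxclust")
        return pd.Series(labels, index=self.genes, name="cluster")


def _uncentered_corr_distance(X: np.ndarray) -> np.ndarray:
    """1 - sum(x*y)/sqrt(sum(x^2) sum(y^2)); zero rows get distance 1."""
    ss = (X ** 2).sum(axis=1)
    zero = ss == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero profile(s): uncentered "
                      "correlation undefined, distance set to 1", stacklevel=3)
    denom = np.sqrt(np.outer(ss, ss))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X @ X.T) / denom
    d = 1.0 - r
    d[zero, :] = 1.0
    d[:, zero] = 1.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


_DISTANCES = ("correlation", "uncentered", "euclidean")
_LINKAGES = ("average", "centroid", "complete")


def hclust_genes(
    relmat: pd.DataFrame,
    genes: list[str] | None = None,
    distance: str = "uncentered",
    linkage: str = "centroid",
) -> GeneClusterTree:
    """Hierarchical clustering of gene profiles under a named recipe.

    Distances: centered Pearson correlation, uncentered correlation
    (scale- but not shift-invariant), or Euclidean.  Centroid linkage on
    a correlation-type distance can produce inversions (a merge lower
    than its children); these are recorded, not hidden.
    """
    if distance not in _DISTANCES:
        raise ValueError(f"distance must be one of {_DISTANCES}")
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    values = relmat if genes is None else relmat.loc[genes]
    if len(values) < 2:
        raise ValueError("need at least 2 genes")
    X = values.to_numpy(dtype=float)
    if distance == "euclidean":
        condensed = pdist(X, metric="euclidean")
    elif distance == "correlation":
        condensed = squareform(_corr_distance_safe(X), checks=False)
    else:
        condensed = squareform(_uncentered_corr_distance(X), checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    heights = Z[:, 2]
    inversions = _find_inversions(Z)
    return GeneClusterTree(
        linkage=Z, genes=values.index,
        distance_name=f"{distance}-{linkage}", inversions=inversions,
    )


def _corr_distance_safe(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant profile(s): correlation "
                      "undefined, distance set to 1", stacklevel=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    d = 1.0 - r
    d[constant, :] = 1.0
    d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def _find_inversions(Z: np.ndarray) -> list[int]:
    """Merge steps whose height is below a child merge's height."""
    n = Z.shape[0] + 1
    inversions = []
    for i in range(Z.shape[0]):
        for child in (int(Z[i, 0]), int(Z[i, 1])):
            if child >= n and Z[i, 2] < Z[child - n, 2]:
                inversions.append(i)
                break
    return inversions


def refine_de_by_cluster(
    tree: GeneClusterTree | None,
    relmat: pd.DataFrame,
    transition: tuple,
    n_cut: int = 10,
) -> tuple[pd.Index, pd.Index]:
    """Refine a transition DE gene set by expression-pattern similarity.

    The DE genes' tree is cut into ``n_cut`` clusters; a cluster is kept
    when its centroid's step across the transition (median over
    timepoints from ``transition[1]`` on, minus median over timepoints
    up to ``transition[0]``) is at least half the median per-gene
    |step| of the full DE set.  Medians make the step robust to
    one-timepoint transients sitting on the transition itself, which
    would otherwise masquerade as sustained changes.  Kept clusters are
    pooled and split by step sign.
    """
    if len(relmat) == 0:
        return pd.Index([]), pd.Index([])
    if tree is None:
        raise ValueError("tree required for non-empty gene set")
    if n_cut > len(relmat):
        raise ValueError(f"n_cut={n_cut} exceeds gene count ({len(relmat)})")
    cols = list(relmat.columns)
    t_a, t_b = transition
    i_a, i_b = cols.index(t_a), cols.index(t_b)
    before = relmat.iloc[:, : i_a + 1]
    after = relmat.iloc[:, i_b:]
    step = after.median(axis=1) - before.median(axis=1)
    threshold = np.median(np.abs(step)) / 2.0
    labels = tree.cut(n_cut).reindex(relmat.index)
    up_genes: list = []
    down_genes: list = []
    for lab, members in labels.groupby(labels).groups.items():
        centroid = relmat.loc[members].mean(axis=0)
        delta = float(centroid.iloc[i_b:].median()
                      - centroid.iloc[: i_a + 1].median())
        if abs(delta) >= threshold:
            (up_genes if delta > 0 else down_genes).extend(members)
    return pd.Index(up_genes), pd.Index(down_genes)


@dataclass(frozen=True)
class SpikeReport:
    flagged: dict                 # timepoint -> pd.Index of flagged genes
    modal_timepoint: object       # timepoint with most flags (None if none)
    all_flagged: pd.Index


def detect_transient_spike(
    mat: pd.DataFrame, min_ratio: float = 32.0
) -> SpikeReport:
    """Flag one-timepoint expression spikes in an ordered log2 series.

    A gene is flagged at interior timepoint t when its value exceeds
    both neighbors and its median over all other timepoints by more
    than log2(min_ratio).  This targets transient contamination events
    (e.g. wind-dispersed pollen on leaf samples at peak flowering)
    rather than sustained stage shifts.
    """
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    arr = mat.to_numpy(dtype=float)
    n_t = arr.shape[1]
    margin = np.log2(min_ratio)
    flagged: dict = {}
    for t in range(1, n_t - 1):
        others = np.delete(arr, t, axis=1)
        med = np.median(others, axis=1)
        neighbor_max = np.maximum(arr[:, t - 1], arr[:, t + 1])
        hit = (arr[:, t] - neighbor_max > margin) & (arr[:, t] - med > margin)
        if hit.any():
            flagged[mat.columns[t]] = mat.index[hit]
    if flagged:
        modal = max(flagged, key=lambda tp: len(flagged[tp]))
        union = flagged[modal]
        for tp, genes in flagged.items():
            if tp != modal:
                union = union.union(genes, sort=False)
    else:
        modal, union = None, pd.Index([])
    return SpikeReport(flagged=flagged, modal_timepoint=modal,
                       all_flagged=union)
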