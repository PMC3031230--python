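"""Organ/tissue specificity scoring by Shannon entropy.

A gene's expression profile over the study's N organ/tissue conditions
is turned into a probability vector p_t = w_t / sum(w), and its entropy
H = -sum p_t log2 p_t (bits) measures how evenly expression is spread:
H = log2(N) for a uniform profile, H = 0 for a single-condition gene.
Genes with low entropy and a high maximal relative expression value are
called organ/tissue specific and grouped by hierarchical clustering of
their relative-expression profiles (correlation distance, average
linkage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import RelativeMatrix

__all__ = [
    "shannon_entropy",
    "condition_weights",
    "select_specific_genes",
    "cluster_specific_genes",
    "ClusterResult",
]


def condition_weights(condition_log2: pd.DataFrame, mode: str = "linear") -> pd.DataFrame:
    """Non-negative weights from a genes x conditions log2 matrix.

    ``linear`` (default): w = 2**log2-value, the defensible reading when
    log2 values can be negative.  ``shifted-log2``: subtract the global
    minimum so the log2 values themselves act as weights.
    """
    if mode == "linear":
        return pd.DataFrame(
            np.exp2(condition_log2.to_numpy(dtype=float)),
            index=condition_log2.index, columns=condition_log2.columns,
        )
    if mode == "shifted-log2":
        arr = condition_log2.to_numpy(dtype=float)
        return pd.DataFrame(arr - arr.min(), index=condition_log2.index,
                            columns=condition_log2.columns)
    raise ValueError(f"unknown weight mode: {mode!r}")


def shannon_entropy(condition_matrix: pd.DataFrame) -> pd.Series:
    """Per-gene Shannon entropy (bits) over condition weights.

    Parameters
    ----------
    condition_matrix
        genes x conditions matrix of non-negative linear-scale weights.

    Returns
    -------
    pandas.Series of H in [0, log2(n_conditions)], indexed by gene.
    """
    arr = condition_matrix.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("condition weights must be non-negative")
    totals = arr.sum(axis=1)
    zero = totals == 0
    if zero.any():
        genes = condition_matrix.index[zero].tolist()
        raise ValueError(f"gene(s) with all-zero profile: {genes}")
    p = arr / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return pd.Series(-plogp.sum(axis=1), index=condition_matrix.index,
                     name="entropy")


def select_specific_genes(
    entropy: pd.Series,
    relmat: RelativeMatrix | pd.DataFrame,
    h_max: float = 4.5,
    rel_min: float = 8.0,
    n_conditions: int | None = None,
) -> pd.DataFrame:
    """Flag genes with entropy < ``h_max`` and max relative expression
    > ``rel_min`` in at least one sample (both strict).

    Returns a frame indexed by gene with columns ``entropy``,
    ``max_relative`` and ``specific``.
    """
    values = relmat.values if isinstance(relmat, RelativeMatrix) else relmat
    if n_conditions is not None:
        if not (0 < h_max <= np.log2(n_conditions)):
            raise ValueError(
                f"h_max={h_max} outside (0, log2({n_conditions})={np.log2(n_conditions):.3f}]"
            )
    common = entropy.index.intersection(values.index)
    if len(common) != len(entropy) or len(common) != len(values.index):
        raise ValueError("entropy and relative matrix must cover the same genes")
    max_rel = values.max(axis=1).reindex(entropy.index)
    specific = (entropy < h_max) & (max_rel > rel_min)
    return pd.DataFrame(
        {"entropy": entropy, "max_relative": max_rel, "specific": specific}
    )


@dataclass(frozen=True)
class ClusterResult:
    labels: pd.Series           # gene -> cluster 1..k (k-largest-first)
    linkage: np.ndarray         # scipy linkage matrix
    genes: pd.Index


def _correlation_distance(profiles: np.ndarray) -> np.ndarray:
    """1 - Pearson r between rows; constant rows get distance 1."""
    sd = profiles.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant profile(s): correlation undefined, "
            "assigned distance 1 to all other profiles",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(profiles)
    d = 1.0 - r
    d[constant, :] = 1.0
    d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    # clip tiny negatives from floating error
    return np.clip(d, 0.0, None)


def cluster_specific_genes(
    relmat: RelativeMatrix | pd.DataFrame,
    k: int = 7,
) -> ClusterResult:
    """Hierarchically cluster specific-gene profiles and cut into ``k``.

    Distance is 1 - Pearson correlation between relative-expression
    profiles, linkage is average (UPGMA).  Cluster labels are renumbered
    1..k by decreasing size; ties broken by the lexicographically
    smallest member gene id.
    """
    values = relmat.values if isinstance(relmat, RelativeMatrix) else relmat
    if len(values) < k:
        raise ValueError(f"need at least k={k} genes, got {len(values)}")
    d = _correlation_distance(values.to_numpy(dtype=float))
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    raw_labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(raw_labels, index=values.index, name="cluster")
    # renumber: largest first, ties by smallest member id
    order = sorted(
        labels.groupby(labels).groups.items(),
        key=lambda kv: (-len(kv[1]), min(map(str, kv[1]))),
    )
    remap = {old: new for new, (old, _) in enumerate(order, start=1)}
    return ClusterResult(labels=labels.map(remap), linkage=Z, genes=values.index)
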