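"""Per-gene hypothesis testing: t-tests with BH-FDR and fold-change
filters, diurnal and stage-transition extraction, cross-tissue
intersections, balanced two-way ANOVA, and the fertile/sterile contrast.

Fold change is the geometric-mean convention: FC = 2**|mean log2(B) -
mean log2(A)|, i.e. the linear ratio implied by the difference of group
means on the log2 scale.  All selection thresholds are strict
inequalities (q < fdr_max, FC > fc_min).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleMetadata

__all__ = [
    "gene_t_test",
    "bh_adjust",
    "extract_de",
    "DEResult",
    "diurnal_extraction",
    "universal_intersection",
    "VennPartition",
    "two_way_anova",
    "fertile_sterile_contrast",
]


def _as_frame(mat) -> pd.DataFrame:
    return mat.values if isinstance(mat, ExpressionMatrix) else mat


def gene_t_test(
    mat,
    group_a: Sequence[str],
    group_b: Sequence[str],
    variant: str = "welch",
) -> pd.DataFrame:
    """Two-sided unpaired t-test per gene on log2 values.

    ``log2fc`` is mean(B) - mean(A).  Degenerate rows where both groups
    have zero variance use the convention p = 1 for equal means and
    p = 0 for unequal means.
    """
    values = _as_frame(mat)
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant: {variant!r}")
    a = values[group_a].to_numpy(dtype=float)
    b = values[group_b].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=(variant == "pooled"))
        p = np.asarray(res.pvalue, dtype=float)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[degenerate & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = 0.0
    return pd.DataFrame({"p": p, "log2fc": log2fc}, index=values.index)


def bh_adjust(p: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (input order)."""
    arr = np.asarray(p, dtype=float)
    if arr.size and ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValueError("p-values must lie in [0, 1]")
    if arr.size == 0:
        return arr.copy()
    return multipletests(arr, method="fdr_bh")[1]


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential-expression table plus the selected sets."""

    table: pd.DataFrame  # p, q, log2fc, fc, direction
    up: pd.Index         # passing genes with log2fc > 0 (higher in B)
    down: pd.Index       # passing genes with log2fc < 0 (higher in A)

    @property
    def selected(self) -> pd.Index:
        return self.up.union(self.down, sort=False)


def extract_de(
    mat,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fdr_max: float = 0.05,
    fc_min: float = 3.0,
    variant: str = "welch",
) -> DEResult:
    """Genes with q < ``fdr_max`` and FC > ``fc_min`` (both strict),
    split by sign of log2fc ('up' means higher in group B)."""
    if not group_a or not group_b:
        raise ValueError("empty sample group")
    tt = gene_t_test(mat, group_a, group_b, variant=variant)
    q = bh_adjust(tt["p"].to_numpy())
    fc = np.exp2(np.abs(tt["log2fc"].to_numpy()))
    direction = np.where(tt["log2fc"].to_numpy() >= 0, "up", "down")
    table = tt.assign(q=q, fc=fc, direction=direction)
    passing = (table["q"] < fdr_max) & (table["fc"] > fc_min)
    up = table.index[passing & (table["log2fc"] > 0)]
    down = table.index[passing & (table["log2fc"] < 0)]
    return DEResult(table=table, up=up, down=down)


def diurnal_extraction(
    mat,
    metadata: SampleMetadata,
    organ: str,
    fdr_max: float = 0.05,
    fc_min: float = 3.0,
    **select,
) -> DEResult:
    """Day/night contrast within one organ.

    Groups are that organ's 12:00 and 24:00 samples (optionally further
    restricted by ``**select`` metadata criteria, e.g. ``dat=76``).
    ``up`` = higher at daytime, ``down`` = higher at nighttime.
    """
    day = metadata.select(organ=organ, time_of_day="12:00", **select)
    night = metadata.select(organ=organ, time_of_day="24:00", **select)
    if not day or not night:
        raise ValueError(f"organ {organ!r} lacks a 12:00 or 24:00 time point")
    return extract_de(mat, night, day, fdr_max=fdr_max, fc_min=fc_min)


@dataclass(frozen=True)
class VennPartition:
    """All 2^k - 1 regions of k differential gene sets."""

    regions: dict[tuple[str, ...], set[str]]  # exact-membership regions
    universal: set[str]                       # genes in every input set
    concordant: dict[str, bool]               # universal gene -> same direction

    def region(self, *names: str) -> set[str]:
        return self.regions[tuple(sorted(names))]


def universal_intersection(results: Mapping[str, DEResult]) -> VennPartition:
    """Venn partition of per-tissue DE gene sets.

    Each input's gene set is up | down; the ``universal`` set is the
    intersection over all tissues, with a per-gene flag for direction
    concordance across tissues.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 result sets")
    names = sorted(results)
    members = {n: set(results[n].selected) for n in names}
    direction = {
        n: {**{g: "up" for g in results[n].up},
            **{g: "down" for g in results[n].down}}
        for n in names
    }
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(members[n] for n in combo))
            outside = set.union(
                *(members[n] for n in names if n not in combo), set()
            ) if len(combo) < len(names) else set()
            regions[tuple(combo)] = inside - outside
    universal = set.intersection(*(members[n] for n in names))
    concordant = {
        g: len({direction[n][g] for n in names}) == 1 for g in universal
    }
    return VennPartition(regions=regions, universal=universal,
                         concordant=concordant)


def two_way_anova(
    mat,
    factor_a: pd.Series,
    factor_b: pd.Series,
) -> pd.DataFrame:
    """Per-gene fixed-effects two-way ANOVA with interaction on a
    balanced crossed design.

    ``factor_a``/``factor_b`` map sample id -> level (e.g. tissue and
    developmental stage).  Returns per-gene p and BH q for both main
    effects and the interaction.  Raises on unbalanced designs or cells
    with fewer than 2 replicates.
    """
    values = _as_frame(mat)
    samples = [s for s in values.columns if s in factor_a.index and s in factor_b.index]
    if len(samples) < len(values.columns):
        missing = [s for s in values.columns if s not in samples]
        raise ValueError(f"sample(s) missing factor levels: {missing}")
    fa = factor_a.loc[samples]
    fb = factor_b.loc[samples]
    a_levels = sorted(fa.unique())
    b_levels = sorted(fb.unique())
    counts = pd.crosstab(fa, fb)
    if counts.shape != (len(a_levels), len(b_levels)) or counts.to_numpy().min() < 2:
        raise ValueError("design must be complete with >= 2 replicates per cell")
    if counts.to_numpy().std() != 0:
        raise ValueError("unbalanced design: unequal cell counts")
    r = int(counts.to_numpy()[0, 0])
    na, nb = len(a_levels), len(b_levels)

    Y = values[samples].to_numpy(dtype=float)  # genes x samples
    grand = Y.mean(axis=1)
    cell_means = np.empty((Y.shape[0], na, nb))
    a_means = np.empty((Y.shape[0], na))
    b_means = np.empty((Y.shape[0], nb))
    for i, al in enumerate(a_levels):
        sel_a = (fa == al).to_numpy()
        a_means[:, i] = Y[:, sel_a].mean(axis=1)
        for j, bl in enumerate(b_levels):
            sel = sel_a & (fb == bl).to_numpy()
            cell_means[:, i, j] = Y[:, sel].mean(axis=1)
    for j, bl in enumerate(b_levels):
        b_means[:, j] = Y[:, (fb == bl).to_numpy()].mean(axis=1)

    ss_a = nb * r * ((a_means - grand[:, None]) ** 2).sum(axis=1)
    ss_b = na * r * ((b_means - grand[:, None]) ** 2).sum(axis=1)
    inter = (cell_means - a_means[:, :, None] - b_means[:, None, :]
             + grand[:, None, None])
    ss_ab = r * (inter ** 2).sum(axis=(1, 2))
    fitted = np.empty_like(Y)
    for i, al in enumerate(a_levels):
        for j, bl in enumerate(b_levels):
            sel = ((fa == al) & (fb == bl)).to_numpy()
            fitted[:, sel] = cell_means[:, i, j][:, None]
    ss_e = ((Y - fitted) ** 2).sum(axis=1)

    df_a, df_b = na - 1, nb - 1
    df_ab = df_a * df_b
    df_e = na * nb * (r - 1)
    mse = ss_e / df_e
    with np.errstate(divide="ignore", invalid="ignore"):
        f_a = (ss_a / df_a) / mse
        f_b = (ss_b / df_b) / mse
        f_ab = (ss_ab / df_ab) / mse
    p_a = stats.f.sf(f_a, df_a, df_e)
    p_b = stats.f.sf(f_b, df_b, df_e)
    p_ab = stats.f.sf(f_ab, df_ab, df_e)
    return pd.DataFrame(
        {
            "p_tissue": p_a, "p_stage": p_b, "p_interaction": p_ab,
            "q_tissue": bh_adjust(p_a), "q_stage": bh_adjust(p_b),
            "q_interaction": bh_adjust(p_ab),
        },
        index=values.index,
    )


def fertile_sterile_contrast(
    mat,
    metadata: SampleMetadata,
    week: int,
    fdr_max: float = 0.05,
    fc_min: float = 2.0,
) -> DEResult:
    """Fertile vs sterile contrast at one week after heading.

    The sterile mutant lines act as replicates of the sterile group.
    ``up`` = higher in fertile plants.
    """
    fertile = metadata.select(genotype="fertile", week=week)
    sterile = metadata.select(genotype="sterile", week=week)
    if not fertile or not sterile:
        raise ValueError(f"missing fertile or sterile samples at week {week}")
    return extract_de(mat, sterile, fertile, fdr_max=fdr_max, fc_min=fc_min)
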