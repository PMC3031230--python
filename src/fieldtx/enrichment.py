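"""Gene-set and promoter-motif enrichment.

GO-slim enrichment uses the one-sided hypergeometric test (upper tail)
with Benjamini-Hochberg correction across terms.  Promoter analysis
scans IUPAC degenerate patterns (e.g. the phosphate-starvation
regulator PHR1's binding site GNATATNC, its own reverse complement)
over 1-kb upstream regions and tests gene-level presence in a study set
against a background with a one-sided Fisher exact test.  Gene-set
trajectory profiles (mean +/- s.e.m. over samples) serve GO-category,
KEGG photosynthesis and miRNA-precursor summaries alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "IUPAC_CODES",
    "MotifPattern",
    "map_to_slim",
    "read_gene2go",
    "read_slim_mapping",
    "hypergeom_enrich",
    "motif_scan",
    "motif_enrichment",
    "MotifEnrichmentResult",
    "geneset_profile",
]

#: IUPAC nucleotide codes -> admitted sequence bases.  A genomic 'N'
#: (unknown base) is matched only by pattern 'N', never by a specific code.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGTN"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate DNA pattern over the IUPAC alphabet."""

    iupac: str

    def __post_init__(self) -> None:
        bad = [c for c in self.iupac if c not in IUPAC_CODES]
        if bad or not self.iupac:
            raise ValueError(f"invalid IUPAC code(s) in pattern: {bad}")

    def __len__(self) -> int:
        return len(self.iupac)

    @property
    def length(self) -> int:
        return len(self.iupac)

    def reverse_complement(self) -> "MotifPattern":
        return MotifPattern(self.iupac.translate(_COMPLEMENT)[::-1])

    @property
    def is_palindromic(self) -> bool:
        return self.iupac == self.reverse_complement().iupac


# ---------------------------------------------------------------------------
# GO slim


def read_gene2go(path: str | Path) -> pd.DataFrame:
    """Two-column (gene_id, term_id) TSV; errors carry line numbers."""
    return _read_two_column(path, ("gene_id", "term_id"))


def read_slim_mapping(path: str | Path) -> pd.DataFrame:
    """Two-column (term_id, slim_id) TSV; errors carry line numbers."""
    return _read_two_column(path, ("term_id", "slim_id"))


def _read_two_column(path: str | Path, names: tuple[str, str]) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2 or not all(f.strip() for f in fields):
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            if lineno == 1 and tuple(fields) == names:
                continue  # optional header row
            rows.append(fields)
    return pd.DataFrame(rows, columns=list(names))


def map_to_slim(
    gene2go: pd.DataFrame, slim_mapping: pd.DataFrame
) -> dict[str, set[str]]:
    """Replace each gene's generic terms by their slim images.

    Returns slim term -> gene set, deduplicated per gene.  Generic terms
    absent from the mapping are dropped (count logged).
    """
    mapping = dict(zip(slim_mapping["term_id"], slim_mapping["slim_id"]))
    if not mapping:
        logger.warning("empty slim mapping: no annotations produced")
        return {}
    known = gene2go["term_id"].isin(mapping)
    dropped = int((~known).sum())
    if dropped:
        logger.info("dropped %d annotation(s) with unmapped generic terms", dropped)
    kept = gene2go[known]
    out: dict[str, set[str]] = {}
    for gene, term in zip(kept["gene_id"], kept["term_id"]):
        out.setdefault(mapping[term], set()).add(gene)
    return out


# ---------------------------------------------------------------------------
# hypergeometric enrichment


def hypergeom_enrich(
    study: Iterable[str],
    background: Iterable[str],
    terms: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in the study set.

    p = P[X >= k] with X ~ Hypergeom(N, K, n) where N is the background
    size, K the term's background hits, n the study size and k the
    term's study hits.  Terms with k = 0 are skipped; q is BH over the
    tested terms.
    """
    study = set(study)
    background = set(background)
    if len(background) < 2:
        raise ValueError("background must contain at least 2 genes")
    strays = study - background
    if strays:
        raise ValueError(f"study gene(s) outside background: {sorted(strays)}")
    N, n = len(background), len(study)
    rows = []
    for term_id in sorted(terms):
        term_genes = set(terms[term_id]) & background
        K = len(term_genes)
        k = len(term_genes & study)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, k, K, n, N, p))
    result = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p"])
    result["q"] = bh_adjust(result["p"].to_numpy()) if len(result) else []
    return result.sort_values(["q", "p", "term_id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# motif scanning


def _validate_sequence(sequence: str) -> None:
    for i, c in enumerate(sequence):
        if c not in "ACGTN":
            raise ValueError(f"invalid sequence character {c!r} at position {i}")


def motif_scan(sequence: str, pattern: MotifPattern | str) -> list[int]:
    """All (possibly overlapping) 0-based forward-strand match positions.

    Each pattern position must admit the sequence base per the IUPAC
    code table; a genomic 'N' matches only a pattern 'N'.
    """
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern)
    sequence = sequence.upper()
    _validate_sequence(sequence)
    L = pattern.length
    n = len(sequence)
    if n < L:
        return []
    # vectorized: boolean admission table (pattern pos x base), AND over
    # offsets of the base-coded sequence
    base_idx = {b: i for i, b in enumerate("ACGTN")}
    codes = np.fromiter((base_idx[c] for c in sequence), dtype=np.int8, count=n)
    admit = np.zeros((L, 5), dtype=bool)
    for j, code in enumerate(pattern.iupac):
        for b in IUPAC_CODES[code]:
            admit[j, base_idx[b]] = True
    ok = np.ones(n - L + 1, dtype=bool)
    for j in range(L):
        ok &= admit[j, codes[j : j + n - L + 1]]
    return np.flatnonzero(ok).tolist()


@dataclass(frozen=True)
class MotifEnrichmentResult:
    p: float                       # one-sided Fisher exact, over-representation
    table: tuple                   # ((study+, study-), (rest+, rest-))
    counts: pd.Series              # per-gene match counts (whole universe)
    study_present: int
    background_present: int


def motif_enrichment(
    study_upstreams: Mapping[str, str],
    background_upstreams: Mapping[str, str],
    pattern: MotifPattern | str,
    flank: int = 1000,
) -> MotifEnrichmentResult:
    """Over-representation of a motif in study promoters vs background.

    Sequences are truncated to their last ``flank`` bases (the region
    proximal to the start).  Gene-level presence (>= 1 match) feeds a
    2x2 table of study / background-minus-study x present / absent,
    tested with a one-sided Fisher exact test.
    """
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern)
    missing = [g for g in study_upstreams if g not in background_upstreams]
    if missing:
        raise ValueError(f"study gene(s) missing from background: {missing}")
    counts = {}
    for gene, seq in background_upstreams.items():
        counts[gene] = len(motif_scan(seq[-flank:], pattern))
    counts = pd.Series(counts, name="matches")
    study_ids = set(study_upstreams)
    present = counts > 0
    a = int(present[list(study_ids)].sum())
    b = len(study_ids) - a
    rest = [g for g in counts.index if g not in study_ids]
    c = int(present[rest].sum())
    d = len(rest) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return MotifEnrichmentResult(
        p=float(p), table=((a, b), (c, d)), counts=counts,
        study_present=a, background_present=a + c,
    )


# ---------------------------------------------------------------------------
# trajectory profiles


def geneset_profile(
    relmat: pd.DataFrame,
    gene_set: Iterable[str],
    sample_order: list[str] | None = None,
) -> pd.DataFrame:
    """Mean and standard error of a gene set's values per sample.

    Used for GO-category trajectories, KEGG photosynthesis sets and
    miRNA-precursor probes alike; returns a frame indexed by sample with
    columns ``mean`` and ``sem``.
    """
    genes = [g for g in gene_set if g in relmat.index]
    if not genes:
        raise ValueError("gene set has empty intersection with the matrix")
    sub = relmat.loc[genes]
    if sample_order is not None:
        sub = sub[sample_order]
    mean = sub.mean(axis=0)
    sem = sub.std(axis=0, ddof=1) / np.sqrt(len(genes)) if len(genes) > 1 \
        else pd.Series(0.0, index=sub.columns)
    return pd.DataFrame({"mean": mean, "sem": sem})
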