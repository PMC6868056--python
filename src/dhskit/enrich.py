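"""Hypergeometric integration of dynamic DHSs with expression data.

Given a universe of N annotated genes, a gene set of size n1 (e.g. genes near
activated DHSs) and another of size n2 (e.g. genes 2-fold up-regulated), the
expected overlap under independence is n1 * n2 / N; the upper-tail
hypergeometric probability P[X >= observed] measures the excess.  Fold
enrichment is observed / expected.

Two counting modes are supported: gene-level (deduplicated gene sets, the
default for set tests) and pair-level, where the observed count is a number
of DHS-gene pairs supplied by the caller and only the expectation/fold/p
arithmetic is performed (``pair_enrichment``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionTable",
    "EnrichmentResult",
    "diff_expressed",
    "hypergeom_overlap",
    "pair_enrichment",
    "fold_enrichment_ladder",
    "direction_concordance",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric overlap test."""

    universe_n: int
    set1_n: int
    set2_n: int
    observed: int
    expected: float
    fold: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "universe_n": self.universe_n, "set1_n": self.set1_n,
            "set2_n": self.set2_n, "observed": self.observed,
            "expected": self.expected, "fold": self.fold, "p": self.p_value,
        }


class ExpressionTable:
    """Per-gene expression values across timepoints (linear scale, >= 0)."""

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression table")
        if (frame.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        self.frame = frame

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", float_format="%.6g")

    @property
    def genes(self) -> set:
        return set(self.frame.index)

    def __getitem__(self, timepoint: str) -> pd.Series:
        return self.frame[timepoint]


def diff_expressed(expr: ExpressionTable, t1: str, t2: str, fold: float = 2.0):
    """Genes with >= ``fold`` expression change between two timepoints.

    Returns (up, down) gene sets: up when t2 >= fold * t1, down when
    t1 >= fold * t2.  A zero baseline with positive signal counts as changed;
    genes at zero in both timepoints are unchanged.  For fold > 1 the two
    sets are disjoint.
    """
    e1 = expr[t1].to_numpy(dtype=float)
    e2 = expr[t2].to_numpy(dtype=float)
    if np.any(e1 < 0) or np.any(e2 < 0):
        raise ValueError("expression values must be non-negative")
    genes = np.asarray(expr.frame.index)
    up = (e2 >= fold * e1) & (e2 > 0)
    down = (e1 >= fold * e2) & (e1 > 0)
    return set(genes[up]), set(genes[down])


def hypergeom_overlap(set1, set2, universe) -> EnrichmentResult:
    """Upper-tail hypergeometric test of the overlap of two gene sets."""
    set1, set2, universe = set(set1), set(set2), set(universe)
    if not set1 <= universe or not set2 <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    observed = len(set1 & set2)
    return pair_enrichment(len(set1), len(set2), len(universe), observed)


def pair_enrichment(set1_n: int, set2_n: int, universe_n: int,
                    observed: int) -> EnrichmentResult:
    """Expectation, fold and upper-tail p from counts alone.

    Used both by :func:`hypergeom_overlap` and to reproduce pair-level counts
    (DHS-gene pairs) where the observed count is tallied externally.
    """
    if universe_n <= 0:
        raise ValueError("empty universe")
    expected = set1_n * set2_n / universe_n
    fold = observed / expected if expected > 0 else float("nan")
    p = float(stats.hypergeom.sf(observed - 1, universe_n, set1_n, set2_n))
    return EnrichmentResult(universe_n, set1_n, set2_n, observed, expected, fold, p)


def fold_enrichment_ladder(gene_dhs_counts: dict, gene_set, universe,
                           thresholds=(1, 2, 3)) -> dict:
    """Fold enrichment of ``gene_set`` among genes with >= k dynamic DHSs.

    Returns {k: EnrichmentResult or None}; None when no gene reaches k.
    """
    gene_set, universe = set(gene_set), set(universe)
    out = {}
    for k in thresholds:
        bucket = {g for g, c in gene_dhs_counts.items() if c >= k} & universe
        out[k] = hypergeom_overlap(bucket, gene_set, universe) if bucket else None
    return out


def direction_concordance(up, down, activated_genes, deactivated_genes,
                          universe) -> dict:
    """2x2 grid of tests relating expression direction to DHS direction.

    Keys are (expression, accessibility) pairs, e.g. ("up", "activated").
    Empty expression sets yield None entries for that row.
    """
    universe = set(universe)
    rows = {"up": set(up) & universe, "down": set(down) & universe}
    cols = {"activated": set(activated_genes) & universe,
            "deactivated": set(deactivated_genes) & universe}
    grid = {}
    for rname, rset in rows.items():
        for cname, cset in cols.items():
            grid[(rname, cname)] = (
                hypergeom_overlap(rset, cset, universe) if rset and cset else None
            )
    return grid
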