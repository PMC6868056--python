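"""Multi-sample DHS landscape comparison.

Builds the high-confidence union of "large" DHSs (more than ``min_cleavage``
cuts each), measures per-sample unique hypersensitive bases by leave-one-out
union differencing, orders a saturation curve, clusters samples with a
bootstrap-supported dendrogram, and projects samples by PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .intervals import IntervalSet, merge, total_bases
from .quantify import DhsMatrix, tally_cuts

__all__ = [
    "LandscapeSet",
    "UniqueBaseReport",
    "Dendrogram",
    "large_dhs_set",
    "build_union",
    "unique_bases",
    "saturation_curve",
    "bootstrap_dendrogram",
    "pca_landscape",
]


def large_dhs_set(profile, min_cleavage: float = 50) -> IntervalSet:
    """The sample's own hotspots carrying more than ``min_cleavage`` of its cuts."""
    hotspots = merge(profile.hotspots)
    counts = tally_cuts(profile.track, hotspots)
    keep = [iv for iv, c in zip(hotspots, counts) if c > min_cleavage]
    return IntervalSet(keep, label=profile.name)


@dataclass
class LandscapeSet:
    """Per-sample large-DHS sets and their merged high-confidence union."""

    sample_names: list
    large_sets: dict  # name -> IntervalSet
    union_dhss: IntervalSet
    union_bases: int

    def subset_union_bases(self, names) -> int:
        ivs = [iv for n in names for iv in self.large_sets[n]]
        return total_bases(IntervalSet(ivs))


@dataclass
class UniqueBaseReport:
    """Bases each sample alone contributes to the union (leave-one-out)."""

    union_bases: int
    unique_bp: dict  # name -> bp lost when the sample is excluded
    unique_fraction: dict = field(init=False)

    def __post_init__(self) -> None:
        self.unique_fraction = {
            n: (bp / self.union_bases if self.union_bases else 0.0)
            for n, bp in self.unique_bp.items()
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unique_bp": pd.Series(self.unique_bp),
                "unique_fraction": pd.Series(self.unique_fraction),
            }
        ).rename_axis("sample")


def build_union(samples, min_cleavage: float = 50) -> LandscapeSet:
    """Merge each sample's large DHSs into the high-confidence union set."""
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("landscape comparison needs at least 2 samples")
    large = {p.name: large_dhs_set(p, min_cleavage) for p in samples}
    union = merge(IntervalSet([iv for s in large.values() for iv in s], label="union"))
    return LandscapeSet([p.name for p in samples], large, union, total_bases(union))


def unique_bases(landscape: LandscapeSet) -> UniqueBaseReport:
    """unique_bp(s) = union bases of all samples minus union bases without s."""
    names = landscape.sample_names
    unique = {
        s: landscape.union_bases
        - landscape.subset_union_bases([n for n in names if n != s])
        for s in names
    }
    return UniqueBaseReport(landscape.union_bases, unique)


def saturation_curve(landscape: LandscapeSet):
    """Cumulative union bp adding samples by descending unique contribution.

    Returns (ordered sample names, cumulative bp list); the last value equals
    the full union size.
    """
    report = unique_bases(landscape)
    order = sorted(landscape.sample_names,
                   key=lambda s: (-report.unique_bp[s], s))
    cumulative = [landscape.subset_union_bases(order[: i + 1])
                  for i in range(len(order))]
    return order, cumulative


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _log_counts(matrix: DhsMatrix) -> np.ndarray:
    return np.log10(1.0 + matrix.counts)


def _linkage(data: np.ndarray, names) -> np.ndarray:
    """Average-linkage tree on 1 - Pearson correlation between sample columns."""
    corr = np.corrcoef(data.T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    dist = (dist + dist.T) / 2
    return hierarchy.average(squareform(dist, checks=False))


def _bipartitions(Z: np.ndarray, names) -> set:
    """Non-trivial unrooted bipartitions of a linkage tree.

    Each side is canonicalized as the side NOT containing names[0].
    """
    n = len(names)
    clusters = {i: frozenset([names[i]]) for i in range(n)}
    parts = set()
    for k, (a, b, _d, _c) in enumerate(Z):
        merged = clusters[int(a)] | clusters[int(b)]
        clusters[n + k] = merged
        side = merged if names[0] not in merged else frozenset(names) - merged
        if 2 <= len(side) <= n - 2:
            parts.add(side)
    return parts


@dataclass
class Dendrogram:
    """Sample tree with bootstrap bipartition support."""

    names: list
    linkage: np.ndarray
    support: dict  # bipartition (frozenset of names) -> fraction in [0, 1]

    def to_newick(self) -> str:
        """Newick string; internal node labels carry bootstrap support."""
        n = len(self.names)
        clusters = {i: frozenset([self.names[i]]) for i in range(n)}
        for k, (a, b, _d, _c) in enumerate(self.linkage):
            clusters[n + k] = clusters[int(a)] | clusters[int(b)]
        all_names = frozenset(self.names)

        def label(node_id: int) -> str:
            members = clusters[node_id]
            side = members if self.names[0] not in members else all_names - members
            sup = self.support.get(side)
            return "" if sup is None else f"{sup:.2f}"

        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0) / 2
            if node.is_leaf():
                return f"{self.names[node.id]}:{length:.6g}"
            inner = ",".join(walk(c, node.dist) for c in (node.left, node.right))
            return f"({inner}){label(node.id)}:{length:.6g}"

        root = tree
        inner = ",".join(walk(c, root.dist) for c in (root.left, root.right))
        return f"({inner}){label(root.id)};"


def bootstrap_dendrogram(matrix: DhsMatrix, n_trees: int = 100,
                         subsample: int = 10_000, seed: int = 0) -> Dendrogram:
    """Sample tree from the full matrix, with bootstrap support.

    Support of each internal bipartition is the fraction of ``n_trees`` trees
    built from random ``subsample``-row subsets (without replacement) that
    contain the same bipartition.  Deterministic given ``seed``.
    """
    n_rows = matrix.counts.shape[0]
    if subsample > n_rows:
        raise ValueError(f"subsample {subsample} exceeds {n_rows} DHS rows")
    names = list(matrix.samples)
    data = _log_counts(matrix)
    main = _linkage(data, names)
    main_parts = _bipartitions(main, names)

    rng = np.random.default_rng(seed)
    hits = {p: 0 for p in main_parts}
    for _ in range(n_trees):
        rows = rng.choice(n_rows, size=subsample, replace=False)
        parts = _bipartitions(_linkage(data[rows], names), names)
        for p in main_parts:
            if p in parts:
                hits[p] += 1
    support = {p: hits[p] / n_trees for p in main_parts}
    return Dendrogram(names, main, support)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_landscape(matrix: DhsMatrix, exclude: IntervalSet | None = None,
                  n_components: int | None = None):
    """PCA of samples over log-transformed, row-centered DHS counts.

    DHSs overlapping ``exclude`` (e.g. the NOR mask) are removed first.
    Returns (scores DataFrame indexed by sample, explained-variance ratios).
    """
    if len(matrix.samples) < 2:
        raise ValueError("PCA needs at least 2 samples")
    counts = matrix.counts
    dhss = matrix.dhss
    if exclude is not None and len(exclude):
        mask = merge(exclude).by_chrom()
        keep = np.ones(len(dhss), dtype=bool)
        for i, iv in enumerate(dhss):
            if iv.chrom not in mask:
                continue
            ms, me = mask[iv.chrom]
            j = np.searchsorted(me, iv.start, side="right")
            if j < ms.size and ms[j] < iv.end:
                keep[i] = False
        counts = counts[keep]
    if counts.shape[0] == 0:
        raise ValueError("no DHSs left after exclusion")
    X = np.log10(1.0 + counts)  # DHS x sample
    X = X - X.mean(axis=1, keepdims=True)  # center each DHS row
    if np.allclose(X, 0.0):
        raise ValueError("degenerate (constant) matrix: PCA undefined")
    n_samples = len(matrix.samples)
    if n_components is None:
        n_components = min(n_samples, 2)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X.T)  # samples x components
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    frame = pd.DataFrame(scores, index=pd.Index(matrix.samples, name="sample"),
                         columns=cols)
    return frame, pca.explained_variance_ratio_
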