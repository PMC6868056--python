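"""Synthetic multi-sample cleavage landscapes with planted truth.

Emulates the statistical structure the analysis assumes: a genome of a few
toy chromosomes carrying non-overlapping planted DHSs that are shared across
samples, private to one sample, or dynamic between the two timepoint samples
with a known fold change; per-base cleavage counts with Poisson or
negative-binomial noise over class-dependent means plus sparse uniform
background; per-sample hotspot sets; and a toy gene annotation whose
expression tracks the planted DHS dynamics with tunable concordance.

Cut positions within a DHS are multinomial-uniform given the DHS total:
every implemented statistic uses interval sums only, so per-base shape is
irrelevant.  Background cuts keep the SPOT fraction below 1 so quality
normalization is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, IntervalSet
from .quantify import CutTrack, DhsMatrix, SampleProfile
from .enrich import ExpressionTable

__all__ = [
    "LandscapeSpec",
    "TruthTable",
    "generate_landscape",
    "generate_annotation",
    "generate_grouped_matrix",
]

SHARED = "shared"
DYN_ACT = "dynamic:activated"      # more accessible in the second timepoint
DYN_DEACT = "dynamic:deactivated"  # less accessible in the second timepoint


@dataclass(frozen=True)
class LandscapeSpec:
    """Study conditions for one synthetic landscape.

    The first two samples are the developmental timepoint pair between which
    dynamic DHSs are planted; any further samples behave like the first.
    ``dhs_rate`` is the expected cut total of a DHS in its baseline "open"
    state; dynamic DHSs are ``fold_change`` times higher in one timepoint.
    Sample-specific DHSs carry signal only in their own sample (elsewhere
    just background).
    """

    n_samples: int = 2
    sample_names: tuple = ()
    chrom_lengths: dict = field(default_factory=lambda: {
        "chr1": 300_000, "chr2": 300_000, "chr3": 300_000})
    n_shared_dhs: int = 200
    n_specific_dhs: int = 20          # per sample
    n_dynamic_dhs: int = 50           # split evenly activated/deactivated
    fold_change: float = 4.0
    dhs_width: tuple = (150, 300)     # bp, uniform
    dhs_rate: float = 500.0           # mean cuts per open DHS
    background_rate: float = 0.01     # cuts per bp outside DHSs
    noise: str = "poisson"            # or "negative_binomial"
    dispersion: float = 10.0          # NB size parameter (larger = closer to Poisson)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples (the timepoint pair)")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")
        if min(self.dhs_width) <= 0 or self.dhs_rate <= 0 or self.background_rate < 0:
            raise ValueError("widths and rates must be positive")
        if self.noise not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if not self.sample_names:
            names = ["t1", "t2"] + [f"s{i+1}" for i in range(2, self.n_samples)]
            object.__setattr__(self, "sample_names", tuple(names))
        if len(self.sample_names) != self.n_samples:
            raise ValueError("sample_names length must equal n_samples")


@dataclass
class TruthTable:
    """Planted DHS identities and per-gene differential-expression truth.

    ``dhs`` columns: chrom, start, end, cls, plus one expected-cuts column
    ``mu_<sample>`` per sample.  ``genes`` (filled by generate_annotation):
    gene_id, de_status in {up, down, none}.
    """

    dhs: pd.DataFrame
    genes: pd.DataFrame | None = None

    def intervals(self, cls_prefix: str | None = None) -> IntervalSet:
        df = self.dhs
        if cls_prefix is not None:
            df = df[df["cls"].str.startswith(cls_prefix)]
        return IntervalSet([GenomicInterval(r.chrom, r.start, r.end)
                            for r in df.itertuples()])

    def classes(self) -> dict:
        return {GenomicInterval(r.chrom, r.start, r.end): r.cls
                for r in self.dhs.itertuples()}

    def to_tsv(self, path) -> None:
        self.dhs.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _place_intervals(spec: LandscapeSpec, rng: np.random.Generator,
                     min_gap: int = 2_000) -> list:
    """Place all planted DHSs without overlap, leaving gaps for genes."""
    n_total = (spec.n_shared_dhs + spec.n_samples * spec.n_specific_dhs
               + spec.n_dynamic_dhs)
    chroms = sorted(spec.chrom_lengths)
    lo_w, hi_w = spec.dhs_width
    # allocate slots proportional to chromosome length on a regular lattice,
    # then jitter: guarantees feasibility and non-overlap in one pass
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    quota = np.floor(n_total * lengths / lengths.sum()).astype(int)
    while quota.sum() < n_total:
        quota[int(np.argmax(lengths / (quota + 1)))] += 1
    intervals = []
    for chrom, n_here in zip(chroms, quota):
        if n_here == 0:
            continue
        slot = spec.chrom_lengths[chrom] // n_here
        if slot < hi_w + min_gap:
            raise ValueError(
                f"cannot place {n_here} DHSs of width <= {hi_w} on {chrom}: "
                "genome too small for the requested landscape")
        for i in range(n_here):
            width = int(rng.integers(lo_w, hi_w + 1))
            lo = i * slot + min_gap // 2
            hi = (i + 1) * slot - width - min_gap // 2
            start = int(rng.integers(lo, max(lo + 1, hi)))
            intervals.append(GenomicInterval(chrom, start, start + width))
    return intervals


def _draw_totals(rng: np.random.Generator, mu: np.ndarray, spec: LandscapeSpec):
    mu = np.asarray(mu, dtype=float)
    if spec.noise == "poisson":
        return rng.poisson(mu)
    # NB with mean mu and size (dispersion) r: p = r / (r + mu)
    r = spec.dispersion
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(r, r / (r + mu[pos]))
    return out


def generate_landscape(spec: LandscapeSpec):
    """Generate per-sample cut tracks and hotspots with a truth table.

    Returns (profiles, truth): one :class:`SampleProfile` per sample, and a
    :class:`TruthTable` recording every planted DHS's class and per-sample
    expected cut totals.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    intervals = _place_intervals(spec, rng)
    order = rng.permutation(len(intervals))
    names = list(spec.sample_names)

    classes: list = [SHARED] * spec.n_shared_dhs
    for name in names:
        classes.extend([f"specific:{name}"] * spec.n_specific_dhs)
    n_act = spec.n_dynamic_dhs // 2 + spec.n_dynamic_dhs % 2
    classes.extend([DYN_ACT] * n_act)
    classes.extend([DYN_DEACT] * (spec.n_dynamic_dhs - n_act))
    assert len(classes) == len(intervals)
    assignment = {intervals[i]: classes[j] for j, i in enumerate(order)}

    # expected cut totals, DHS x sample
    ivs_sorted = sorted(assignment)
    mu = np.zeros((len(ivs_sorted), spec.n_samples))
    for i, iv in enumerate(ivs_sorted):
        cls = assignment[iv]
        if cls == SHARED:
            mu[i, :] = spec.dhs_rate
        elif cls.startswith("specific:"):
            mu[i, names.index(cls.split(":", 1)[1])] = spec.dhs_rate
        elif cls == DYN_ACT:
            mu[i, :] = spec.dhs_rate
            mu[i, 1] = spec.dhs_rate * spec.fold_change
        elif cls == DYN_DEACT:
            mu[i, :] = spec.dhs_rate
            mu[i, 0] = spec.dhs_rate * spec.fold_change

    profiles = []
    for j, name in enumerate(names):
        positions: dict = {}
        totals = _draw_totals(rng, mu[:, j], spec)
        for iv, total in zip(ivs_sorted, totals):
            if total == 0:
                continue
            pos = rng.integers(iv.start, iv.end, size=int(total))
            positions.setdefault(iv.chrom, []).append(pos)
        for chrom in sorted(spec.chrom_lengths):
            length = spec.chrom_lengths[chrom]
            n_bg = rng.poisson(spec.background_rate * length)
            if n_bg:
                positions.setdefault(chrom, []).append(
                    rng.integers(0, length, size=int(n_bg)))
        track = CutTrack.from_positions(
            {c: np.concatenate(p) for c, p in positions.items()})
        hotspots = IntervalSet(
            [iv for i, iv in enumerate(ivs_sorted) if mu[i, j] > 0],
            label=f"{name}_hotspots")
        profiles.append(SampleProfile(name, track, hotspots))

    truth_rows = [
        {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
         "cls": assignment[iv],
         **{f"mu_{n}": mu[i, j] for j, n in enumerate(names)}}
        for i, iv in enumerate(ivs_sorted)
    ]
    truth = TruthTable(pd.DataFrame(truth_rows))
    return profiles, truth


def generate_annotation(spec: LandscapeSpec, truth: TruthTable,
                        concordance_p: float = 1.0,
                        baseline_expr: float = 100.0):
    """Tile genes between planted DHSs and derive a concordant expression table.

    One gene is placed in each gap between consecutive planted DHSs (and it
    therefore flanks both).  A gene whose dynamic neighbors are all activated
    is 2-fold up at the second timepoint with probability ``concordance_p``
    (all deactivated: 2-fold down); genes with conflicting or no dynamic
    neighbors are unchanged.  Every fifth gap also receives a transposon
    interval.  Truth gains per-gene DE status.  Deterministic given
    ``spec.seed`` (an independent substream).
    """
    if not 0 <= concordance_p <= 1:
        raise ValueError("concordance_p must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    classes = truth.classes()
    by_chrom: dict = {}
    for iv in sorted(classes):
        by_chrom.setdefault(iv.chrom, []).append(iv)

    genes, tes = [], []
    gene_neighbors: dict = {}
    gid = 0
    for chrom in sorted(by_chrom):
        ivs = by_chrom[chrom]
        for left, right in zip(ivs, ivs[1:]):
            gap_lo, gap_hi = left.end + 50, right.start - 50
            span = gap_hi - gap_lo
            if span < 300:
                continue
            gid += 1
            gene_id = f"G{gid:05d}"
            # gene occupies the left 60% of the gap; room for a TE on the right
            g_start = gap_lo
            g_end = gap_lo + max(200, int(span * 0.6))
            strand = "+" if gid % 2 else "-"
            genes.append(GeneModel(gene_id, chrom, g_start, g_end, strand))
            gene_neighbors[gene_id] = (classes[left], classes[right])
            if gid % 5 == 0 and gap_hi - g_end >= 120:
                tes.append(GenomicInterval(chrom, g_end + 10, gap_hi - 10))

    status = {}
    for gene in genes:
        ncls = {c for c in gene_neighbors[gene.gene_id] if c.startswith("dynamic")}
        de = "none"
        if ncls == {DYN_ACT} and rng.random() < concordance_p:
            de = "up"
        elif ncls == {DYN_DEACT} and rng.random() < concordance_p:
            de = "down"
        status[gene.gene_id] = de

    t1 = {g.gene_id: baseline_expr for g in genes}
    t2 = {}
    for g in genes:
        if status[g.gene_id] == "up":
            t2[g.gene_id] = 2 * baseline_expr
        elif status[g.gene_id] == "down":
            t2[g.gene_id] = baseline_expr / 2
        else:
            t2[g.gene_id] = baseline_expr
    expr = ExpressionTable(pd.DataFrame(
        {"t1": pd.Series(t1), "t2": pd.Series(t2)}).rename_axis("gene_id"))

    truth.genes = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes],
         "de_status": [status[g.gene_id] for g in genes]})
    return genes, IntervalSet(tes, label="TE"), expr


def generate_grouped_matrix(n_dhs: int = 2_000, group_sizes=(3, 3),
                            informative_frac: float = 0.3, fold: float = 4.0,
                            rate: float = 300.0, seed: int = 0) -> DhsMatrix:
    """A DHS-by-sample count matrix with two planted sample groups.

    ``informative_frac`` of the DHSs are ``fold`` times more accessible in
    the second group; counts are Poisson.  Used to validate dendrogram and
    PCA group recovery.
    """
    rng = np.random.default_rng(seed)
    names = [f"A{i+1}" for i in range(group_sizes[0])] + \
            [f"B{i+1}" for i in range(group_sizes[1])]
    mu = np.full((n_dhs, len(names)), rate)
    n_inf = int(n_dhs * informative_frac)
    mu[:n_inf, group_sizes[0]:] *= fold
    counts = rng.poisson(mu)
    width = 200
    ivs = [GenomicInterval("chr1", i * 1_000, i * 1_000 + width)
           for i in range(n_dhs)]
    return DhsMatrix(IntervalSet(ivs), names, counts.astype(float))
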