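"""Genomic-context annotation and DHS-to-gene assignment.

A DHS's midpoint decides its context: the 400 bp strand-aware window upstream
of a TSS, a gene body (intragenic), a transposable element, or intergenic.
A midpoint coinciding with several elements is tallied in all of them, so
context tallies can sum to more than the number of DHSs.

Gene assignment is proximity-based: a midpoint inside a gene body is assigned
to that gene; an intergenic midpoint is assigned to its nearest gene on each
side (up to two flanking genes).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationSet",
    "midpoint",
    "genomic_context",
    "assign_genes",
    "dynamic_dhs_per_gene",
    "genes_by_direction",
    "context_tally",
]

CONTEXTS = ("TSS", "intergenic", "intragenic", "transposon")


@dataclass
class AnnotationSet:
    """Gene models plus transposon intervals and the TSS window size (bp)."""

    genes: list
    transposons: IntervalSet = field(default_factory=IntervalSet)
    tss_window: int = 400

    def __post_init__(self) -> None:
        if self.tss_window <= 0:
            raise ValueError("tss_window must be positive")
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids in annotation")
        self.genes = sorted(self.genes, key=lambda g: (g.chrom, g.start, g.gene_id))


def midpoint(dhs: GenomicInterval) -> int:
    """DHS midpoint, floor((start + end) / 2)."""
    return (dhs.start + dhs.end) // 2


def _tss_window(gene, window: int):
    """Half-open genomic span of the strand-aware upstream window."""
    if gene.strand == "+":
        return max(0, gene.tss - window), gene.tss
    return gene.tss + 1, gene.tss + 1 + window


def genomic_context(dhs: GenomicInterval, ann: AnnotationSet) -> set:
    """Contexts containing the DHS midpoint; never empty (falls back to intergenic)."""
    mid = midpoint(dhs)
    contexts: set = set()
    for gene in ann.genes:
        if gene.chrom != dhs.chrom:
            continue
        if gene.start <= mid < gene.end:
            contexts.add("intragenic")
        ws, we = _tss_window(gene, ann.tss_window)
        if ws <= mid < we:
            contexts.add("TSS")
    for te in ann.transposons:
        if te.chrom == dhs.chrom and te.start <= mid < te.end:
            contexts.add("transposon")
            break
    if not contexts:
        contexts.add("intergenic")
    return contexts


def context_tally(dhss, ann: AnnotationSet) -> Counter:
    """Per-context DHS counts; a multi-context midpoint is tallied in each,
    so the total may exceed the number of DHSs."""
    tally: Counter = Counter()
    for dhs in dhss:
        tally.update(genomic_context(dhs, ann))
    return tally


def assign_genes(dhs: GenomicInterval, genes) -> list:
    """Assign a DHS to its neighboring gene(s) by midpoint proximity.

    Inside a gene body: that gene.  Otherwise the nearest gene on each side,
    with distance measured from the midpoint to the nearest gene-body edge
    and distance ties broken by lexicographic gene id.  Chromosomes without
    genes yield an empty assignment.
    """
    mid = midpoint(dhs)
    chrom_genes = [g for g in genes if g.chrom == dhs.chrom]
    if not chrom_genes:
        logger.warning("no genes on %s; DHS %s left unassigned", dhs.chrom, dhs)
        return []

    containing = sorted(g.gene_id for g in chrom_genes if g.start <= mid < g.end)
    if containing:
        return containing

    # nearest on the left (gene entirely at coordinates <= mid)
    left = [(mid - (g.end - 1), g.gene_id) for g in chrom_genes if g.end - 1 < mid]
    right = [(g.start - mid, g.gene_id) for g in chrom_genes if g.start > mid]
    out = []
    if left:
        out.append(min(left)[1])
    if right:
        out.append(min(right)[1])
    return out


def dynamic_dhs_per_gene(calls, genes) -> dict:
    """Count, per gene, the dynamic DHSs assigned to it.

    Each dynamic call (label != static) contributes 1 to every gene it is
    assigned to; genes with no dynamic neighbor are absent from the map.
    """
    counts: Counter = Counter()
    for call in calls:
        if call.label == "static":
            continue
        for gid in assign_genes(call.dhs, genes):
            counts[gid] += 1
    return dict(counts)


def genes_by_direction(calls, genes) -> dict:
    """Gene sets neighboring activated and deactivated DHSs."""
    out = {"activated": set(), "deactivated": set()}
    for call in calls:
        if call.label in out:
            out[call.label].update(assign_genes(call.dhs, genes))
    return out
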