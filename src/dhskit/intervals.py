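"""Genomic interval primitives and BED/GFF3 input-output.

All coordinates are 0-based half-open (BED convention) internally; GFF3 input
(1-based inclusive) is converted on read.  Chromosome names are matched by
exact string equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GeneModel",
    "read_bed",
    "write_bed",
    "read_gff_genes",
    "write_gff_genes",
    "merge",
    "subtract_mask",
    "intersect",
    "total_bases",
]


class GenomicInterval(NamedTuple):
    """A half-open genomic span [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def validate(self) -> "GenomicInterval":
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                             "require 0 <= start < end")
        return self

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class GeneModel(NamedTuple):
    """A gene body with a strand-aware transcription start site.

    ``tss`` is the 5' end of the gene: ``start`` on the + strand,
    ``end - 1`` on the - strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class IntervalSet:
    """A sorted collection of :class:`GenomicInterval`.

    A *normalized* set has no overlapping or abutting intervals on the same
    chromosome; :func:`merge` produces one.  Construction sorts by
    (chrom, start, end) but does not merge.
    """

    intervals: list = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ivs = [GenomicInterval(*iv).validate() for iv in self.intervals]
        ivs.sort()
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    @property
    def chroms(self) -> list:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> dict:
        """Per-chromosome (starts, ends) integer arrays, in sorted order."""
        out: dict = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, ([], []))
            out[iv.chrom][0].append(iv.start)
            out[iv.chrom][1].append(iv.end)
        return {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in out.items()
        }

    def is_normalized(self) -> bool:
        """True when no two same-chromosome intervals overlap or abut."""
        for starts, ends in self.by_chrom().values():
            if starts.size > 1 and np.any(starts[1:] <= ends[:-1]):
                return False
        return True

    def total_bases(self) -> int:
        return total_bases(self)

    def merge(self) -> "IntervalSet":
        return merge(self)

    def subtract(self, mask: "IntervalSet") -> "IntervalSet":
        return subtract_mask(self, mask)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        return intersect(self, other)


def merge(intervals: IntervalSet) -> IntervalSet:
    """Coalesce overlapping *or abutting* intervals (``bedops -m`` semantics)."""
    merged: list = []
    for chrom, (starts, ends) in sorted(intervals.by_chrom().items()):
        cur_s, cur_e = None, None
        for s, e in zip(starts, ends):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # overlap or abut
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append(GenomicInterval(chrom, int(cur_s), int(cur_e)))
    return IntervalSet(merged, label=intervals.label)


def subtract_mask(intervals: IntervalSet, mask: IntervalSet) -> IntervalSet:
    """Remove every base of ``mask`` from ``intervals``.

    Partially covered intervals are truncated; fully covered ones vanish.
    """
    mask_by_chrom = merge(mask).by_chrom()
    out: list = []
    for iv in intervals:
        if iv.chrom not in mask_by_chrom:
            out.append(iv)
            continue
        mstarts, mends = mask_by_chrom[iv.chrom]
        pos = iv.start
        # mask intervals that could overlap [start, end)
        lo = int(np.searchsorted(mends, iv.start, side="right"))
        for ms, me in zip(mstarts[lo:], mends[lo:]):
            if ms >= iv.end:
                break
            if ms > pos:
                out.append(GenomicInterval(iv.chrom, pos, int(ms)))
            pos = max(pos, int(me))
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end))
    return IntervalSet(out, label=intervals.label)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Per-base intersection of two interval sets (both merged first)."""
    a_m, b_m = merge(a), merge(b)
    b_by = b_m.by_chrom()
    out: list = []
    for iv in a_m:
        if iv.chrom not in b_by:
            continue
        bs, be = b_by[iv.chrom]
        lo = int(np.searchsorted(be, iv.start, side="right"))
        for s, e in zip(bs[lo:], be[lo:]):
            if s >= iv.end:
                break
            os_, oe = max(iv.start, int(s)), min(iv.end, int(e))
            if os_ < oe:
                out.append(GenomicInterval(iv.chrom, os_, oe))
    return IntervalSet(out)


def total_bases(intervals: IntervalSet) -> int:
    """Total bases covered; on a normalized set this is the per-base union size."""
    return int(sum(iv.length for iv in merge(intervals)))


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> IntervalSet:
    """Read a BED3(+) file into an :class:`IntervalSet` (sorted).

    Raises :class:`ValueError` naming the offending line on malformed input.
    """
    ivs: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if not (0 <= start < end):
                raise ValueError(f"{path}: line {lineno}: invalid span {start}-{end}")
            ivs.append(GenomicInterval(chrom, start, end))
    return IntervalSet(ivs, label=str(Path(path).stem))


def write_bed(intervals: IntervalSet, path, scores: Iterable | None = None) -> None:
    """Write sorted BED records; optional ``scores`` adds name+score columns."""
    with open(path, "w") as fh:
        if scores is None:
            for iv in intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        else:
            for iv, sc in zip(intervals, scores):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{sc}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff_genes(path, primary_only: bool = True) -> list:
    """Extract gene models from a GFF3 file via its mRNA features.

    Only primary transcripts (ID suffix ``.1``) are retained by default; the
    gene id is the transcript id with the suffix stripped.  GFF3 1-based
    inclusive coordinates become 0-based half-open.  Records without a strand
    are skipped with a warning.
    """
    genes: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start1, end1, _score, strand, _phase, attrs = fields
            if ftype != "mRNA":
                continue
            tid = _gff_attr(attrs, "ID")
            if tid is None:
                logger.warning("%s: line %d: mRNA without ID attribute, skipped", path, lineno)
                continue
            if primary_only and not tid.endswith(".1"):
                continue
            if strand not in ("+", "-"):
                logger.warning("%s: line %d: missing strand for %s, skipped", path, lineno, tid)
                continue
            gene_id = tid.rsplit(".", 1)[0] if primary_only else tid
            start, end = int(start1) - 1, int(end1)
            if not (start < end):
                raise ValueError(f"{path}: line {lineno}: invalid gene span")
            genes[gene_id] = GeneModel(gene_id, chrom, start, end, strand)
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


def write_gff_genes(genes: Iterable, path) -> None:
    """Write gene models as GFF3 gene + mRNA feature pairs (primary transcript)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            s1, e1 = g.start + 1, g.end
            fh.write(f"{g.chrom}\t.\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.chrom}\t.\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}.1;Parent={g.gene_id}\n")


def _gff_attr(attrs: str, key: str):
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1:]
    return None
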