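"""Cut-count quantification and normalization.

Per-base DNase I cleavage counts (a :class:`CutTrack`) are tallied within
union DHS intervals, normalized for sample quality by the SPOT-style fraction
of cleavages falling inside the sample's 1% FDR hotspots, filtered for low
signal, and optionally depth-thinned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, merge

__all__ = [
    "CutTrack",
    "SampleProfile",
    "DhsMatrix",
    "tally_cuts",
    "spot_fraction",
    "normalize_counts",
    "filter_low_signal",
    "thin_track",
    "read_bedgraph",
    "write_bedgraph",
]


@dataclass
class CutTrack:
    """Sparse per-base cleavage counts: chrom -> (positions, counts).

    Positions are sorted, counts are positive integers; absent positions
    are zero.
    """

    data: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict = {}
        for chrom, (pos, cnt) in self.data.items():
            pos = np.asarray(pos, dtype=np.int64)
            cnt = np.asarray(cnt, dtype=np.int64)
            if np.any(cnt < 0):
                raise ValueError("negative cleavage count")
            keep = cnt > 0
            pos, cnt = pos[keep], cnt[keep]
            order = np.argsort(pos, kind="stable")
            pos, cnt = pos[order], cnt[order]
            if pos.size and np.any(np.diff(pos) == 0):
                # collapse duplicate positions
                upos, inv = np.unique(pos, return_inverse=True)
                ucnt = np.zeros(upos.size, dtype=np.int64)
                np.add.at(ucnt, inv, cnt)
                pos, cnt = upos, ucnt
            if pos.size:
                clean[chrom] = (pos, cnt)
        self.data = clean

    @classmethod
    def from_positions(cls, positions_by_chrom: dict) -> "CutTrack":
        """Build from raw cut-site position lists (one entry per cleavage)."""
        data = {}
        for chrom, positions in positions_by_chrom.items():
            pos, cnt = np.unique(np.asarray(positions, dtype=np.int64), return_counts=True)
            data[chrom] = (pos, cnt)
        return cls(data)

    @property
    def total_cuts(self) -> int:
        return int(sum(cnt.sum() for _, cnt in self.data.values()))

    def chrom_positions(self, chrom: str):
        if chrom in self.data:
            return self.data[chrom]
        empty = np.empty(0, dtype=np.int64)
        return empty, empty

    def __eq__(self, other) -> bool:
        if not isinstance(other, CutTrack) or set(self.data) != set(other.data):
            return False
        return all(
            np.array_equal(self.data[c][0], other.data[c][0])
            and np.array_equal(self.data[c][1], other.data[c][1])
            for c in self.data
        )


@dataclass
class SampleProfile:
    """One sample: its cut track, its 1% FDR hotspot set, and quality factor."""

    name: str
    track: CutTrack
    hotspots: IntervalSet

    @property
    def spot_fraction(self) -> float:
        return spot_fraction(self.track, self.hotspots)


@dataclass
class DhsMatrix:
    """Union DHSs x samples matrix of (optionally normalized) cut counts."""

    dhss: IntervalSet
    samples: list
    counts: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.dhss), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.dhss)} DHSs x {len(self.samples)} samples")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    def column(self, sample: str) -> np.ndarray:
        try:
            j = self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}; have {self.samples}") from None
        return self.counts[:, j]

    def to_frame(self) -> pd.DataFrame:
        index = [str(iv) for iv in self.dhss]
        return pd.DataFrame(self.counts, index=pd.Index(index, name="dhs"),
                            columns=list(self.samples))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, normalized: bool = False) -> "DhsMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ivs = []
        for key in df.index:
            chrom, span = key.rsplit(":", 1)
            start, end = span.split("-")
            ivs.append(GenomicInterval(chrom, int(start), int(end)))
        return cls(IntervalSet(ivs), list(df.columns), df.to_numpy(), normalized=normalized)

    @classmethod
    def from_samples(cls, dhss: IntervalSet, profiles, normalize: bool = False) -> "DhsMatrix":
        """Tally every profile's cuts over ``dhss``; optionally SPOT-normalize."""
        cols = []
        for p in profiles:
            col = tally_cuts(p.track, dhss).astype(float)
            if normalize:
                col = normalize_counts(col, p.spot_fraction)
            cols.append(col)
        return cls(dhss, [p.name for p in profiles], np.column_stack(cols),
                   normalized=normalize)


def tally_cuts(track: CutTrack, dhss: IntervalSet) -> np.ndarray:
    """Sum per-base cleavages within each DHS [start, end)."""
    out = np.zeros(len(dhss), dtype=np.int64)
    by_chrom: dict = {}
    for i, iv in enumerate(dhss):
        by_chrom.setdefault(iv.chrom, []).append((i, iv.start, iv.end))
    for chrom, rows in by_chrom.items():
        pos, cnt = track.chrom_positions(chrom)
        if pos.size == 0:
            continue
        csum = np.concatenate(([0], np.cumsum(cnt)))
        idx = np.array([r[0] for r in rows])
        starts = np.array([r[1] for r in rows])
        ends = np.array([r[2] for r in rows])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        out[idx] = csum[hi] - csum[lo]
    return out


def spot_fraction(track: CutTrack, hotspots: IntervalSet) -> float:
    """Proportion of the sample's cleavages inside its hotspots (quality score)."""
    total = track.total_cuts
    if total == 0:
        raise ValueError("cannot compute SPOT fraction: track has zero cuts")
    inside = int(tally_cuts(track, merge(hotspots)).sum())
    return inside / total


def normalize_counts(counts: np.ndarray, spot: float) -> np.ndarray:
    """Divide counts by the SPOT fraction (sample-quality normalization)."""
    if not 0 < spot <= 1:
        raise ValueError(f"spot fraction must be in (0, 1], got {spot}")
    return np.asarray(counts, dtype=float) / spot


def filter_low_signal(matrix: DhsMatrix, min_mean: float = 50) -> DhsMatrix:
    """Drop DHSs whose mean cut count across samples is ``min_mean`` or less."""
    means = matrix.counts.mean(axis=1)
    keep = means > min_mean
    return DhsMatrix(
        IntervalSet([iv for iv, k in zip(matrix.dhss, keep) if k], label=matrix.dhss.label),
        list(matrix.samples),
        matrix.counts[keep],
        normalized=matrix.normalized,
    )


def thin_track(track: CutTrack, target_depth: int, seed: int) -> CutTrack:
    """Binomially thin a track toward ``target_depth`` total cuts.

    Each stored cleavage is retained independently with probability
    target_depth / total_cuts, so the expected total equals ``target_depth``.
    A position holding k cleavages contributes k Bernoulli trials.
    """
    total = track.total_cuts
    if target_depth > total:
        raise ValueError(f"target_depth {target_depth} exceeds total cuts {total}")
    if target_depth < 0:
        raise ValueError("target_depth must be non-negative")
    p = target_depth / total if total else 0.0
    rng = np.random.default_rng(seed)
    data = {}
    for chrom, (pos, cnt) in sorted(track.data.items()):
        if p == 1.0:
            data[chrom] = (pos.copy(), cnt.copy())
            continue
        new = rng.binomial(cnt, p)
        keep = new > 0
        data[chrom] = (pos[keep], new[keep])
    return CutTrack(data)


# ---------------------------------------------------------------------------
# bedGraph I/O
# ---------------------------------------------------------------------------

def read_bedgraph(path) -> CutTrack:
    """Read a bedGraph (chrom, start, end, count) into a CutTrack.

    Both single-base and run-length records are accepted; a run of length L
    with count c stores c at each of its L positions.
    """
    by_chrom: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), fields[3]
            count = int(float(value))
            if count <= 0:
                continue
            pos, cnt = by_chrom.setdefault(chrom, ([], []))
            pos.extend(range(start, end))
            cnt.extend([count] * (end - start))
    return CutTrack({c: (np.array(p, dtype=np.int64), np.array(k, dtype=np.int64))
                     for c, (p, k) in by_chrom.items()})


def write_bedgraph(track: CutTrack, path) -> None:
    """Write a CutTrack as run-length-compressed bedGraph (sorted, stable)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            pos, cnt = track.data[chrom]
            if pos.size == 0:
                continue
            run_start = pos[0]
            prev_pos, prev_cnt = pos[0], cnt[0]
            for p, c in zip(pos[1:], cnt[1:]):
                if p == prev_pos + 1 and c == prev_cnt:
                    prev_pos = p
                    continue
                fh.write(f"{chrom}\t{run_start}\t{prev_pos + 1}\t{prev_cnt}\n")
                run_start, prev_pos, prev_cnt = p, p, c
            fh.write(f"{chrom}\t{run_start}\t{prev_pos + 1}\t{prev_cnt}\n")
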