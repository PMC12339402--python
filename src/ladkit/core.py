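"""Core genomic data types.

All coordinates are 0-based half-open (BED convention), internally and on
disk. Strand is ignored throughout: domain and coverage analyses here are
strandless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally carrying a state/domain tag."""

    chrom: str
    start: int
    end: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp with another interval (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class Genome:
    """Ordered map of chromosome name -> length in bp."""

    def __init__(self, lengths: Dict[str, int] | Iterable[tuple]):
        items = list(lengths.items()) if isinstance(lengths, dict) else list(lengths)
        self._lengths: Dict[str, int] = {}
        for name, length in items:
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            self._lengths[name] = int(length)
        if not self._lengths:
            raise ValueError("genome must have at least one chromosome")

    @property
    def chroms(self) -> List[str]:
        return list(self._lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __getitem__(self, chrom: str) -> int:
        return self._lengths[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self._lengths)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"Genome({self._lengths!r})"

    def items(self):
        return self._lengths.items()

    def total_length(self) -> int:
        return sum(self._lengths.values())

    def n_bins(self, chrom: str, bin_size: int) -> int:
        """ceil(L / bin_size): the final bin may be shorter than bin_size."""
        return math.ceil(self._lengths[chrom] / bin_size)

    def bin_lengths(self, chrom: str, bin_size: int) -> np.ndarray:
        """Actual bp length of every bin; only the last bin may be partial."""
        L = self._lengths[chrom]
        n = self.n_bins(chrom, bin_size)
        lengths = np.full(n, bin_size, dtype=np.int64)
        lengths[-1] = L - bin_size * (n - 1)
        return lengths


class BinnedSignalTrack:
    """Fixed-width per-chromosome bins carrying signal values (e.g. RPKM).

    `values[chrom]` is a float array of length ceil(L / bin_size);
    `mask[chrom]` is a boolean array, True where the bin is valid
    (False = blacklisted or missing). Invalid bins carry NaN.
    """

    def __init__(
        self,
        genome: Genome,
        bin_size: int,
        values: Dict[str, np.ndarray],
        mask: Optional[Dict[str, np.ndarray]] = None,
    ):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.genome = genome
        self.bin_size = int(bin_size)
        self.values: Dict[str, np.ndarray] = {}
        self.mask: Dict[str, np.ndarray] = {}
        for chrom in genome:
            n = genome.n_bins(chrom, bin_size)
            v = np.asarray(values[chrom], dtype=float)
            if v.shape != (n,):
                raise ValueError(
                    f"{chrom}: expected {n} bins, got {v.shape}"
                )
            m = (
                np.asarray(mask[chrom], dtype=bool)
                if mask is not None
                else np.ones(n, dtype=bool)
            )
            if m.shape != (n,):
                raise ValueError(f"{chrom}: mask shape mismatch")
            v = v.copy()
            v[~m] = np.nan
            if np.any(v[m] < 0):
                raise ValueError(f"{chrom}: negative signal values in valid bins")
            self.values[chrom] = v
            self.mask[chrom] = m.copy()

    @classmethod
    def empty(cls, genome: Genome, bin_size: int) -> "BinnedSignalTrack":
        values = {c: np.full(genome.n_bins(c, bin_size), np.nan) for c in genome}
        mask = {c: np.zeros(genome.n_bins(c, bin_size), dtype=bool) for c in genome}
        return cls(genome, bin_size, values, mask)

    def same_grid(self, other: "BinnedSignalTrack") -> bool:
        return self.genome == other.genome and self.bin_size == other.bin_size

    def valid_runs(self, chrom: str) -> List[np.ndarray]:
        """Maximal runs of consecutive valid-bin values (invalid bins split runs)."""
        m = self.mask[chrom]
        v = self.values[chrom]
        runs: List[np.ndarray] = []
        start = None
        for i, ok in enumerate(m):
            if ok and start is None:
                start = i
            elif not ok and start is not None:
                runs.append(v[start:i].copy())
                start = None
        if start is not None:
            runs.append(v[start:].copy())
        return runs

    def valid_run_spans(self, chrom: str) -> List[tuple]:
        """(start_bin, end_bin) half-open spans of maximal valid runs."""
        m = self.mask[chrom]
        spans = []
        start = None
        for i, ok in enumerate(m):
            if ok and start is None:
                start = i
            elif not ok and start is not None:
                spans.append((start, i))
                start = None
        if start is not None:
            spans.append((start, len(m)))
        return spans


@dataclass
class DomainSet:
    """Labeled genomic intervals for one mark (one sample or a consensus).

    Intervals are kept sorted by (chrom, start) and non-overlapping within
    a chromosome.
    """

    mark: str = ""
    sample: str = ""
    intervals: List[GenomicInterval] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start))
        prev: Dict[str, int] = {}
        for iv in self.intervals:
            if iv.chrom in prev and iv.start < prev[iv.chrom]:
                raise ValueError(
                    f"overlapping intervals on {iv.chrom} near {iv.start}"
                )
            prev[iv.chrom] = iv.end

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def by_chrom(self) -> Dict[str, List[GenomicInterval]]:
        out: Dict[str, List[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def merge_intervals(
    intervals: Sequence[GenomicInterval], merge_distance: int = 0
) -> List[GenomicInterval]:
    """Merge overlapping or bookended (gap <= merge_distance) intervals."""
    out: List[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + merge_distance:
            last = out[-1]
            if iv.end > last.end:
                out[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.label)
        else:
            out.append(iv)
    return out


def intersect_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> List[GenomicInterval]:
    """Base-pair intersection of two sorted non-overlapping interval sets."""
    by_chrom_b: Dict[str, List[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    out: List[GenomicInterval] = []
    for iv in a:
        for jv in by_chrom_b.get(iv.chrom, []):
            s, e = max(iv.start, jv.start), min(iv.end, jv.end)
            if s < e:
                out.append(GenomicInterval(iv.chrom, s, e, iv.label))
    return sorted(out, key=lambda x: (x.chrom, x.start))


def union_bp(intervals: Sequence[GenomicInterval]) -> int:
    """Total bp covered by the union of intervals."""
    return sum(len(iv) for iv in merge_intervals(list(intervals)))


def jaccard_bp(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> float:
    """Base-pair Jaccard index between two interval sets (1.0 if both empty)."""
    ma, mb = merge_intervals(list(a)), merge_intervals(list(b))
    inter = sum(len(iv) for iv in intersect_intervals(ma, mb))
    union = union_bp(list(ma) + list(mb))
    return inter / union if union else 1.0
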